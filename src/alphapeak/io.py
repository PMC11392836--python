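"""Reading and writing the pipeline's plain-text interchange formats.

Spectra travel as long CSV (subject_id, parcel, freq_hz, power); metadata as
one CSV row per subject; time series as long CSV or HDF5 (one dataset per
subject/parcel pair, with the sampling rate stored as an attribute).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import PowerSpectrum, RegionalTimeSeries

SPECTRA_COLUMNS = ["subject_id", "parcel", "freq_hz", "power"]


def write_spectra_csv(spectra: pd.DataFrame, path: str | Path) -> None:
    spectra[SPECTRA_COLUMNS].to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra file missing columns: {sorted(missing)}")
    return df


def spectra_to_objects(spectra: pd.DataFrame) -> list[PowerSpectrum]:
    """Split a long spectra table into PowerSpectrum objects."""
    out = []
    for (sid, parcel), sub in spectra.groupby(["subject_id", "parcel"],
                                              sort=True):
        sub = sub.sort_values("freq_hz")
        out.append(PowerSpectrum(
            subject_id=sid, parcel=parcel,
            freqs=sub["freq_hz"].to_numpy(),
            power=sub["power"].to_numpy(),
        ))
    return out


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata file missing column {col!r}")
    return df


def read_timeseries_csv(path: str | Path, fs: float = 500.0
                        ) -> list[RegionalTimeSeries]:
    """Long CSV with columns subject_id, parcel, sample_index, amplitude."""
    df = pd.read_csv(path)
    required = {"subject_id", "parcel", "sample_index", "amplitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-series file missing columns: {sorted(missing)}")
    out = []
    for (sid, parcel), sub in df.groupby(["subject_id", "parcel"], sort=True):
        sub = sub.sort_values("sample_index")
        out.append(RegionalTimeSeries(subject_id=sid, parcel=parcel, fs=fs,
                                      samples=sub["amplitude"].to_numpy()))
    return out


def write_timeseries_hdf5(series: list[RegionalTimeSeries],
                          path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for ts in series:
            ds = fh.create_dataset(f"{ts.subject_id}/{ts.parcel}",
                                   data=ts.samples)
            ds.attrs["fs"] = ts.fs


def read_timeseries_hdf5(path: str | Path) -> list[RegionalTimeSeries]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh):
            for parcel in sorted(fh[sid]):
                ds = fh[sid][parcel]
                out.append(RegionalTimeSeries(
                    subject_id=sid, parcel=parcel,
                    fs=float(ds.attrs["fs"]),
                    samples=np.asarray(ds[()], dtype=float),
                ))
    return out
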