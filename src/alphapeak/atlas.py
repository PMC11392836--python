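"""Desikan-Killiany parcel-to-region mapping and regional aggregation.

The 68 cortical parcels of the Desikan-Killiany atlas are grouped into ten
analysis regions: {left, right} x {cingulate, frontal, occipital, parietal,
temporal}.  The insula (one parcel per hemisphere) belongs to none of the
five lobes in this scheme; the shipped default maps it to ``unassigned`` and
regional aggregation skips it.  Supply a custom mapping file to absorb it
into a lobe instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
LOBES = ("cingulate", "frontal", "occipital", "parietal", "temporal")
VALID_LOBES = LOBES + ("unassigned",)

#: The ten analysis regions, in the order used for reporting.
REGIONS = tuple(f"{h} {l}" for h in HEMISPHERES for l in LOBES)

#: The 34 Desikan-Killiany cortical parcel names (one hemisphere).
DK_PARCELS_34 = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: All 68 parcel labels, hemisphere-prefixed ("lh_bankssts", ...).
DK_PARCELS_68 = tuple(
    f"{pre}_{p}" for pre in ("lh", "rh") for p in DK_PARCELS_34
)


class MappingError(ValueError):
    """Raised for malformed parcel-to-region mapping tables."""


@dataclass
class RegionMapping:
    """Validated parcel -> (hemisphere, lobe) assignment for all 68 parcels."""

    entries: dict[str, tuple[str, str]]

    def __post_init__(self):
        seen = set(self.entries)
        missing = sorted(set(DK_PARCELS_68) - seen)
        extra = sorted(seen - set(DK_PARCELS_68))
        if missing:
            raise MappingError(f"mapping is missing parcels: {missing}")
        if extra:
            raise MappingError(f"mapping contains unknown parcels: {extra}")
        for parcel, (hemi, lobe) in self.entries.items():
            if hemi not in HEMISPHERES:
                raise MappingError(
                    f"parcel {parcel!r}: unknown hemisphere {hemi!r}")
            if lobe not in VALID_LOBES:
                raise MappingError(f"parcel {parcel!r}: unknown lobe {lobe!r}")

    def region_of(self, parcel: str) -> str | None:
        """Analysis region for a parcel, or None for unassigned parcels."""
        hemi, lobe = self.entries[parcel]
        if lobe == "unassigned":
            return None
        return f"{hemi} {lobe}"

    def region_series(self, parcels: pd.Series) -> pd.Series:
        """Vectorized :meth:`region_of`; unassigned parcels map to NaN."""
        lut = {p: self.region_of(p) for p in self.entries}
        unknown = set(parcels.unique()) - set(lut)
        if unknown:
            raise MappingError(f"unmapped parcels: {sorted(unknown)}")
        return parcels.map(lut)

    @property
    def regions(self) -> tuple[str, ...]:
        return REGIONS


def load_mapping(path: str | Path | None = None) -> RegionMapping:
    """Read a parcel mapping TSV (columns: parcel, hemisphere, lobe).

    With no path, the packaged default Desikan-Killiany lobe scheme is used.
    Duplicate rows, missing parcels, and unknown lobes raise
    :class:`MappingError` naming the offending entries.
    """
    if path is None:
        ref = resources.files("alphapeak").joinpath("data/dk10.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"parcel", "hemisphere", "lobe"}
    if not required.issubset(df.columns):
        raise MappingError(
            f"mapping file needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    dup = df["parcel"][df["parcel"].duplicated()].tolist()
    if dup:
        raise MappingError(f"duplicate parcel entries: {sorted(set(dup))}")
    entries = {
        row.parcel: (row.hemisphere, row.lobe) for row in df.itertuples()
    }
    return RegionMapping(entries)


def aggregate_regions(
    parcel_fits: pd.DataFrame,
    mapping: RegionMapping | None = None,
    rel_alpha: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Average valid parcel PAFs into the ten analysis regions per subject.

    ``parcel_fits`` is the output of :func:`alphapeak.peaks.estimate_paf_table`
    (columns ``subject_id, parcel, paf_hz, valid``).  Invalid parcels are
    excluded from the mean; a region with no valid parcel gets a missing
    PAF.  ``rel_alpha`` (optional, columns ``subject_id, parcel, rel_alpha``)
    is averaged over *all* parcels of the region, valid or not.

    Returns one row per (subject, region) with ``paf_hz``, ``n_valid_parcels``
    and ``n_total_parcels`` (and ``rel_alpha`` when supplied).
    """
    mapping = mapping or load_mapping()
    df = parcel_fits.copy()
    df["region"] = mapping.region_series(df["parcel"])
    df = df.dropna(subset=["region"])  # unassigned parcels are skipped

    grouped = df.groupby(["subject_id", "region"], sort=True)
    out = grouped.agg(
        n_valid_parcels=("valid", "sum"),
        n_total_parcels=("valid", "size"),
    ).reset_index()
    paf = (
        df[df["valid"]]
        .groupby(["subject_id", "region"])["paf_hz"]
        .mean()
        .rename("paf_hz")
    )
    out = out.merge(paf, on=["subject_id", "region"], how="left")

    if rel_alpha is not None:
        ra = rel_alpha.copy()
        ra["region"] = mapping.region_series(ra["parcel"])
        ra = ra.dropna(subset=["region"])
        ra = (
            ra.groupby(["subject_id", "region"])["rel_alpha"]
            .mean()
            .reset_index()
        )
        out = out.merge(ra, on=["subject_id", "region"], how="left")

    out["n_valid_parcels"] = out["n_valid_parcels"].astype(int)
    cols = ["subject_id", "region", "paf_hz", "n_valid_parcels",
            "n_total_parcels"]
    if rel_alpha is not None:
        cols.append("rel_alpha")
    return out[cols]


def validity_percentage(n_valid: int, n_total: int) -> float:
    """Valid-PAF percentage rounded to one decimal, e.g. 1227/1292 -> 95.0."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    return round(100.0 * n_valid / n_total, 1)


def validity_summary(
    parcel_fits: pd.DataFrame,
    grouping: str,
    metadata: pd.DataFrame | None = None,
    mapping: RegionMapping | None = None,
) -> pd.DataFrame:
    """Valid/invalid PAF counts per diagnosis group or per region.

    ``grouping='diagnosis'`` counts every parcel (including unassigned ones)
    per subject group and needs ``metadata`` with ``subject_id`` and
    ``group``; ``grouping='region'`` counts parcels of the ten analysis
    regions.  Percentages are reported at one decimal.
    """
    df = parcel_fits.copy()
    if df.empty:
        return pd.DataFrame(
            columns=[grouping, "n_valid", "n_invalid", "n_total", "pct_valid"]
        )
    if grouping == "diagnosis":
        if metadata is None:
            raise ValueError("metadata required for grouping by diagnosis")
        df = df.merge(
            metadata[["subject_id", "group"]], on="subject_id", how="left"
        )
        key = "group"
    elif grouping == "region":
        mapping = mapping or load_mapping()
        df["region"] = mapping.region_series(df["parcel"])
        df = df.dropna(subset=["region"])
        key = "region"
    else:
        raise ValueError("grouping must be 'diagnosis' or 'region'")

    g = df.groupby(key, sort=True)["valid"]
    out = pd.DataFrame({
        "n_valid": g.sum().astype(int),
        "n_total": g.size().astype(int),
    }).reset_index().rename(columns={key: grouping})
    out["n_invalid"] = out["n_total"] - out["n_valid"]
    out["pct_valid"] = [
        validity_percentage(v, t)
        for v, t in zip(out["n_valid"], out["n_total"])
    ]
    return out[[grouping, "n_valid", "n_invalid", "n_total", "pct_valid"]]
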