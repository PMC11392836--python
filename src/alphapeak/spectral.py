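"""Welch spectral estimation for parcel-level source time series.

The pipeline here starts downstream of source reconstruction: each input is
an artifact-free parcel time series sampled at 500 Hz.  The recording is cut
into consecutive 5-s segments (subjects with fewer than 10 complete segments
are rejected), and a one-sided power spectral density is estimated with
Hamming-tapered 5-s windows at 80% overlap, which yields a 0.2 Hz frequency
grid at the default sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class SegmentRejectionError(ValueError):
    """Recording too short: fewer complete segments than the required minimum."""

    def __init__(self, n_achieved: int, n_required: int):
        self.n_achieved = n_achieved
        self.n_required = n_required
        super().__init__(
            f"only {n_achieved} complete segments available, "
            f"{n_required} required"
        )


@dataclass
class RegionalTimeSeries:
    """One parcel's source-level signal for one subject."""

    subject_id: str
    parcel: str
    fs: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class PowerSpectrum:
    """Frequency/power pairs for one subject x parcel on a uniform grid."""

    subject_id: str
    parcel: str
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        d = np.diff(self.freqs)
        if self.freqs.size >= 2:
            if not np.all(d > 0):
                raise ValueError("frequency grid must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frequency grid spacing must be constant")
        if np.any(self.power < 0):
            raise ValueError("power values must be non-negative")

    @property
    def df(self) -> float:
        """Grid spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def band_mask(self, lo: float, hi: float, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask for bins with lo <= f <= hi (endpoints inclusive)."""
        return (self.freqs >= lo - tol) & (self.freqs <= hi + tol)


def segment_recording(
    ts: RegionalTimeSeries,
    segment_len_s: float = 5.0,
    min_segments: int = 10,
) -> list[np.ndarray]:
    """Cut a recording into consecutive non-overlapping fixed-length segments.

    The trailing remainder that does not fill a whole segment is dropped.
    Raises :class:`SegmentRejectionError` when fewer than ``min_segments``
    complete segments are available, carrying the achieved count so callers
    can log per-subject exclusions.
    """
    if segment_len_s <= 0:
        raise ValueError("segment length must be positive")
    seg_n = int(round(segment_len_s * ts.fs))
    n_full = ts.samples.size // seg_n
    if n_full < min_segments:
        raise SegmentRejectionError(n_full, min_segments)
    return [
        ts.samples[i * seg_n : (i + 1) * seg_n] for i in range(n_full)
    ]


def welch_psd(
    segments: list[np.ndarray],
    fs: float,
    window: str = "hamming",
    overlap_fraction: float = 0.8,
    respect_segment_boundaries: bool = False,
    subject_id: str = "",
    parcel: str = "",
) -> PowerSpectrum:
    """Average-periodogram (Welch) PSD over accepted segments.

    By default the accepted segments -- continuous stretches of a single
    recording -- are concatenated and tapered windows of one segment length
    are slid across the concatenation with the requested overlap, giving a
    bin spacing of ``1 / segment_len_s`` (0.2 Hz for 5-s segments).  With
    ``respect_segment_boundaries=True`` each segment instead contributes a
    single tapered periodogram and no window crosses a segment junction.
    """
    if not segments:
        raise ValueError("at least one segment is required")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    nperseg = len(segments[0])
    if any(len(s) != nperseg for s in segments):
        raise ValueError("all segments must have equal length")

    if respect_segment_boundaries:
        psds = []
        for seg in segments:
            f, p = signal.welch(
                seg, fs=fs, window=window, nperseg=nperseg, noverlap=0,
                detrend="constant", scaling="density",
            )
            psds.append(p)
        power = np.mean(psds, axis=0)
        freqs = f
    else:
        x = np.concatenate(segments)
        noverlap = int(round(overlap_fraction * nperseg))
        freqs, power = signal.welch(
            x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
            detrend="constant", scaling="density",
        )
    return PowerSpectrum(subject_id=subject_id, parcel=parcel,
                         freqs=freqs, power=power)


def psd_from_timeseries(
    ts: RegionalTimeSeries,
    segment_len_s: float = 5.0,
    min_segments: int = 10,
    window: str = "hamming",
    overlap_fraction: float = 0.8,
    respect_segment_boundaries: bool = False,
) -> PowerSpectrum:
    """Segment a recording and estimate its Welch PSD in one call."""
    segments = segment_recording(ts, segment_len_s, min_segments)
    return welch_psd(
        segments, fs=ts.fs, window=window, overlap_fraction=overlap_fraction,
        respect_segment_boundaries=respect_segment_boundaries,
        subject_id=ts.subject_id, parcel=ts.parcel,
    )


def relative_alpha_power(
    spec: PowerSpectrum,
    alpha_band: tuple[float, float] = (7.0, 13.0),
    total_band: tuple[float, float] = (1.0, 55.0),
) -> float:
    """Alpha-band power as a fraction of broadband power.

    Sums spectral power over bins inside ``alpha_band`` and divides by the
    sum over bins inside ``total_band``; band endpoints are inclusive on the
    discrete grid.  The result lies in [0, 1].
    """
    lo, hi = total_band
    if spec.freqs[0] > lo + 1e-9 or spec.freqs[-1] < hi - 1e-9:
        raise ValueError(
            f"spectrum [{spec.freqs[0]:g}, {spec.freqs[-1]:g}] Hz does not "
            f"cover the total band [{lo:g}, {hi:g}] Hz"
        )
    total = spec.power[spec.band_mask(*total_band)].sum()
    if total <= 0:
        raise ValueError("total power is zero; relative alpha power undefined")
    alpha = spec.power[spec.band_mask(*alpha_band)].sum()
    return float(alpha / total)
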