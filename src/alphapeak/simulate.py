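"""Seeded synthetic spectra, time series, and cohorts.

Every downstream stage of the pipeline is testable without any recording:
this module generates (a) single power spectra as a 1/f power law plus an
additive Gaussian alpha peak with multiplicative log-power noise, (b) colored-
noise time series whose expected PSD follows the same law (for exercising
the Welch stage end to end), and (c) whole two-group cohorts -- 19 children
with autism spectrum disorder (ASD) and 24 typically developing (TD) peers
by default -- with group-specific age ranges, trait-score distributions, and
region-specific age->PAF slopes.

The cohort defaults encode the study conditions this package models:
5-7-year-olds whose cingulate PAF rises with age by 0.053 Hz/month in the
ASD group only, SRS autistic-trait t-scores of 67.6 +/- 14.3 (ASD) versus
46.4 +/- 6.4 (TD), and K-ABC cognitive scores near the population mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import atlas
from .spectral import PowerSpectrum

GROUPS = ("ASD", "TD")


def _default_paf_baseline() -> dict[str, float]:
    # Child-typical alpha near 9 Hz; posterior (occipital/temporal) regions
    # sit slightly lower than the cingulate reference.
    base = {"cingulate": 9.0, "frontal": 8.9, "parietal": 8.9,
            "occipital": 8.6, "temporal": 8.6}
    out = {f"{h} {l}": base[l] for h in atlas.HEMISPHERES for l in atlas.LOBES}
    out["unassigned"] = 8.8
    return out


def _default_age_slope() -> dict[tuple[str, str], float]:
    # Hz per month of age, centered at the group mean age.  Only the ASD
    # cingulate regions carry a positive developmental slope by default.
    slopes = {(r, g): 0.0 for r in list(atlas.REGIONS) + ["unassigned"]
              for g in GROUPS}
    slopes[("left cingulate", "ASD")] = 0.053
    slopes[("right cingulate", "ASD")] = 0.053
    return slopes


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Generative parameters for one synthetic power spectrum.

    Power at frequency f (Hz) is

        10 ** (offset - exponent * log10 f + eps)
            * (1 + peak_amplitude * exp(-(f - peak_center)^2 / (2 peak_width^2)))

    with eps ~ N(0, noise_sd^2) drawn independently per bin.  Both the noise
    and the alpha peak ride multiplicatively on the aperiodic power law
    (equivalently, additively in the log-power domain where the 1/f line is
    fitted), so power stays strictly positive and the exponentiated residual
    of a noiseless spectrum is exactly ``1 + peak_amplitude * gaussian`` --
    the quantity the peak fit parameterizes.  ``peak_amplitude`` is thus the
    peak's power relative to the local aperiodic level (1.0 doubles it).
    """

    aperiodic_offset: float = 1.0
    aperiodic_exponent: float = 1.5
    peak_amplitude: float = 1.0
    peak_center: float = 9.0
    peak_width: float = 1.0
    noise_sd: float = 0.05
    freq_min: float = 1.0
    freq_max: float = 55.0
    freq_step: float = 0.2

    def __post_init__(self):
        if self.freq_min <= 0 or self.freq_step <= 0:
            raise ValueError("freq_min and freq_step must be positive")
        if self.freq_min >= self.freq_max:
            raise ValueError("freq_min must be below freq_max")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic exponent must be >= 0")
        if self.peak_amplitude < 0 or self.peak_width <= 0:
            raise ValueError("peak amplitude >= 0 and width > 0 required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def freqs(self) -> np.ndarray:
        n = int(round((self.freq_max - self.freq_min) / self.freq_step)) + 1
        return self.freq_min + self.freq_step * np.arange(n)


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters for a two-group synthetic cohort.

    Each subject receives a diagnosis, sex, an age drawn uniformly over the
    group's range (months), SRS total and subscale t-scores, K-ABC MPS and
    ACH scores, and one synthetic spectrum per Desikan-Killiany parcel.  The
    true alpha-peak center of a parcel is

        baseline[region] + age_slope[region, group] * (age - group mean age)
            + subject effect + parcel jitter

    and a group-specific fraction of parcels gets peak amplitude zero (no
    alpha peak, hence no distinct PAF downstream).
    """

    n_asd: int = 19
    n_td: int = 24
    age_range: dict = field(
        default_factory=lambda: {"ASD": (60, 89), "TD": (60, 91)})
    p_male: dict = field(
        default_factory=lambda: {"ASD": 13 / 19, "TD": 14 / 24})
    srs_mean: dict = field(default_factory=lambda: {"ASD": 67.6, "TD": 46.4})
    srs_sd: dict = field(default_factory=lambda: {"ASD": 14.3, "TD": 6.4})
    subscale_jitter_sd: float = 4.0
    mps_mean: dict = field(default_factory=lambda: {"ASD": 103.1, "TD": 115.4})
    mps_sd: dict = field(default_factory=lambda: {"ASD": 16.7, "TD": 12.4})
    ach_mean: dict = field(default_factory=lambda: {"ASD": 98.0, "TD": 107.4})
    ach_sd: dict = field(default_factory=lambda: {"ASD": 17.8, "TD": 13.7})
    epoch_mean: dict = field(default_factory=lambda: {"ASD": 38.6, "TD": 42.3})
    epoch_sd: dict = field(default_factory=lambda: {"ASD": 8.1, "TD": 8.0})
    epoch_range: dict = field(
        default_factory=lambda: {"ASD": (20, 52), "TD": (24, 52)})
    paf_baseline: dict = field(default_factory=_default_paf_baseline)
    age_slope: dict = field(default_factory=_default_age_slope)
    subject_sd: float = 0.45
    parcel_sd: float = 0.3
    invalid_peak_rate: dict = field(
        default_factory=lambda: {"ASD": 0.05, "TD": 0.02})
    spectrum: SpectrumSimConfig = field(default_factory=SpectrumSimConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_asd < 1 or self.n_td < 1:
            raise ValueError("group sizes must be >= 1")
        if self.subject_sd < 0 or self.parcel_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for g in GROUPS:
            if not 0 <= self.invalid_peak_rate[g] <= 1:
                raise ValueError("invalid_peak_rate must be in [0, 1]")
            lo, hi = self.age_range[g]
            if lo > hi:
                raise ValueError("age range must satisfy lo <= hi")
        known = set(list(atlas.REGIONS) + ["unassigned"])
        unknown = set(self.paf_baseline) - known
        unknown |= {r for (r, _g) in self.age_slope} - known
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    def group_mean_age(self, group: str) -> float:
        lo, hi = self.age_range[group]
        return (lo + hi) / 2.0


def simulate_spectrum(
    config: SpectrumSimConfig,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    parcel: str = "sim",
) -> PowerSpectrum:
    """Draw one synthetic power spectrum on the configured grid."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    f = config.freqs
    eps = rng.normal(0.0, config.noise_sd, size=f.size) if config.noise_sd > 0 \
        else np.zeros(f.size)
    aperiodic = 10.0 ** (
        config.aperiodic_offset
        - config.aperiodic_exponent * np.log10(f)
        + eps
    )
    bump = 1.0 + config.peak_amplitude * np.exp(
        -((f - config.peak_center) ** 2) / (2.0 * config.peak_width**2)
    )
    return PowerSpectrum(subject_id=subject_id, parcel=parcel,
                         freqs=f, power=aperiodic * bump)


def simulate_timeseries(
    config: SpectrumSimConfig,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    parcel: str = "sim",
):
    """Colored noise whose expected PSD follows the configured spectrum.

    White Gaussian noise is shaped in the frequency domain by the square
    root of the target PSD (aperiodic power law plus Gaussian alpha bump),
    which gives exact control of the expected Welch spectrum.  The DC
    component is zeroed.
    """
    from .spectral import RegionalTimeSeries

    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n_float = duration_s * fs
    n = int(round(n_float))
    if n < 1 or abs(n_float - n) > 1e-9:
        raise ValueError("duration_s * fs must be a positive integer")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(f)
    pos = f > 0
    target[pos] = 10.0 ** (
        config.aperiodic_offset - config.aperiodic_exponent * np.log10(f[pos])
    )
    target *= 1.0 + config.peak_amplitude * np.exp(
        -((f - config.peak_center) ** 2) / (2.0 * config.peak_width**2)
    )
    target[0] = 0.0
    # unit-variance white noise has one-sided density 2/fs
    H = np.sqrt(target * fs / 2.0)
    x = np.fft.irfft(W * H, n=n)
    return RegionalTimeSeries(subject_id=subject_id, parcel=parcel,
                              fs=fs, samples=x)


def _simulate_subjects(config: CohortSimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in (("ASD", config.n_asd), ("TD", config.n_td)):
        lo, hi = config.age_range[group]
        for i in range(n):
            sid = f"{group.lower()}{i + 1:03d}"
            srs = rng.normal(config.srs_mean[group], config.srs_sd[group])
            subs = srs + rng.normal(0.0, config.subscale_jitter_sd, size=5)
            e_lo, e_hi = config.epoch_range[group]
            epochs = int(np.clip(
                round(rng.normal(config.epoch_mean[group],
                                 config.epoch_sd[group])), e_lo, e_hi))
            rows.append({
                "subject_id": sid,
                "group": group,
                "sex": "M" if rng.random() < config.p_male[group] else "F",
                "age_months": int(rng.integers(lo, hi + 1)),
                "srs_total": round(srs, 1),
                "srs_awareness": round(subs[0], 1),
                "srs_cognition": round(subs[1], 1),
                "srs_communication": round(subs[2], 1),
                "srs_motivation": round(subs[3], 1),
                "srs_mannerism": round(subs[4], 1),
                "mps": round(rng.normal(config.mps_mean[group],
                                        config.mps_sd[group]), 1),
                "ach": round(rng.normal(config.ach_mean[group],
                                        config.ach_sd[group]), 1),
                "epoch_count": epochs,
            })
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortSimConfig | None = None,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Generate a full synthetic cohort: metadata plus per-parcel spectra.

    Returns ``(metadata, spectra)`` where ``metadata`` has one row per
    subject and ``spectra`` is a long table (subject_id, parcel, freq_hz,
    power) with one spectrum per subject x 68 parcels.  With
    ``return_truth=True`` a third frame carries the generative truth per
    parcel (region, true peak center, whether a peak was planted) for
    parameter-recovery tests.

    Identical config and seed give bit-identical output.
    """
    config = config or CohortSimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    mapping = atlas.load_mapping()
    parcels = list(atlas.DK_PARCELS_68)
    regions = [mapping.region_of(p) or "unassigned" for p in parcels]

    meta = _simulate_subjects(config, rng)
    n_subj = len(meta)
    n_parcel = len(parcels)
    f = config.spectrum.freqs
    n_freq = f.size

    subj_effect = rng.normal(0.0, config.subject_sd, size=n_subj)

    centers = np.empty((n_subj, n_parcel))
    has_peak = np.empty((n_subj, n_parcel), dtype=bool)
    for i, row in enumerate(meta.itertuples()):
        age_dev = row.age_months - config.group_mean_age(row.group)
        for j, region in enumerate(regions):
            centers[i, j] = (
                config.paf_baseline[region]
                + config.age_slope[(region, row.group)] * age_dev
                + subj_effect[i]
            )
        has_peak[i] = rng.random(n_parcel) >= config.invalid_peak_rate[row.group]
        centers[i] += rng.normal(0.0, config.parcel_sd, size=n_parcel)

    sp = config.spectrum
    eps = (rng.normal(0.0, sp.noise_sd, size=(n_subj * n_parcel, n_freq))
           if sp.noise_sd > 0 else np.zeros((n_subj * n_parcel, n_freq)))
    aperiodic = 10.0 ** (
        sp.aperiodic_offset - sp.aperiodic_exponent * np.log10(f)[None, :]
        + eps
    )
    amp = np.where(has_peak.ravel(), sp.peak_amplitude, 0.0)
    bump = 1.0 + amp[:, None] * np.exp(
        -((f[None, :] - centers.ravel()[:, None]) ** 2)
        / (2.0 * sp.peak_width**2)
    )
    power = aperiodic * bump

    spectra = pd.DataFrame({
        "subject_id": np.repeat(meta["subject_id"].to_numpy(),
                                n_parcel * n_freq),
        "parcel": np.tile(np.repeat(parcels, n_freq), n_subj),
        "freq_hz": np.tile(f, n_subj * n_parcel),
        "power": power.ravel(),
    })

    if not return_truth:
        return meta, spectra
    truth = pd.DataFrame({
        "subject_id": np.repeat(meta["subject_id"].to_numpy(), n_parcel),
        "parcel": np.tile(parcels, n_subj),
        "region": np.tile(regions, n_subj),
        "true_center_hz": centers.ravel(),
        "has_peak": has_peak.ravel(),
    })
    return meta, spectra, truth
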