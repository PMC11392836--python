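"""Peak alpha frequency (PAF) estimation from power spectra.

The estimator removes the aperiodic 1/f background and parameterizes the
alpha peak in four steps:

1. log10-transform frequency and power over the 1-55 Hz fit range;
2. fit a line by robust (Huber, tuning constant 1.35) regression of log
   power on log frequency -- the robust loss keeps narrowband oscillatory
   peaks from dragging the background fit;
3. subtract the line, exponentiate the residual, and isolate the 7-13 Hz
   alpha band (endpoints inclusive on the discrete grid);
4. least-squares fit a Gaussian ``1 + a*exp(-(f-mu)^2 / (2*sigma^2))`` to
   the band residual.  The vertex ``mu`` is the PAF.

A fit whose vertex lands outside the alpha band, fails to converge, or has
non-positive amplitude marks the parcel as having no distinct PAF; such
parcels are excluded from regional averaging downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .spectral import PowerSpectrum

#: Consistency factor making the median absolute deviation an unbiased
#: estimate of the Gaussian standard deviation.
MAD_CONSISTENCY = 0.6745

REJECT_REASONS = (
    "outside_band", "no_convergence", "non_positive_amplitude",
    "empty_residual",
)

#: Amplitudes at or below this are treated as "no peak" rather than a
#: genuine oscillation; keeps exactly-flat residuals from passing validity.
AMPLITUDE_FLOOR = 1e-8


@dataclass(frozen=True)
class BandConfig:
    """Frequency ranges for background fitting and alpha isolation."""

    fit_range: tuple[float, float] = (1.0, 55.0)
    alpha_band: tuple[float, float] = (7.0, 13.0)

    def __post_init__(self):
        flo, fhi = self.fit_range
        alo, ahi = self.alpha_band
        if not (flo < fhi and alo < ahi):
            raise ValueError("band bounds must satisfy lower < upper")
        if not (flo <= alo and ahi <= fhi):
            raise ValueError("alpha band must be nested inside the fit range")
        if flo <= 0:
            raise ValueError("fit range must be strictly positive (log scale)")


@dataclass
class AperiodicFit:
    """Line fitted to log10 power vs log10 frequency (the 1/f trend)."""

    intercept: float
    slope: float
    tuning_constant: float = 1.35
    n_iterations: int = 0
    converged: bool = True

    def predict_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log10(freqs)


@dataclass
class AlphaPeakFit:
    """Gaussian alpha-peak parameterization; ``center`` is the PAF in Hz."""

    amplitude: float
    center: float
    width: float
    valid: bool
    reject_reason: str | None = None

    def __post_init__(self):
        if self.reject_reason is not None and self.reject_reason not in REJECT_REASONS:
            raise ValueError(f"unknown reject reason {self.reject_reason!r}")
        if self.valid and self.reject_reason is not None:
            raise ValueError("valid fits carry no reject reason")


def _floor_power(power: np.ndarray) -> np.ndarray:
    """Replace non-positive power bins so the log transform is defined.

    Zeros (possible in degenerate synthetic inputs) are floored at 1e-6
    times the smallest positive bin.
    """
    if np.all(power > 0):
        return power
    positive = power[power > 0]
    if positive.size == 0:
        raise ValueError("spectrum has no positive power in the fit range")
    return np.where(power > 0, power, positive.min() * 1e-6)


def huber_line_fit_batch(
    x: np.ndarray,
    Y: np.ndarray,
    tuning_constant: float = 1.35,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Huber M-estimated straight lines for many series sharing one abscissa.

    Iteratively reweighted least squares: residuals are standardized by the
    MAD-based scale re-estimated each iteration, weights are 1 inside the
    tuning constant and ``c/|u|`` outside, and iteration stops when no
    coefficient moves by more than ``tol``.  Rows whose residual scale
    collapses to zero (exact line) converge immediately.

    Parameters
    ----------
    x : (m,) abscissa shared by all rows.
    Y : (n, m) one series per row.

    Returns
    -------
    intercepts, slopes, n_iterations, converged : (n,) arrays.
    """
    x = np.asarray(x, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    n, m = Y.shape
    if m < 3:
        raise ValueError("need at least 3 points for a robust line fit")

    xx = x * x
    # OLS start
    sx, sxx = x.sum(), xx.sum()
    det0 = m * sxx - sx * sx
    sy = Y.sum(axis=1)
    sxy = Y @ x
    slope = (m * sxy - sx * sy) / det0
    intercept = (sxx * sy - sx * sxy) / det0

    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    c = tuning_constant

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        r = Y[idx] - (intercept[idx, None] + slope[idx, None] * x)
        med = np.median(r, axis=1, keepdims=True)
        scale = np.median(np.abs(r - med), axis=1) / MAD_CONSISTENCY
        exact = scale < 1e-12
        converged[idx[exact]] = True
        active[idx[exact]] = False
        idx = idx[~exact]
        if idx.size == 0:
            break
        r = r[~exact]
        u = np.abs(r) / scale[~exact, None]
        w = np.where(u <= c, 1.0, c / np.maximum(u, 1e-300))

        Yi = Y[idx]
        s0 = w.sum(axis=1)
        s1 = w @ x
        s2 = w @ xx
        t0 = (w * Yi).sum(axis=1)
        t1 = (w * Yi) @ x
        det = s0 * s2 - s1 * s1
        new_slope = (s0 * t1 - s1 * t0) / det
        new_intercept = (s2 * t0 - s1 * t1) / det

        delta = np.maximum(
            np.abs(new_slope - slope[idx]), np.abs(new_intercept - intercept[idx])
        )
        slope[idx] = new_slope
        intercept[idx] = new_intercept
        n_iter[idx] += 1
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    return intercept, slope, n_iter, converged


def fit_aperiodic(
    spec: PowerSpectrum,
    cfg: BandConfig = BandConfig(),
    tuning_constant: float = 1.35,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> AperiodicFit:
    """Fit the 1/f background line in log10-log10 coordinates.

    Regresses log10(power) on log10(frequency) over the fit range using
    Huber robust regression with the given tuning constant.
    """
    mask = spec.band_mask(*cfg.fit_range)
    if mask.sum() < 3:
        raise ValueError("need at least 3 bins inside the fit range")
    f = spec.freqs[mask]
    p = _floor_power(spec.power[mask])
    intercept, slope, n_iter, conv = huber_line_fit_batch(
        np.log10(f), np.log10(p)[None, :], tuning_constant, max_iter, tol
    )
    return AperiodicFit(
        intercept=float(intercept[0]), slope=float(slope[0]),
        tuning_constant=tuning_constant, n_iterations=int(n_iter[0]),
        converged=bool(conv[0]),
    )


def detrend_spectrum(
    spec: PowerSpectrum,
    fit: AperiodicFit,
    cfg: BandConfig = BandConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the fitted 1/f line from the log10 spectrum.

    Returns ``(freqs, residual)`` over the fit range, where
    ``residual(f) = log10 power(f) - (intercept + slope * log10 f)``.
    """
    if not fit.converged:
        raise ValueError("aperiodic fit did not converge; residual undefined")
    mask = spec.band_mask(*cfg.fit_range)
    f = spec.freqs[mask]
    p = _floor_power(spec.power[mask])
    return f, np.log10(p) - fit.predict_log10(f)


def isolate_alpha(
    freqs: np.ndarray,
    residual: np.ndarray,
    cfg: BandConfig = BandConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentiate the residual and restrict it to the alpha band.

    Band endpoints are inclusive on the discrete grid; the returned values
    are ``10**residual`` so a flat (peak-free) residual sits at 1.
    """
    lo, hi = cfg.alpha_band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return freqs[mask], 10.0 ** residual[mask]


def _gaussian(f, a, mu, sigma):
    return 1.0 + a * np.exp(-((f - mu) ** 2) / (2.0 * sigma**2))


def _gaussian_free(f, a, mu, sigma, baseline):
    return baseline + a * np.exp(-((f - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_peak(
    band_freqs: np.ndarray,
    band_values: np.ndarray,
    alpha_band: tuple[float, float] = (7.0, 13.0),
    free_baseline: bool = False,
    mu_bounds: tuple[float, float] = (5.0, 15.0),
    sigma_bounds: tuple[float, float] = (0.1, 6.0),
) -> AlphaPeakFit:
    """Least-squares Gaussian fit to the exponentiated alpha-band residual.

    The baseline is fixed at 1 (the null level of an exponentiated residual)
    unless ``free_baseline`` is set.  The vertex ``mu`` is allowed to roam
    beyond the alpha band during optimization so that the exclusion rule --
    a vertex outside the band means no distinct PAF -- can actually fire.
    """
    band_freqs = np.asarray(band_freqs, float)
    band_values = np.asarray(band_values, float)
    if band_freqs.size == 0:
        return AlphaPeakFit(np.nan, np.nan, np.nan, False, "empty_residual")
    if band_freqs.size < 4:
        raise ValueError("need at least 4 bins in the alpha band")
    if not free_baseline and np.max(band_values) - 1.0 <= 0.0:
        # no bin above the null level: nothing to parameterize
        return AlphaPeakFit(0.0, np.nan, np.nan, False,
                            "non_positive_amplitude")

    i0 = int(np.argmax(band_values))
    a0 = max(float(band_values[i0]) - 1.0, 1e-3)
    mu0 = float(np.clip(band_freqs[i0], *mu_bounds))
    p0 = [a0, mu0, 1.0]
    lower = [0.0, mu_bounds[0], sigma_bounds[0]]
    upper = [np.inf, mu_bounds[1], sigma_bounds[1]]
    model = _gaussian
    if free_baseline:
        p0 = p0 + [1.0]
        lower = lower + [-np.inf]
        upper = upper + [np.inf]
        model = _gaussian_free

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                model, band_freqs, band_values, p0=p0,
                bounds=(lower, upper), maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return AlphaPeakFit(np.nan, np.nan, np.nan, False, "no_convergence")

    a, mu, sigma = float(popt[0]), float(popt[1]), float(popt[2])
    if not np.all(np.isfinite(popt)):
        return AlphaPeakFit(np.nan, np.nan, np.nan, False, "no_convergence")
    if a <= AMPLITUDE_FLOOR:
        return AlphaPeakFit(a, mu, sigma, False, "non_positive_amplitude")
    lo, hi = alpha_band
    if not (lo - 1e-12 <= mu <= hi + 1e-12):
        return AlphaPeakFit(a, mu, sigma, False, "outside_band")
    return AlphaPeakFit(a, mu, sigma, True, None)


def estimate_paf(
    spec: PowerSpectrum,
    cfg: BandConfig = BandConfig(),
    tuning_constant: float = 1.35,
    free_baseline: bool = False,
) -> AlphaPeakFit:
    """End-to-end PAF estimate: 1/f removal, alpha isolation, Gaussian fit."""
    fit = fit_aperiodic(spec, cfg, tuning_constant)
    if not fit.converged:
        return AlphaPeakFit(np.nan, np.nan, np.nan, False, "no_convergence")
    freqs, residual = detrend_spectrum(spec, fit, cfg)
    band_f, band_v = isolate_alpha(freqs, residual, cfg)
    if band_f.size == 0:
        return AlphaPeakFit(np.nan, np.nan, np.nan, False, "empty_residual")
    return fit_gaussian_peak(band_f, band_v, cfg.alpha_band,
                             free_baseline=free_baseline)


def _lm_gaussian_batch(
    f: np.ndarray,
    Y: np.ndarray,
    mu_bounds: tuple[float, float] = (5.0, 15.0),
    sigma_bounds: tuple[float, float] = (0.1, 6.0),
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Levenberg-Marquardt Gaussian fits for many band residuals at once.

    Fits ``1 + a * exp(-(f - mu)^2 / (2 sigma^2))`` to every row of ``Y``
    by damped Gauss-Newton with parameters projected into their bounds after
    each accepted step.  Returns ``(params, converged)`` with ``params`` of
    shape (n, 3) ordered (a, mu, sigma).  Rows that fail to converge should
    be re-fit with the scalar optimizer.
    """
    Y = np.atleast_2d(Y)
    n, m = Y.shape
    i0 = np.argmax(Y, axis=1)
    a = np.maximum(Y[np.arange(n), i0] - 1.0, 1e-3)
    mu = np.clip(f[i0], *mu_bounds)
    sigma = np.full(n, 1.0)
    lam = np.full(n, 1e-3)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)

    idx_all = np.arange(n)
    for _ in range(max_iter):
        idx = idx_all[active]
        if idx.size == 0:
            break
        ai, mui, si = a[idx], mu[idx], sigma[idx]
        ei = np.exp(-((f[None, :] - mui[:, None]) ** 2)
                    / (2.0 * si[:, None] ** 2))
        ri = 1.0 + ai[:, None] * ei - Y[idx]
        ci = (ri * ri).sum(axis=1)
        d = f[None, :] - mui[:, None]
        J = np.stack([
            ei,
            ai[:, None] * ei * d / si[:, None] ** 2,
            ai[:, None] * ei * d * d / si[:, None] ** 3,
        ], axis=2)                                   # (k, m, 3)
        JtJ = np.einsum("kmi,kmj->kij", J, J)
        Jtr = np.einsum("kmi,km->ki", J, ri)
        # Marquardt damping: lam * diag(JtJ) added to the diagonal
        A = JtJ.copy()
        diag = np.maximum(np.diagonal(JtJ, axis1=1, axis2=2), 1e-12)
        A[:, np.arange(3), np.arange(3)] += lam[idx, None] * diag
        try:
            delta = np.linalg.solve(A, -Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([
                np.linalg.lstsq(A[k], -Jtr[k], rcond=None)[0]
                for k in range(idx.size)
            ])
        a_new = np.maximum(ai + delta[:, 0], 0.0)
        mu_new = np.clip(mui + delta[:, 1], *mu_bounds)
        s_new = np.clip(si + delta[:, 2], *sigma_bounds)
        e2 = np.exp(-((f[None, :] - mu_new[:, None]) ** 2)
                    / (2.0 * s_new[:, None] ** 2))
        r2 = 1.0 + a_new[:, None] * e2 - Y[idx]
        c2 = (r2 * r2).sum(axis=1)
        better = c2 <= ci
        step = np.max(np.abs(delta), axis=1)
        a[idx[better]] = a_new[better]
        mu[idx[better]] = mu_new[better]
        sigma[idx[better]] = s_new[better]
        lam[idx[better]] = np.maximum(lam[idx[better]] / 3.0, 1e-12)
        lam[idx[~better]] = np.minimum(lam[idx[~better]] * 5.0, 1e8)
        done = better & ((step < 1e-8) | (np.abs(ci - c2) < tol * (1 + ci)))
        stuck = (~better) & (lam[idx] >= 1e8)
        converged[idx[done]] = True
        active[idx[done | stuck]] = False

    params = np.stack([a, mu, sigma], axis=1)
    return params, converged


def estimate_paf_table(
    spectra: pd.DataFrame,
    cfg: BandConfig = BandConfig(),
    tuning_constant: float = 1.35,
    free_baseline: bool = False,
) -> pd.DataFrame:
    """Vectorized PAF estimation for a long table of spectra.

    ``spectra`` has columns ``subject_id, parcel, freq_hz, power`` with every
    (subject, parcel) series on the same frequency grid.  The aperiodic fits
    run as one batched Huber IRLS; the Gaussian peak fits run per series.

    Returns one row per (subject, parcel) with the peak parameters, validity
    flag, reject reason and the aperiodic line coefficients.
    """
    freqs = np.sort(spectra["freq_hz"].unique())
    wide = spectra.pivot_table(
        index=["subject_id", "parcel"], columns="freq_hz", values="power",
        sort=True,
    )
    if wide.isna().any().any():
        raise ValueError("all spectra must share the same frequency grid")
    keys = wide.index
    P = wide.to_numpy()

    lo, hi = cfg.fit_range
    fmask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    f = freqs[fmask]
    if f.size < 3:
        raise ValueError("need at least 3 bins inside the fit range")
    Pfit = P[:, fmask].copy()
    # floor non-positive bins per row before logging
    bad = Pfit <= 0
    if bad.any():
        for i in np.flatnonzero(bad.any(axis=1)):
            Pfit[i] = _floor_power(Pfit[i])
    logf = np.log10(f)
    logP = np.log10(Pfit)

    intercept, slope, n_iter, conv = huber_line_fit_batch(
        logf, logP, tuning_constant
    )
    residual = logP - (intercept[:, None] + slope[:, None] * logf)

    alo, ahi = cfg.alpha_band
    amask = (f >= alo - 1e-9) & (f <= ahi + 1e-9)
    band_f = f[amask]

    # Vectorized Levenberg-Marquardt handles the bulk; rows it cannot
    # settle are re-fit with the scalar curve_fit path (identical model).
    use_batch = band_f.size >= 4 and not free_baseline
    if use_batch:
        band_Y = 10.0 ** residual[:, amask]
        params, lm_conv = _lm_gaussian_batch(band_f, band_Y)

    def _classify(i: int) -> AlphaPeakFit:
        if np.max(band_Y[i]) - 1.0 <= 0.0:
            return AlphaPeakFit(0.0, np.nan, np.nan, False,
                                "non_positive_amplitude")
        a, mu, sigma = params[i]
        if a <= AMPLITUDE_FLOOR:
            return AlphaPeakFit(a, mu, sigma, False, "non_positive_amplitude")
        if not (alo - 1e-12 <= mu <= ahi + 1e-12):
            return AlphaPeakFit(a, mu, sigma, False, "outside_band")
        return AlphaPeakFit(a, mu, sigma, True, None)

    records = []
    for i, (sid, parcel) in enumerate(keys):
        if not conv[i]:
            pk = AlphaPeakFit(np.nan, np.nan, np.nan, False, "no_convergence")
        elif band_f.size == 0:
            pk = AlphaPeakFit(np.nan, np.nan, np.nan, False, "empty_residual")
        elif use_batch and lm_conv[i]:
            pk = _classify(i)
        else:
            pk = fit_gaussian_peak(
                band_f, 10.0 ** residual[i, amask], cfg.alpha_band,
                free_baseline=free_baseline,
            )
        records.append({
            "subject_id": sid, "parcel": parcel,
            "paf_hz": pk.center if pk.valid else np.nan,
            "amplitude": pk.amplitude, "width_hz": pk.width,
            "valid": pk.valid, "reject_reason": pk.reject_reason or "",
            "aperiodic_slope": slope[i], "aperiodic_intercept": intercept[i],
        })
    return pd.DataFrame.from_records(records)
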