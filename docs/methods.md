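# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `alphapeak`.  It is written for users who need to judge
whether the defaults fit their data and what the test suite does and does
not establish.

## Scope

The pipeline starts at parcel-level source time series (or precomputed
spectra).  Everything upstream — acquisition, filtering, artifact
rejection, source reconstruction — is assumed done.  The package covers:
spectral estimation, PAF parameterization, regional aggregation, and the
group-level statistics.

## Spectral estimation

Recordings are cut into consecutive non-overlapping 5-s segments; the
trailing remainder is dropped.  Subjects with fewer than 10 complete
segments (50 s of data) are rejected with an error carrying the achieved
count, so exclusions are loggable.  The PSD is estimated with Welch's
method: 5-s Hamming windows slid with 80% overlap over the concatenation
of the accepted segments, mean removal per window, one-sided density
scaling.  A 5-s window at 500 Hz gives the 0.2 Hz bin spacing the peak
fit expects.

Two readings of "5-s epochs with 80% overlap" are defensible: windows
sliding across the whole record, or one periodogram per epoch.  The
default slides across the concatenation (more averaging; windows may
straddle segment junctions, acceptable because segments are contiguous
stretches of one recording); `respect_segment_boundaries=True` switches to
per-segment periodograms.  Only the default preserves both the 0.2 Hz
resolution and the stated overlap.

Density scaling is immaterial downstream: PAF uses log-slopes and
residual ratios, and relative alpha power is a ratio, so the scaling
convention cancels.

Relative alpha power = sum of power over bins in 7–13 Hz divided by the
sum over 1–55 Hz, endpoints inclusive on the discrete grid.

## PAF parameterization

The estimator follows the aperiodic-plus-peak decomposition family
(log-log linear background plus Gaussian peak):

1. `log10 P` vs `log10 f` over 1–55 Hz, Huber M-estimation with tuning
   constant 1.35.  IRLS details (not externally prescribed, chosen as
   standard robust-regression practice): residual scale re-estimated each
   iteration as MAD/0.6745, weights `min(1, c/|u|)` on standardized
   residuals, convergence when no coefficient moves more than 1e−8,
   maximum 200 iterations, OLS start.  A zero-MAD (exact line) fit
   converges immediately.  The implementation is a vectorized batch IRLS
   (all spectra share the frequency grid); tests pin it against
   statsmodels RLM with the same Huber norm.
2. Residual = `log10 P` minus the fitted line; exponentiated (`10^r`) and
   restricted to 7–13 Hz inclusive.
3. Gaussian fit `1 + a·exp(−(f−μ)²/2σ²)` by least squares.  The baseline
   is fixed at 1 because the null level of an exponentiated residual is
   `10^0`; a free-baseline variant is available via `free_baseline=True`.
   Initialization: `μ0` = argmax of the band residual, `a0` = max − 1
   (floored at 1e−3), `σ0` = 1 Hz.  Bounds: `a ≥ 0`, `μ ∈ [5, 15]`,
   `σ ∈ [0.1, 6]` Hz.  The vertex must be free to leave the alpha band so
   the exclusion rule can fire; validity is then checked on [7, 13].
4. Validity: a fit is a distinct PAF iff the optimizer converged, `a`
   exceeds a 1e−8 floor, and `7 ≤ μ ≤ 13`.  Reject reasons are recorded
   (`outside_band`, `no_convergence`, `non_positive_amplitude`,
   `empty_residual`).  A band residual with no bin above 1 is classified
   `non_positive_amplitude` without fitting — there is no peak to
   parameterize, and letting the optimizer run on an exactly flat input
   produces an arbitrary vertex.

Numerical details: log base 10 throughout (slope and PAF are
base-invariant; the intercept convention is log10 power at 1 Hz).
Non-positive power bins — possible in synthetic edge cases — are floored
at 1e−6 times the smallest positive bin before logging.  Batch estimation
uses a vectorized damped Gauss–Newton (Levenberg–Marquardt with projected
bounds) across all spectra; rows it cannot settle fall back to
`scipy.optimize.curve_fit`.  Tests assert the two paths agree to 1e−3 Hz
and that the fitted vertex matches a dense brute-force grid search within
0.05 Hz.

## Atlas aggregation

The shipped mapping assigns the 68 Desikan-Killiany parcels to
{left, right} × {cingulate, frontal, occipital, parietal, temporal}
(4 cingulate, 11 frontal, 4 occipital, 5 parietal, 9 temporal parcels per
hemisphere).  The insula belongs to none of the five lobes in this scheme;
rather than invent anatomy the default marks it `unassigned` and excludes
it from regional means (66 of 68 parcels mapped; validity bookkeeping by
diagnosis still counts all 68).  A user mapping file can absorb it into a
lobe instead.  Regional PAF is the unweighted arithmetic mean over valid
parcels; a region with no valid parcel is missing, and valid/total counts
are carried so exclusion rates are auditable.

## Statistics

- Two-group comparisons: pooled-variance Student t (Welch available),
  differences oriented second-minus-first group so (ASD, TD) argument
  order reports TD−ASD.  Chi-square tests take an explicit
  continuity-correction flag — the uncorrected and Yates statistics both
  appear in practice for 2×2 tables and no silent default is imposed
  beyond `off`.
- Region-wise models: OLS with HC1 sandwich errors by default (HC0/HC3
  selectable); t inference on `n − p` residual degrees of freedom.  HC1
  matches the convention of common commercial statistics packages.
- FDR: Benjamini-Hochberg step-up, one family per analysis = the ten
  per-region p-values of that analysis's focal (interaction) term.
  Pooling families across analyses is possible by calling `bh_fdr` on the
  concatenated p-values.
- Missing regional PAFs are handled listwise per region: each region's
  model uses that region's complete cases.
- Mixed model: fixed effects region (reference left cingulate) ×
  diagnosis, random intercept per subject, REML; Wald z inference.  When
  the random-intercept variance collapses (or the fit fails), the model
  falls back to OLS with cluster-robust (by subject) standard errors and
  warns; in the zero-variance limit the fixed effects coincide with OLS,
  which the tests assert.
- SRS subscale exploration is deliberately uncorrected at α = 0.05 and
  flagged as exploratory in the API docs.

## Synthetic cohort generator

The generator defines the study conditions the package is tested under:

- Groups: 19 ASD / 24 TD subjects; ages uniform over 60–89 (ASD) and
  60–91 (TD) months (only the ranges are specified upstream, so uniform is
  assumed); sex ratios 13/19 and 14/24 male.
- Traits: SRS total t-scores N(67.6, 14.3²) vs N(46.4, 6.4²); subscales =
  total + N(0, 4²) jitter; K-ABC MPS N(103.1, 16.7²) vs N(115.4, 12.4²),
  ACH N(98.0, 17.8²) vs N(107.4, 13.7²); epoch counts truncated normals.
- PAF structure: regional baselines near the child-typical 9 Hz
  (posterior regions 0.3–0.4 Hz lower), an ASD-only age slope of
  0.053 Hz/month in both cingulate regions, a shared subject effect
  N(0, 0.45²) Hz and parcel jitter N(0, 0.3²) Hz.  These two SDs are
  conventions — upstream reports imply only the total residual scale
  (≈0.5 Hz at the regional level, which this combination reproduces) —
  and age slopes are applied to age centered at the group mean.
- Spectra: power = `10^(offset − b·log10 f + ε) · (1 + a·G(f; μ, σ))`,
  with ε i.i.d. N(0, 0.05²) per bin.  Both noise and peak are
  multiplicative on the aperiodic law (additive in log-power, where the
  line is fitted): this keeps power positive, and makes the exponentiated
  residual of a noiseless spectrum exactly the `1 + a·G` curve the peak
  stage fits, so generative truth and estimand coincide.  A peak planted
  additively in *linear* power would shift the residual vertex by
  ≈ `b·σ²/μ` (0.15–0.2 Hz) and make "recovery within half a bin"
  unattainable for any estimator of this form.  Default relative
  amplitude 1.0 (the peak doubles local power), width 1 Hz.
- No-peak parcels: a group-specific fraction (5% ASD, 2% TD) gets peak
  amplitude zero.  With log-noise present, a peak-free spectrum is only
  *detected* as invalid when noise does not mimic an in-band bump, so
  realized invalidity rates sit below the planted rates; validity
  percentages quoted in the acceptance output are computed from the
  fixed count bookkeeping, not from noisy detection.
- Time series: white Gaussian noise shaped in the frequency domain by the
  square root of the target PSD (exact expected-PSD control; DC zeroed;
  unit-variance white noise has one-sided density 2/fs).

What the generator does **not** emulate: source leakage and inter-parcel
correlation, non-Gaussian trait distributions, within-subject covariance
structure beyond a single shared offset, multi-peak or knee-shaped
spectra, and nonstationarity.  Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to those real-data features.

## Problem sizes and calibrations in the test suite

Monte-Carlo checks use: 200 seeded spectra for noisy PAF recovery
(±0.3 Hz for ≥95%), 2,000 replicates for the robust-SE type-I calibration
(0.05 ± 0.02 under an error SD doubling across the predictor range) and
for the null-cohort family-wise BH false-flag rate (≤ q + 0.02), and 100
simulated cohorts for interaction-slope CI coverage (≥90%) — the last at
the full spectra→PAF→regions→regression chain.  The BH *detection* check
(both cingulate regions flagged in ≥90% of replicates) runs at a
lower-noise sensitivity condition (subject SD 0.15 Hz): at the default
residual scale the planted slope corresponds to t ≈ 2.9, for which
single-study replication power is near 60% — a property of the effect
size, not of the implementation.

## Known limitations

- Single-Gaussian peak model: bimodal alpha or strong theta/beta peaks
  are not decomposed; the fit reports whichever compromise minimizes
  squared error.
- The aperiodic model has no knee parameter; spectra with a bend inside
  1–55 Hz will bias the line and hence the residual.
- Whether the original analysis fixed the Gaussian baseline at 1, 0, or
  left it free is unknowable from the outside; PAF on clear peaks is
  insensitive, but borderline validity calls can differ between baseline
  conventions (`free_baseline` exposes the alternative).
- The insula assignment and the exact 68→10 grouping are configurable
  precisely because the canonical assignment is ambiguous.
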