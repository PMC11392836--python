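# alphapeak

Peak alpha frequency (PAF) analysis for resting-state MEG/EEG source
spectra, built for developmental group studies: estimate the PAF of every
cortical parcel, aggregate into lobar regions, and test how PAF relates to
diagnosis, age, and behavioral traits.

The package is aimed at researchers who already have parcel-level source
time series (or precomputed power spectra) — for example 68
Desikan-Killiany parcels per subject — and want a tested, reproducible
implementation of the downstream spectral and statistical analysis.  A
seeded synthetic-cohort generator stands in for raw recordings, so every
stage runs and is verifiable without any data download.

## The method

For each subject × parcel power spectrum `P(f)` on a uniform grid
(0.2 Hz resolution from 5-s Welch windows at 500 Hz):

1. **Aperiodic fit.** Regress `log10 P(f)` on `log10 f` over 1–55 Hz with
   Huber robust regression (tuning constant `c = 1.35`, IRLS with
   MAD-estimated scale).  The robust loss keeps the narrowband alpha peak
   from biasing the 1/f background line.
2. **Detrend and isolate.** Subtract the line, exponentiate the residual,
   and keep the alpha band 7–13 Hz (endpoints inclusive).  A peak-free
   residual sits at 1.
3. **Peak fit.** Least-squares fit
   `R(f) = 1 + a·exp(−(f−μ)² / 2σ²)`.
   The vertex `μ` is the PAF.  The fit is *invalid* — no distinct PAF —
   when the vertex falls outside 7–13 Hz, the amplitude is non-positive,
   or the optimizer fails; invalid parcels are excluded downstream.
4. **Aggregate.** Average valid parcel PAFs into ten regions
   ({left, right} × {cingulate, frontal, occipital, parietal, temporal}).
5. **Statistics.** Per region, fit `PAF ~ diagnosis + x + diagnosis·x`
   (x = age in months, SRS total t-score, or K-ABC scores) by OLS with HC1
   sandwich standard errors, applying Benjamini-Hochberg FDR control at
   q = 0.05 across the ten interaction p-values; follow up significant
   interactions with per-group simple regressions.  Region × diagnosis
   contrasts of PAF and relative alpha power use a linear mixed model with
   a per-subject random intercept.

## Worked example

```python
import alphapeak as ap

meta, spectra = ap.simulate_cohort(seed=11)       # 19 ASD + 24 TD subjects
fits = ap.estimate_paf_table(spectra)             # 2,924 parcel spectra
regions = ap.aggregate_regions(fits)
scan = ap.region_interaction_scan(regions, meta, moderator="age_months")
```

Running `python examples/03_cohort_statistics.py` (the same computation)
prints:

```
43 subjects, 2924 parcel spectra, 2905 valid PAFs

region                diagnosis-age interaction (Hz/month)
left cingulate        coef +0.063  t +4.07  p 0.000 *
left frontal          coef +0.006  t +0.34  p 0.736
...
right cingulate       coef +0.060  t +3.20  p 0.003 *
...
```

The default generator plants an ASD-specific age→PAF slope of
0.053 Hz/month in the two cingulate regions only; the starred rows show
the scan recovering exactly those regions after FDR correction, with
coefficient estimates near the planted value.  The other eight regions
stay null.

Each script in `examples/` is a short, self-contained walk-through of one
capability (single-spectrum PAF, Welch estimation, cohort statistics, the
one-call pipeline).  A thin CLI mirrors the stages:

```bash
alphapeak run --seed 7 --out runs/demo    # full pipeline + manifest
alphapeak report runs/demo                # markdown summary tables
```

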