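"""Simulate a cohort and run the region-wise interaction analysis.

Generates the default synthetic cohort (19 ASD + 24 TD children, ages 5-7
years) in which only the cingulate regions carry an ASD-specific age slope
of 0.053 Hz/month, estimates every parcel PAF, aggregates into the ten
lobar regions, and fits the per-region model

    PAF ~ diagnosis + age + diagnosis x age

with HC1 robust standard errors and Benjamini-Hochberg correction across
the ten interaction p-values.
"""

import alphapeak as ap

meta, spectra = ap.simulate_cohort(seed=11)
fits = ap.estimate_paf_table(spectra)
regions = ap.aggregate_regions(fits)

print(f"{len(meta)} subjects, {len(fits)} parcel spectra, "
      f"{int(fits['valid'].sum())} valid PAFs")

scan = ap.region_interaction_scan(regions, meta, moderator="age_months")
print("\nregion                diagnosis-age interaction (Hz/month)")
for region, flagged in zip(scan.fdr.labels, scan.fdr.reject):
    cell = scan.results[region]["diagnosis:age_months"]
    star = " *" if flagged else ""
    print(f"{region:20s}  coef {cell['coef']:+.3f}  t {cell['t']:+.2f}  "
          f"p {cell['p']:.3f}{star}")
print("\n* = significant after Benjamini-Hochberg at q = 0.05.")
print("Only the cingulate rows should be starred: the generator plants the")
print("0.053 Hz/month ASD-only age slope there and nowhere else.")
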