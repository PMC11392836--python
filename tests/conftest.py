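import numpy as np
import pandas as pd
import pytest

import alphapeak as ap
from alphapeak import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (5 ASD + 6 TD) shared across tests; read-only."""
    cfg = ap.CohortSimConfig(n_asd=5, n_td=6, seed=42)
    meta, spectra, truth = ap.simulate_cohort(cfg, return_truth=True)
    return cfg, meta, spectra, truth


@pytest.fixture(scope="session")
def small_parcel_fits(small_cohort):
    _, _, spectra, _ = small_cohort
    return ap.estimate_paf_table(spectra)


def make_metadata(n_asd=19, n_td=24, seed=0):
    """Subject metadata only (no spectra) for statistics-layer tests."""
    cfg = ap.CohortSimConfig(n_asd=n_asd, n_td=n_td, seed=seed)
    rng = np.random.default_rng(seed)
    return cfg, simulate._simulate_subjects(cfg, rng)


def make_region_table(cfg, meta, rng, slopes=None, subject_sd=0.25,
                      region_sd=0.2):
    """Regional PAF table drawn straight from the linear generative model.

    Bypasses the spectral stage: one PAF per subject x region equal to
    baseline + slope * (age - group mean age) + subject effect + noise.
    Used to exercise the regression layer at known truth.
    """
    slopes = slopes or {}
    subj_eff = rng.normal(0.0, subject_sd, size=len(meta))
    rows = []
    for i, row in enumerate(meta.itertuples()):
        age_dev = row.age_months - cfg.group_mean_age(row.group)
        for region in ap.REGIONS:
            slope = slopes.get((region, row.group), 0.0)
            rows.append({
                "subject_id": row.subject_id,
                "region": region,
                "paf_hz": (cfg.paf_baseline[region] + slope * age_dev
                           + subj_eff[i] + rng.normal(0.0, region_sd)),
                "n_valid_parcels": 4,
                "n_total_parcels": 4,
            })
    return pd.DataFrame(rows)
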