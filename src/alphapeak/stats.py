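"""Group comparisons and region-wise regression models.

Implements the statistical layer applied to regional peak alpha frequency
(PAF) tables: pooled-variance t-tests and chi-square tests for group
descriptives, per-region OLS models with heteroscedasticity-robust
(sandwich) standard errors and diagnosis x moderator interactions,
Benjamini-Hochberg false-discovery-rate control across the ten regions,
follow-up per-group regressions, uncorrected SRS-subscale exploration, and
linear mixed models with a per-subject random intercept for region x
diagnosis contrasts.

Conventions fixed throughout: diagnosis is coded ASD=1, TD=0; two-sample
differences are reported as (second group - first group), so calling with
(ASD, TD) summaries reproduces TD-minus-ASD signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

DIAGNOSIS_CODE = {"TD": 0, "ASD": 1}

SRS_SUBSCALES = (
    "srs_awareness", "srs_cognition", "srs_communication",
    "srs_motivation", "srs_mannerism",
)


# ---------------------------------------------------------------------------
# simple two-group tests

def two_sample_t(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
) -> tuple[float, int, float]:
    """Pooled-variance Student t-test from group summaries.

    Returns ``(t, df, p)`` with ``t`` oriented as (mean2 - mean1) / SE and
    ``df = n1 + n2 - 2``.  A zero pooled variance with unequal means yields
    an infinite t (flagged by the caller via ``np.isinf``).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean2 - mean1
    if sp2 == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        return float(t), df, 0.0 if diff != 0 else 1.0
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def two_sample_t_from_samples(
    x1: np.ndarray, x2: np.ndarray, equal_var: bool = True
) -> tuple[float, float, float]:
    """t-test on raw vectors; difference oriented as (x2 - x1)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if equal_var:
        return two_sample_t(len(x1), x1.mean(), x1.std(ddof=1),
                            len(x2), x2.mean(), x2.std(ddof=1))
    res = sps.ttest_ind(x2, x1, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]].

    ``continuity=True`` applies the Yates correction.  Zero row or column
    margins raise.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=continuity)
    return float(chi2), int(dof), float(p)


def chi_square_rxc(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# regression machinery

@dataclass
class RegressionResult:
    """One fitted linear model: coefficients with (robust) inference."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    df_resid: float
    pvalues: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    f_pvalue: float
    rsquared: float
    nobs: int
    se_flavor: str = "HC1"
    use_t: bool = True

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "coef": float(self.coef[i]), "se": float(self.se[i]),
            "t": float(self.tvalues[i]), "p": float(self.pvalues[i]),
            "ci": (float(self.ci_low[i]), float(self.ci_high[i])),
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.coef, "robust_se": self.se,
            "t": self.tvalues, "df": self.df_resid, "p": self.pvalues,
            "ci_lo": self.ci_low, "ci_hi": self.ci_high,
            "f_p": self.f_pvalue, "r2": self.rsquared,
        })


@dataclass
class FDRDecision:
    """Benjamini-Hochberg step-up decision for one family of p-values."""

    pvalues: np.ndarray
    q: float
    reject: np.ndarray
    family: str = ""
    labels: list[str] = field(default_factory=list)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify columns whose removal restores full rank
        dependent = [
            col for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(mat, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; "
                         f"linearly dependent terms: {dependent}")


def fit_ols_robust(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    se_flavor: str = "HC1",
) -> RegressionResult:
    """OLS point estimates with heteroscedasticity-consistent standard errors.

    ``design`` holds the predictor columns (no intercept; one is added).
    Inference uses the t distribution on the residual degrees of freedom,
    n - (number of terms including the intercept).  ``se_flavor`` may be any
    statsmodels HC variant ("HC0", "HC1", "HC3") or "nonrobust".
    """
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    X = X.rename(columns={"const": "intercept"})
    if len(y) <= X.shape[1]:
        raise ValueError("more terms than observations")
    _check_rank(X)
    model = sm.OLS(y, X)
    if se_flavor.lower() == "nonrobust":
        res = model.fit()
    else:
        res = model.fit(cov_type=se_flavor, use_t=True)
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        terms=list(X.columns),
        coef=res.params.to_numpy(),
        se=res.bse.to_numpy(),
        tvalues=res.tvalues.to_numpy(),
        df_resid=float(res.df_resid),
        pvalues=res.pvalues.to_numpy(),
        ci_low=ci[0].to_numpy(),
        ci_high=ci[1].to_numpy(),
        f_pvalue=float(res.f_pvalue),
        rsquared=float(res.rsquared),
        nobs=int(res.nobs),
        se_flavor=se_flavor,
    )


def bh_fdr(pvalues, q: float = 0.05, family: str = "",
           labels: list[str] | None = None) -> FDRDecision:
    """Benjamini-Hochberg step-up rule at FDR level ``q``.

    Rejects every hypothesis with p <= p(k*), where k* is the largest k such
    that the k-th smallest p-value satisfies p(k) <= k*q/m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return FDRDecision(p, q, np.zeros(0, dtype=bool), family, labels or [])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= thresh)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        cutoff = sorted_p[passing[-1]]
        reject = p <= cutoff
    return FDRDecision(p, q, reject, family, labels or [])


# ---------------------------------------------------------------------------
# region-wise analyses

@dataclass
class ScanResult:
    """Per-region interaction models plus the family FDR decision."""

    moderator: str
    results: dict[str, RegressionResult]
    fdr: FDRDecision
    focal_term: str
    skipped: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        frames = []
        for region, res in self.results.items():
            df = res.summary_frame()
            df.insert(0, "region", region)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        flagged = dict(zip(self.fdr.labels, self.fdr.reject))
        out["fdr_reject"] = [
            bool(flagged.get(r, False)) if t == self.focal_term else False
            for r, t in zip(out["region"], out["term"])
        ]
        return out


def _merged_region_frame(region_table: pd.DataFrame,
                         metadata: pd.DataFrame) -> pd.DataFrame:
    df = region_table.merge(metadata, on="subject_id", how="left")
    df["diagnosis"] = df["group"].map(DIAGNOSIS_CODE)
    if df["diagnosis"].isna().any():
        missing = df.loc[df["diagnosis"].isna(), "subject_id"].unique()
        raise ValueError(f"subjects without metadata: {list(missing)[:5]}")
    return df


def region_interaction_scan(
    region_table: pd.DataFrame,
    metadata: pd.DataFrame,
    moderator: str = "age_months",
    outcome: str = "paf_hz",
    q: float = 0.05,
    se_flavor: str = "HC1",
    min_n: int = 6,
) -> ScanResult:
    """Per-region models ``outcome ~ diagnosis + moderator + interaction``.

    Fits one robust-SE OLS model per analysis region on that region's
    complete cases, then applies the Benjamini-Hochberg step-up across the
    regions' interaction p-values (the focal family for one analysis).
    Regions with fewer than ``min_n`` complete cases are skipped and listed
    in the result.
    """
    df = _merged_region_frame(region_table, metadata)
    focal = f"diagnosis:{moderator}"
    results: dict[str, RegressionResult] = {}
    skipped: list[str] = []
    for region, sub in df.groupby("region", sort=True):
        sub = sub.dropna(subset=[outcome, moderator])
        if len(sub) < min_n:
            skipped.append(region)
            continue
        design = pd.DataFrame({
            "diagnosis": sub["diagnosis"].to_numpy(float),
            moderator: sub[moderator].to_numpy(float),
            focal: (sub["diagnosis"] * sub[moderator]).to_numpy(float),
        }, index=sub.index)
        results[region] = fit_ols_robust(sub[outcome], design, se_flavor)
    labels = list(results)
    pvals = [results[r][focal]["p"] for r in labels]
    fdr = bh_fdr(pvals, q=q, family=f"{moderator} interaction", labels=labels)
    return ScanResult(moderator=moderator, results=results, fdr=fdr,
                      focal_term=focal, skipped=skipped)


def per_group_regression(
    region_table: pd.DataFrame,
    metadata: pd.DataFrame,
    region: str,
    group: str,
    predictor: str = "age_months",
    outcome: str = "paf_hz",
    se_flavor: str = "HC1",
) -> RegressionResult:
    """Simple within-group regression ``outcome ~ predictor`` for one region."""
    df = _merged_region_frame(region_table, metadata)
    sub = df[(df["region"] == region) & (df["group"] == group)]
    sub = sub.dropna(subset=[outcome, predictor])
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 usable subjects")
    if sub[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} is constant in {group!r}")
    design = sub[[predictor]].astype(float)
    return fit_ols_robust(sub[outcome], design, se_flavor)


def subscale_scan(
    region_table: pd.DataFrame,
    metadata: pd.DataFrame,
    region: str = "right temporal",
    subscales: tuple[str, ...] = SRS_SUBSCALES,
    group: str | None = "TD",
    outcome: str = "paf_hz",
    se_flavor: str = "HC1",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exploratory per-subscale simple regressions, uncorrected at p < alpha.

    One ``outcome ~ subscale`` model per SRS subscale, within ``group`` (or
    pooled when ``group`` is None), for a single region.  Returns a tidy
    frame with a ``significant`` flag at the uncorrected threshold.
    """
    df = _merged_region_frame(region_table, metadata)
    missing = [s for s in subscales if s not in df.columns]
    if missing:
        raise ValueError(f"missing subscale columns: {missing}")
    sub = df[df["region"] == region]
    if group is not None:
        sub = sub[sub["group"] == group]
    rows = []
    for s in subscales:
        data = sub.dropna(subset=[outcome, s])
        if data[s].nunique() < 2:
            raise ValueError(f"subscale {s!r} is constant")
        res = fit_ols_robust(data[outcome], data[[s]].astype(float),
                             se_flavor)
        cell = res[s]
        rows.append({
            "region": region, "subscale": s, "n": res.nobs,
            "coef": cell["coef"], "robust_se": cell["se"], "t": cell["t"],
            "df": res.df_resid, "p": cell["p"],
            "significant": cell["p"] < alpha,
        })
    return pd.DataFrame(rows)


def fit_lmm_region_diagnosis(
    region_table: pd.DataFrame,
    metadata: pd.DataFrame,
    outcome: str = "paf_hz",
    reference_region: str = "left cingulate",
    reml: bool = True,
) -> RegressionResult:
    """Mixed model ``outcome ~ region * diagnosis`` with a subject intercept.

    Fixed effects are region dummies (reference = ``reference_region``),
    diagnosis, and their interaction; subject enters as a random intercept
    (fit by REML).  Inference is by Wald z.  If the random-effect variance
    is singular or the fit fails, the model falls back to OLS with
    cluster-robust (by subject) standard errors and a warning is emitted.
    """
    df = _merged_region_frame(region_table, metadata).dropna(subset=[outcome])
    if df["region"].nunique() < 2 or df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 regions and 2 subjects")
    formula = (
        f"Q('{outcome}') ~ C(region, Treatment(reference='{reference_region}'))"
        " * diagnosis"
    )

    def _clean(term: str) -> str:
        term = term.replace(
            f"C(region, Treatment(reference='{reference_region}'))", "region")
        return term.replace("[T.", "[").replace("Intercept", "intercept")

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject_id"])
            res = model.fit(reml=reml)
        if not res.converged or not np.isfinite(res.params).all():
            singular = True
        elif float(res.cov_re.iloc[0, 0]) < 1e-10:
            singular = True
    except Exception:
        singular = True

    if singular:
        warnings.warn(
            "random-intercept variance singular or fit failed; "
            "falling back to OLS with cluster-robust SEs", RuntimeWarning)
        ols = smf.ols(formula, df).fit(
            cov_type="cluster",
            cov_kwds={"groups": df["subject_id"]},
            use_t=False,
        )
        ci = ols.conf_int()
        terms = [_clean(t) for t in ols.params.index]
        return RegressionResult(
            terms=terms, coef=ols.params.to_numpy(), se=ols.bse.to_numpy(),
            tvalues=ols.tvalues.to_numpy(), df_resid=float(ols.df_resid),
            pvalues=ols.pvalues.to_numpy(), ci_low=ci[0].to_numpy(),
            ci_high=ci[1].to_numpy(), f_pvalue=float(ols.f_pvalue),
            rsquared=float(ols.rsquared), nobs=int(ols.nobs),
            se_flavor="cluster", use_t=False,
        )

    fe = res.fe_params
    fe_names = list(fe.index)
    bse = res.bse_fe
    z = fe / bse
    p = 2.0 * sps.norm.sf(np.abs(z))
    crit = sps.norm.ppf(0.975)
    return RegressionResult(
        terms=[_clean(t) for t in fe_names],
        coef=fe.to_numpy(), se=bse.to_numpy(), tvalues=z.to_numpy(),
        df_resid=float(res.df_resid), pvalues=np.asarray(p),
        ci_low=(fe - crit * bse).to_numpy(),
        ci_high=(fe + crit * bse).to_numpy(),
        f_pvalue=np.nan, rsquared=np.nan, nobs=int(res.nobs),
        se_flavor="mixed", use_t=False,
    )


# ---------------------------------------------------------------------------
# descriptives

def descriptives_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Group descriptives with the tests used for each row.

    Continuous variables get pooled Student t-tests oriented TD - ASD; sex
    gets an uncorrected chi-square on the male/female counts.
    """
    asd = metadata[metadata["group"] == "ASD"]
    td = metadata[metadata["group"] == "TD"]
    rows = []
    m_asd = int((asd["sex"] == "M").sum())
    m_td = int((td["sex"] == "M").sum())
    chi2, _, p = chi_square_2x2(m_asd, len(asd) - m_asd,
                                m_td, len(td) - m_td, continuity=False)
    rows.append({
        "variable": "sex_pct_male",
        "asd_mean": round(100 * m_asd / len(asd), 1),
        "asd_sd": np.nan,
        "td_mean": round(100 * m_td / len(td), 1),
        "td_sd": np.nan,
        "stat": chi2, "test": "chi2", "p": p,
    })
    for col in ("age_months", "epoch_count", "srs_total", "mps", "ach"):
        if col not in metadata.columns:
            continue
        t, _, p = two_sample_t_from_samples(asd[col], td[col])
        rows.append({
            "variable": col,
            "asd_mean": asd[col].mean(), "asd_sd": asd[col].std(ddof=1),
            "td_mean": td[col].mean(), "td_sd": td[col].std(ddof=1),
            "stat": t, "test": "t", "p": p,
        })
    return pd.DataFrame(rows)
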