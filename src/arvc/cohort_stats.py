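"""Cohort-level analyses over variant calls and clinical covariates.

Covers the downstream battery run on a quantified cohort: the baseline
clinical summary, the AR-expression group comparisons (rank-based,
Benjamini-Hochberg adjusted when pairwise), the univariate screen and
multivariate regression of relative variant expression on clinical
covariates, and the deterministic oncoprint ordering used to display
co-occurrence of variant positivity.

The clinical table is expected to carry ``patient_id``,
``age_at_biopsy`` (years), ``n_treatment_lines`` (integer >= 1) and one
0/1 indicator column per prior treatment agent; missing values mark a
record incomplete.  Regressions run on complete cases only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CLINICAL_ID",
    "clinical_covariates",
    "complete_cases",
    "cohort_summary",
    "single_treatment_subset",
    "mann_whitney",
    "bh_adjust",
    "any_variant_vs_ar_expression",
    "per_count_group_tests",
    "univariate_screen",
    "multivariate_model",
    "oncoprint_order",
]

CLINICAL_ID = "patient_id"
_NON_TREATMENT = {CLINICAL_ID, "age_at_biopsy", "n_treatment_lines"}


def clinical_covariates(clinical: pd.DataFrame) -> list[str]:
    """Covariate columns in screen order: age, lines, then treatments."""
    treatments = [c for c in clinical.columns if c not in _NON_TREATMENT]
    return ["age_at_biopsy", "n_treatment_lines"] + treatments


def complete_cases(clinical: pd.DataFrame) -> pd.DataFrame:
    """Records with no missing covariate (complete-case analysis set)."""
    return clinical.dropna(subset=clinical_covariates(clinical))


def cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics table.

    Continuous covariates get median and range; each treatment indicator
    gets count and percentage over its evaluable (non-missing) records,
    one decimal.  An indicator with zero evaluable records reports a
    missing percentage rather than dividing by zero.
    """
    rows = []
    n = len(clinical)
    for col in ["age_at_biopsy", "n_treatment_lines"]:
        if col not in clinical.columns:
            continue
        vals = clinical[col].dropna()
        rows.append(
            {
                "characteristic": col,
                "n_evaluable": len(vals),
                "n_missing": n - len(vals),
                "median": float(vals.median()) if len(vals) else np.nan,
                "min": float(vals.min()) if len(vals) else np.nan,
                "max": float(vals.max()) if len(vals) else np.nan,
                "count": np.nan,
                "percent": np.nan,
            }
        )
    for col in clinical.columns:
        if col in _NON_TREATMENT:
            continue
        vals = clinical[col].dropna()
        count = int((vals == 1).sum())
        pct = round(100.0 * count / len(vals), 1) if len(vals) else np.nan
        rows.append(
            {
                "characteristic": col,
                "n_evaluable": len(vals),
                "n_missing": n - len(vals),
                "median": np.nan,
                "min": np.nan,
                "max": np.nan,
                "count": count,
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)


def single_treatment_subset(
    clinical: pd.DataFrame, min_group: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """Patients with exactly one prior treatment, grouped by that agent.

    Returns (group sizes over all single-treatment patients, the retained
    complete-case records restricted to groups of >= ``min_group``).
    """
    cases = complete_cases(clinical)
    treatments = [c for c in cases.columns if c not in _NON_TREATMENT]
    indic = cases[treatments].astype(int)
    single = cases[indic.sum(axis=1) == 1].copy()
    single["treatment_group"] = indic.loc[single.index].idxmax(axis=1)
    sizes = single["treatment_group"].value_counts()
    keep = sizes[sizes >= min_group].index
    return sizes, single[single["treatment_group"].isin(keep)]


# ---------------------------------------------------------------------------
# rank-based group comparisons


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution for small tie-free groups (both n <=
    ``exact_max_n``), normal approximation with tie correction and
    continuity correction otherwise.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    status: str  # ok | degenerate
    u: float = np.nan
    p: float = np.nan
    n_positive_group: int = 0
    n_negative_group: int = 0


def any_variant_vs_ar_expression(
    ar: pd.Series, positivity: pd.DataFrame
) -> GroupComparison:
    """AR expression in samples positive for >=1 variant vs none.

    ``ar`` is the normalized AR gene expression per sample; ``positivity``
    the samples x variants boolean call matrix.  Ties are handled by
    midranks.  An empty group yields an explicit degenerate result.
    """
    common = ar.index.intersection(positivity.index)
    any_pos = positivity.loc[common].any(axis=1)
    pos = ar.loc[common][any_pos].to_numpy()
    neg = ar.loc[common][~any_pos].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        return GroupComparison("degenerate", n_positive_group=len(pos), n_negative_group=len(neg))
    u, p = mann_whitney(pos, neg)
    return GroupComparison("ok", u, p, len(pos), len(neg))


def per_count_group_tests(ar: pd.Series, n_positive: pd.Series) -> pd.DataFrame:
    """All pairwise rank tests between per-variant-count groups, BH-adjusted.

    Samples are grouped by their number of positive variants; every pair
    of groups with >= 2 samples each is compared and q-values are
    computed by Benjamini-Hochberg over the pairwise family.  Skipped
    singleton pairs are reported with status ``skipped``.
    """
    common = ar.index.intersection(n_positive.index)
    groups = {
        k: ar.loc[common][n_positive.loc[common] == k].to_numpy()
        for k in sorted(n_positive.loc[common].unique())
    }
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        ga, gb = groups[a], groups[b]
        if len(ga) < 2 or len(gb) < 2:
            rows.append(
                {"group_a": a, "group_b": b, "n_a": len(ga), "n_b": len(gb),
                 "u": np.nan, "p": np.nan, "q": np.nan, "status": "skipped"}
            )
            continue
        u, p = mann_whitney(ga, gb)
        rows.append(
            {"group_a": a, "group_b": b, "n_a": len(ga), "n_b": len(gb),
             "u": u, "p": p, "q": np.nan, "status": "ok"}
        )
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# clinical regressions


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def univariate_screen(
    clinical: pd.DataFrame,
    relexpr: pd.DataFrame,
    alpha: float = 0.05,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """OLS of relative expression on each single covariate, per variant.

    Complete cases only; samples with undefined (NaN) relative expression
    are dropped per variant.  A constant covariate, or a fit with no
    residual degrees of freedom, is flagged ``inestimable``.  Covariates
    with p < ``alpha`` are flagged significant.
    """
    cases = complete_cases(clinical).set_index(CLINICAL_ID)
    covs = covariates or clinical_covariates(clinical)
    rows = []
    for variant in relexpr.columns:
        y_all = relexpr[variant]
        shared = cases.index.intersection(y_all.dropna().index)
        for cov in covs:
            x = cases.loc[shared, cov].to_numpy(dtype=float)
            y = y_all.loc[shared].to_numpy(dtype=float)
            if len(shared) < 3 or np.ptp(x) == 0.0:
                rows.append({"variant": variant, "covariate": cov, "n": len(shared),
                             "slope": np.nan, "p": np.nan,
                             "significant": False, "status": "inestimable"})
                continue
            fit = _ols(y, pd.DataFrame({cov: x}))
            p = float(fit.pvalues[cov])
            if fit.df_resid <= 0 or not np.isfinite(p):
                rows.append({"variant": variant, "covariate": cov, "n": len(shared),
                             "slope": float(fit.params[cov]), "p": np.nan,
                             "significant": False, "status": "inestimable"})
                continue
            rows.append({"variant": variant, "covariate": cov, "n": len(shared),
                         "slope": float(fit.params[cov]), "p": p,
                         "significant": bool(p < alpha), "status": "ok"})
    return pd.DataFrame(rows)


def multivariate_model(
    clinical: pd.DataFrame,
    relexpr: pd.DataFrame,
    features: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One multiple regression per variant over the selected features.

    Features perfectly collinear with earlier ones are dropped with a
    ``collinear-dropped`` notice before fitting.  Coefficients with
    p < ``alpha`` are flagged retained (the multivariate-significant
    trends).
    """
    if not features:
        raise ValueError("multivariate model requires >= 1 selected feature")
    cases = complete_cases(clinical).set_index(CLINICAL_ID)
    rows = []
    for variant in relexpr.columns:
        y_all = relexpr[variant]
        shared = cases.index.intersection(y_all.dropna().index)
        X_full = cases.loc[shared, features].astype(float)
        y = y_all.loc[shared].to_numpy(dtype=float)
        kept: list[str] = []
        for f in features:
            trial = X_full[kept + [f]].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(trial)), trial])) < (
                len(kept) + 2
            ):
                rows.append({"variant": variant, "feature": f, "n": len(shared),
                             "coef": np.nan, "p": np.nan, "retained": False,
                             "status": "collinear-dropped"})
                continue
            kept.append(f)
        if not kept or len(shared) <= len(kept) + 1:
            for f in kept:
                rows.append({"variant": variant, "feature": f, "n": len(shared),
                             "coef": np.nan, "p": np.nan, "retained": False,
                             "status": "inestimable"})
            continue
        fit = _ols(y, X_full[kept])
        for f in kept:
            p = float(fit.pvalues[f])
            rows.append({"variant": variant, "feature": f, "n": len(shared),
                         "coef": float(fit.params[f]), "p": p,
                         "retained": bool(np.isfinite(p) and p < alpha), "status": "ok"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# oncoprint ordering


def oncoprint_order(positivity: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Deterministic (sample, variant) orderings for a co-occurrence plot.

    Variants are sorted by descending prevalence (name as tie-break).
    Samples use the memo-sort: each sample's positivity vector, read in
    variant order, is a binary number sorted descending; ties fall back
    to sample id.  The ordering is invariant to input row/column order.
    """
    prevalence = positivity.sum(axis=0)
    variant_order = sorted(positivity.columns, key=lambda v: (-int(prevalence[v]), str(v)))
    mat = positivity[variant_order]

    def sample_key(s):
        bits = tuple(0 if b else 1 for b in mat.loc[s])  # 0 sorts first => positive first
        return (bits, str(s))

    sample_order = sorted(positivity.index, key=sample_key)
    return sample_order, variant_order
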