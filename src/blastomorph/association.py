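"""Implantation-association statistics for a morphometric cohort.

Covers the full analysis sequence run on a cohort of transferred embryos
with known implantation data (kid = 1 implanted, 0 not):

* descriptive group comparisons (pooled-variance two-sided Student's t-test,
  Welch available as an option; Pearson chi-square without continuity
  correction for 2x2 tables);
* univariable and age-adjusted multivariable logistic regressions with
  odds ratios and Wald 95% confidence intervals;
* a Pearson-correlation collinearity screen (|r| >= 0.6 with p < 0.05
  flags a covariate pair);
* the mean-split criterion (blastocyst size strictly above the cohort mean)
  with unadjusted and age-adjusted odds ratios;
* ROC/AUC by the Mann-Whitney pair-counting estimator with half credit for
  ties, variance by DeLong's structural-components method, and the paired
  DeLong test for comparing two correlated AUCs.

No multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .datatypes import CovariateFit, LogisticFitResult, ROCResult

__all__ = [
    "two_sample_ttest",
    "chi2_test",
    "logistic_fit",
    "or_from_rates",
    "split_by_mean",
    "roc_auc",
    "delong_compare",
    "collinearity_screen",
    "analysis_report",
    "PerfectSeparationError",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# group comparisons

def two_sample_ttest(
    x: Sequence[float], y: Sequence[float], *, welch: bool = False
) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance; Welch on request)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and np.var(x, ddof=1) + np.var(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def chi2_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# logistic regression

def logistic_fit(
    covariates: pd.DataFrame | np.ndarray,
    outcome: Sequence[int] | None = None,
    names: Sequence[str] | None = None,
    *,
    maxiter: int = 100,
) -> LogisticFitResult:
    """Maximum-likelihood logistic regression with Wald odds-ratio intervals.

    ``covariates`` may be a design DataFrame (column names kept) or a 2-D
    array with ``names``; an intercept column ``const`` is always added.
    An empty design fits the intercept-only model.  Complete separation
    raises :class:`PerfectSeparationError`; hitting the iteration cap is
    flagged via ``converged`` rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")

    if isinstance(covariates, pd.DataFrame):
        X = covariates.astype(float)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(len(y), 0)
        if arr.ndim == 1:
            arr = arr[:, None]
        if names is None:
            names = [f"x{i}" for i in range(arr.shape[1])]
        X = pd.DataFrame(arr, columns=list(names))
    if len(X) != len(y):
        raise ValueError("covariates and outcome lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")

    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=maxiter, warn_convergence=False)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise PerfectSeparationError(
            f"complete separation or singular information matrix: {exc}"
        ) from exc
    if not np.all(np.isfinite(res.bse)):
        raise PerfectSeparationError(
            "non-finite standard errors: separation or a degenerate design"
        )

    fits: dict[str, CovariateFit] = {}
    for name in design.columns:
        coef = float(res.params[name])
        se = float(res.bse[name])
        fits[name] = CovariateFit(
            name=name,
            coef=coef,
            se=se,
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - _Z95 * se)),
            ci_high=float(np.exp(coef + _Z95 * se)),
            p_value=float(res.pvalues[name]),
        )
    return LogisticFitResult(
        covariates=fits,
        log_likelihood=float(res.llf),
        converged=bool(res.mle_retvals["converged"]),
        n_iterations=int(res.mle_retvals["iterations"]),
        n_obs=int(res.nobs),
    )


def or_from_rates(p1: float, p2: float) -> float:
    """Odds ratio from two event rates: (p1/(1-p1)) / (p2/(1-p2))."""
    for p in (p1, p2):
        if not (0.0 < p < 1.0):
            raise ValueError("rates must lie strictly between 0 and 1")
    return (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))


def split_by_mean(sizes: Sequence[float]) -> np.ndarray:
    """Group-1 indicator: strictly greater than the arithmetic cohort mean."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("sizes must be nonempty")
    return sizes > sizes.mean()


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance

def _delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per negative).

    Uses the midrank formulation, which handles ties with half credit and
    runs in O(n log n).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    if set(np.unique(labels).tolist()) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """AUC (Mann-Whitney, ties at half credit) with DeLong SE and 95% CI."""
    scores, labels = _check_labels(np.asarray(scores), np.asarray(labels))
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    return ROCResult(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - _Z95 * se),
        ci_high=min(1.0, auc + _Z95 * se),
        n_pos=m,
        n_neg=n,
    )


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float]:
    """Paired DeLong test for equality of two correlated AUCs.

    Both score vectors must be on the same subjects.  Returns (z, two-sided
    p).  When the variance of the AUC difference is zero — e.g. one score is
    a monotone transform of the other — p = 1 for a zero difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    a, labels = _check_labels(a, np.asarray(labels))
    b, _ = _check_labels(b, np.asarray(labels))

    auc_a, v10_a, v01_a = _delong_components(a, labels)
    auc_b, v10_b, v01_b = _delong_components(b, labels)
    m, n = v10_a.size, v01_a.size

    var = 0.0
    if m > 1:
        s10 = np.cov(v10_a, v10_b, ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(v01_a, v01_b, ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n

    diff = auc_a - auc_b
    if var <= 1e-16:
        if abs(diff) <= 1e-12:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# collinearity screen

def collinearity_screen(
    covariates: pd.DataFrame, *, r_threshold: float = 0.6, alpha: float = 0.05
) -> dict:
    """Flag covariate pairs with |Pearson r| >= 0.6 and p < 0.05.

    Returns the flagged pairs and an exclusion recommendation (from each
    flagged pair, the later column is recommended for exclusion, so a
    derived ratio is dropped before its parents).
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 covariates to screen")
    for name in covariates.columns:
        if np.var(covariates[name].to_numpy(dtype=float)) == 0.0:
            raise ValueError(f"covariate {name!r} is constant")

    flagged = []
    excluded: list[str] = []
    for name_a, name_b in itertools.combinations(covariates.columns, 2):
        r, p = stats.pearsonr(
            covariates[name_a].to_numpy(dtype=float),
            covariates[name_b].to_numpy(dtype=float),
        )
        if abs(r) >= r_threshold and p < alpha:
            flagged.append({"pair": [name_a, name_b], "r": float(r), "p": float(p)})
            if name_b not in excluded:
                excluded.append(name_b)
    return {"flagged_pairs": flagged, "recommended_exclusions": excluded}


# ---------------------------------------------------------------------------
# full analysis report

_MORPHOMETRIC_VARS = ["blastocyst_size_um", "icm_size_um", "icm_ratio", "icm_shape"]


def _group_descriptive(cohort: pd.DataFrame, var: str) -> dict:
    pos = cohort.loc[cohort["kid"] == 1, var].to_numpy(dtype=float)
    neg = cohort.loc[cohort["kid"] == 0, var].to_numpy(dtype=float)
    t, p = two_sample_ttest(pos, neg)
    return {
        "kidp_mean": float(pos.mean()),
        "kidp_sd": float(pos.std(ddof=1)),
        "kidn_mean": float(neg.mean()),
        "kidn_sd": float(neg.std(ddof=1)),
        "t": t,
        "p": p,
    }


def _fit_section(cohort: pd.DataFrame, columns: list[str]) -> dict:
    fit = logistic_fit(cohort[columns], cohort["kid"].to_numpy())
    return fit.to_dict()


def analysis_report(cohort: pd.DataFrame) -> dict:
    """Run the full association analysis on a cohort table.

    Sections: descriptives (mean +/- SD by implantation outcome with
    t-tests), collinearity screen, univariable logistic fits per
    morphometric, age-adjusted multivariable fits (with the ratio variant
    and a without-ICM-size variant), the mean-split criterion with
    unadjusted and age-adjusted odds ratios, and ROC/AUC for age plus the
    criterion versus age alone with the paired DeLong comparison (a
    raw-size variant is reported alongside).  Deterministic: the same
    cohort always yields the identical report.
    """
    required = {"woman_age_years", "kid", *_MORPHOMETRIC_VARS}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    kid = cohort["kid"].to_numpy(dtype=int)
    if kid.min() == kid.max():
        raise ValueError("cohort must contain both implantation outcomes")

    n = len(cohort)
    report: dict = {
        "n": n,
        "n_kidp": int(kid.sum()),
        "n_kidn": int(n - kid.sum()),
        "prevalence": float(kid.mean()),
    }

    report["descriptives"] = {
        var: _group_descriptive(cohort, var)
        for var in ["woman_age_years", *_MORPHOMETRIC_VARS]
    }

    report["collinearity"] = collinearity_screen(
        cohort[["woman_age_years", *_MORPHOMETRIC_VARS]]
    )

    report["univariable"] = {
        var: _fit_section(cohort, [var]) for var in _MORPHOMETRIC_VARS
    }

    report["multivariable"] = {
        "icm_size_blastocyst_size_age": _fit_section(
            cohort, ["icm_size_um", "blastocyst_size_um", "woman_age_years"]
        ),
        "icm_size_icm_ratio_age": _fit_section(
            cohort, ["icm_size_um", "icm_ratio", "woman_age_years"]
        ),
        "blastocyst_size_age": _fit_section(
            cohort, ["blastocyst_size_um", "woman_age_years"]
        ),
    }

    # Mean-split criterion: blastocyst size strictly above the cohort mean.
    group1 = split_by_mean(cohort["blastocyst_size_um"].to_numpy())
    work = cohort.assign(size_above_mean=group1.astype(float))
    rate1 = float(kid[group1].mean())
    rate2 = float(kid[~group1].mean())
    table = np.array(
        [
            [int(kid[group1].sum()), int((~kid.astype(bool))[group1].sum())],
            [int(kid[~group1].sum()), int((~kid.astype(bool))[~group1].sum())],
        ]
    )
    chi2, chi2_p = chi2_test(table)
    adjusted = logistic_fit(
        work[["size_above_mean", "woman_age_years"]], kid
    )
    report["mean_split"] = {
        "size_mean_um": float(cohort["blastocyst_size_um"].mean()),
        "n_group1": int(group1.sum()),
        "n_group2": int((~group1).sum()),
        "rate_group1": rate1,
        "rate_group2": rate2,
        "unadjusted_or": or_from_rates(rate1, rate2),
        "chi2": chi2,
        "chi2_p": chi2_p,
        "adjusted": adjusted.to_dict(),
    }

    # ROC: age + criterion vs age alone (fitted probabilities as scores),
    # plus the raw-size variant of the combined model.
    fit_combined = logistic_fit(work[["size_above_mean", "woman_age_years"]], kid)
    fit_age = logistic_fit(work[["woman_age_years"]], kid)
    fit_raw = logistic_fit(work[["blastocyst_size_um", "woman_age_years"]], kid)

    def _probs(fit: LogisticFitResult, columns: list[str]) -> np.ndarray:
        eta = np.full(n, fit["const"].coef)
        for col in columns:
            eta = eta + fit[col].coef * work[col].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    scores_combined = _probs(fit_combined, ["size_above_mean", "woman_age_years"])
    scores_age = _probs(fit_age, ["woman_age_years"])
    scores_raw = _probs(fit_raw, ["blastocyst_size_um", "woman_age_years"])
    z, p = delong_compare(scores_combined, scores_age, kid)
    report["roc"] = {
        "age_plus_criterion": roc_auc(scores_combined, kid).to_dict(),
        "age_alone": roc_auc(scores_age, kid).to_dict(),
        "age_plus_raw_size": roc_auc(scores_raw, kid).to_dict(),
        "delong_z": z,
        "delong_p": p,
    }
    return report
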