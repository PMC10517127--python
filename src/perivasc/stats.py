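"""Cohort statistics over per-eye metric tables.

Implements the analysis chain applied to the corrected perivascular
reflectivity: inter-grader agreement (ICC), three-group comparison
(one-way ANOVA with Bonferroni-corrected pairwise post-hoc t-tests), the
paired obstructive-vs-contralateral quadrant test, univariate/multivariate
linear regression with standardized coefficients, and the disease-duration
sub-analysis.

Conventions (each selectable where ambiguity exists in practice):

- ICC: two-way random effects, absolute agreement — ICC(2,1) for single
  measures and ICC(2,k) for average measures.
- Post-hoc t-test: Student (pooled variance) by default, Welch optional;
  a zero-variance group triggers an automatic Welch fallback.
- Bonferroni: adjusted P = min(1, raw P x number of pairwise comparisons).
- Standardization: z-scores with sample SD (ddof=1); binary predictors are
  coded 0/1 before standardization, so the univariate standardized beta
  equals the Pearson correlation with the outcome.
- Missing covariates: listwise deletion per model, with logged counts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

MULTIVARIATE_ENTRY_P = 0.2  # univariate P below which a factor enters the
# multivariate model


# ---------------------------------------------------------------------------
# agreement


def icc_agreement(ratings: np.ndarray) -> tuple[float, float]:
    """Two-way random, absolute-agreement ICC from an n x k rating matrix.

    Returns ``(icc_single, icc_average)`` = (ICC(2,1), ICC(2,k)) from the
    two-way ANOVA mean squares::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    where MSR, MSC, MSE are the subject, rater and residual mean squares.
    A matrix with zero between-subject variance has no subject signal to
    agree on; both coefficients are reported as 0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise InputError("ratings must be an n_subjects x k_raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise InputError("ratings matrix contains missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    denom_avg = msr + (msc - mse) / n
    if np.isclose(msr, 0.0) or denom_single <= 0 or denom_avg <= 0:
        warnings.warn(
            "zero between-subject variance: ICC undefined, reporting 0",
            stacklevel=2,
        )
        return 0.0, 0.0
    return float((msr - mse) / denom_single), float((msr - mse) / denom_avg)


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_bonferroni: float


@dataclass
class GroupComparison:
    metric: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    anova_f: float
    anova_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def group_comparison(
    records: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    equal_var: bool = True,
) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-corrected pairwise post-hoc t-tests.

    The Bonferroni family is the set of pairwise group comparisons (3 for
    three groups).  ``equal_var=True`` gives the classical pooled-variance
    independent t-test; a group with zero variance falls back to Welch.
    """
    df = records[[group_col, metric]].dropna()
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise InputError(f"need >= 2 groups, got {groups}")
    samples = {g: df.loc[df[group_col] == g, metric].to_numpy(float) for g in groups}
    for g, v in samples.items():
        if v.size < 2:
            raise InputError(f"group {g!r} has n = {v.size} < 2")

    f_stat, f_p = sps.f_oneway(*samples.values())
    if not np.isfinite(f_p) and abs(f_stat) < 1e-12:
        # identical group means: zero between-group variance, nothing to reject
        f_stat, f_p = 0.0, 1.0

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        va, vb = samples[a], samples[b]
        use_equal = equal_var
        if use_equal and (va.std(ddof=1) == 0.0 or vb.std(ddof=1) == 0.0):
            logger.warning(
                "zero variance in group %r or %r: using Welch t-test", a, b
            )
            use_equal = False
        t, p = sps.ttest_ind(va, vb, equal_var=use_equal)
        pairwise.append(
            PairwiseComparison(a, b, float(t), float(p), float(min(1.0, p * m)))
        )
    return GroupComparison(
        metric=metric,
        group_means={g: float(v.mean()) for g, v in samples.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in samples.items()},
        group_ns={g: int(v.size) for g, v in samples.items()},
        anova_f=float(f_stat),
        anova_p=float(f_p),
        pairwise=pairwise,
    )


def paired_quadrant_test(
    obstructive: np.ndarray, contralateral: np.ndarray
) -> tuple[float, float]:
    """Paired t-test of obstructive- vs contralateral-quadrant values.

    Returns ``(t, p)`` on the within-eye differences.  If every difference
    is zero the test is degenerate; ``(0.0, 1.0)`` is returned with a
    warning rather than NaN.
    """
    x = np.asarray(obstructive, dtype=float)
    y = np.asarray(contralateral, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired vectors must be 1-D and of equal length")
    if x.size < 2:
        raise InputError(f"need n >= 2 pairs, got {x.size}")
    diffs = x - y
    if np.all(diffs == diffs[0]) and diffs[0] == 0.0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionRow:
    predictor: str
    standardized_beta: float
    p_value: float
    r_squared: float | None = None


@dataclass
class RegressionSuite:
    outcome: str
    univariate: list[RegressionRow]
    multivariate: list[RegressionRow]
    multivariate_predictors: list[str]
    n_univariate: dict[str, int]
    n_multivariate: int


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise InputError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def regression_suite(
    records: pd.DataFrame,
    outcome: str = "corrected_reflectivity",
    predictors: list[str] | None = None,
    entry_p: float = MULTIVARIATE_ENTRY_P,
) -> RegressionSuite:
    """Univariate screens plus an entry-rule multivariate linear model.

    Every predictor is fit alone against the outcome, both z-standardized
    (binary predictors coded 0/1 first), so the standardized beta equals
    the Pearson correlation.  Predictors with univariate P below
    ``entry_p`` (default 0.2) enter one joint multivariate fit.  Missing
    values are dropped listwise per model.
    """
    if predictors is None:
        predictors = [
            c
            for c in records.columns
            if c != outcome and pd.api.types.is_numeric_dtype(records[c])
        ]
    if not predictors:
        raise InputError("no predictors to screen")

    univariate: list[RegressionRow] = []
    n_univariate: dict[str, int] = {}
    for pred in predictors:
        sub = records[[outcome, pred]].dropna()
        n = len(sub)
        n_univariate[pred] = n
        dropped = len(records) - n
        if dropped:
            logger.info("univariate %s: dropped %d rows with missing data", pred, dropped)
        if n < 3:
            logger.warning("univariate %s: n = %d < 3, skipped", pred, n)
            continue
        y = _zscore(sub[outcome].to_numpy(float))
        x = _zscore(sub[pred].to_numpy(float))
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        univariate.append(
            RegressionRow(
                predictor=pred,
                standardized_beta=float(fit.params[1]),
                p_value=float(fit.pvalues[1]),
                r_squared=float(fit.rsquared),
            )
        )

    selected = [r.predictor for r in univariate if r.p_value < entry_p]
    multivariate: list[RegressionRow] = []
    n_multi = 0
    if selected:
        sub = records[[outcome] + selected].dropna()
        n_multi = len(sub)
        if n_multi <= len(selected) + 1:
            raise InputError(
                f"multivariate model needs n > {len(selected) + 1}, got {n_multi}"
            )
        X = np.column_stack([_zscore(sub[p].to_numpy(float)) for p in selected])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            offenders = _collinear_predictors(X, selected)
            raise InputError(
                "collinear multivariate design; offending predictors: "
                + ", ".join(offenders)
            )
        y = _zscore(sub[outcome].to_numpy(float))
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for i, pred in enumerate(selected):
            multivariate.append(
                RegressionRow(
                    predictor=pred,
                    standardized_beta=float(fit.params[i + 1]),
                    p_value=float(fit.pvalues[i + 1]),
                    r_squared=float(fit.rsquared),
                )
            )
    return RegressionSuite(
        outcome=outcome,
        univariate=univariate,
        multivariate=multivariate,
        multivariate_predictors=selected,
        n_univariate=n_univariate,
        n_multivariate=n_multi,
    )


def _collinear_predictors(X: np.ndarray, names: list[str]) -> list[str]:
    """Name predictors whose removal restores full column rank."""
    full_rank = np.linalg.matrix_rank(X)
    offenders = []
    for i, name in enumerate(names):
        reduced = np.delete(X, i, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            offenders.append(name)
    return offenders or list(names)


# ---------------------------------------------------------------------------
# duration sub-analysis


@dataclass
class StratumRegression:
    n: int
    standardized_beta: float | None
    r_squared: float | None
    p_value: float | None


@dataclass
class DurationSubanalysis:
    split_months: float
    n_early: int
    n_late: int
    reflectivity_t: float
    reflectivity_p: float
    injections_t: float
    injections_p: float
    early: StratumRegression
    late: StratumRegression


def duration_subanalysis(
    records: pd.DataFrame,
    split_months: float = 36.0,
    outcome: str = "corrected_reflectivity",
    predictor: str = "injections_per_year",
    duration_col: str = "duration_months",
    equal_var: bool = True,
) -> DurationSubanalysis:
    """Disease-duration stratified comparison and per-stratum regression.

    Eyes are split at ``split_months`` (default 36: below vs at-or-above
    three years from diagnosis to scan).  Reflectivity and injection rate
    are compared between strata with independent t-tests, and the
    reflectivity-on-injection-rate simple regression (standardized beta,
    R^2, P) is fit within each stratum.  A stratum with n < 3 skips its
    regression with a warning; an empty stratum is an error.
    """
    df = records[[outcome, predictor, duration_col]].dropna()
    early = df[df[duration_col] < split_months]
    late = df[df[duration_col] >= split_months]
    if len(early) == 0 or len(late) == 0:
        raise InputError(
            f"empty duration stratum at split {split_months} months "
            f"(n_early={len(early)}, n_late={len(late)})"
        )
    t_refl, p_refl = sps.ttest_ind(
        early[outcome], late[outcome], equal_var=equal_var
    )
    t_inj, p_inj = sps.ttest_ind(
        early[predictor], late[predictor], equal_var=equal_var
    )

    def _stratum_fit(sub: pd.DataFrame) -> StratumRegression:
        if len(sub) < 3:
            warnings.warn(
                f"stratum n = {len(sub)} < 3: regression skipped", stacklevel=3
            )
            return StratumRegression(len(sub), None, None, None)
        y = _zscore(sub[outcome].to_numpy(float))
        x = _zscore(sub[predictor].to_numpy(float))
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        return StratumRegression(
            n=len(sub),
            standardized_beta=float(fit.params[1]),
            r_squared=float(fit.rsquared),
            p_value=float(fit.pvalues[1]),
        )

    return DurationSubanalysis(
        split_months=split_months,
        n_early=len(early),
        n_late=len(late),
        reflectivity_t=float(t_refl),
        reflectivity_p=float(p_refl),
        injections_t=float(t_inj),
        injections_p=float(p_inj),
        early=_stratum_fit(early),
        late=_stratum_fit(late),
    )
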