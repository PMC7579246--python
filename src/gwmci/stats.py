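"""Statistical layer: contingency chi-squares, ANOVA/ANCOVA with planned
contrasts, hierarchical and stepwise linear regression with standardized
coefficients, and the correlated-endpoints significance threshold.

Conventions
-----------
* Chi-square tests are Pearson, no continuity correction.
* ANCOVA group tests are partial F tests comparing the full linear model
  to the model without the group indicators (reference coding, CN as the
  default reference).
* Binary outcomes (e.g. MCI status 0/1) are fitted by ordinary least
  squares as a linear probability model.
* Standardized coefficients z-score the outcome and every predictor,
  binary predictors included, matching common statistics-package output;
  t and p are identical between the raw and standardized fits.
* All p-values are two-sided.
* Rows with missing values are dropped listwise within each model; the
  dropped count is recorded on the fit.

The multiple-comparison adjustment for correlated endpoints discounts
the Bonferroni/Sidak test count by the average pairwise intercorrelation
r̄ of the endpoints: the effective number of tests is m_eff = n^(1 - r̄),
and the per-test threshold is the Sidak value 1 - (1 - alpha)^(1/m_eff).
At r̄ = 0 this is the ordinary Sidak correction; at r̄ = 1 (fully
dependent endpoints) no correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "AnovaResult",
    "LinearModelFit",
    "StepResult",
    "ContrastResult",
    "AdjustedAlpha",
    "CollinearityError",
    "DegenerateDataError",
    "contingency",
    "chi_square",
    "one_way_anova",
    "anova_from_summary",
    "ancova_group_test",
    "planned_contrasts",
    "standardize_and_fit",
    "hierarchical_regression",
    "stepwise_regression",
    "average_intercorrelation",
    "effective_alpha",
]

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class DegenerateDataError(ValueError):
    """The data admit no meaningful test (zero margins, zero variance...)."""


# ---------------------------------------------------------------------------
# Contingency tables and chi-square


@dataclass
class ContingencyTable:
    """An r x c table of counts with labelled rows and columns."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError(
                f"contingency table must be at least 2x2, got {r}x{c}"
            )
        if (self.counts < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("contingency table total must be positive")
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths do not match table shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray


def contingency(
    labels: Sequence, variable: Sequence, name: str = "variable"
) -> ContingencyTable:
    """Cross-tabulate a categorical variable against group labels.

    Rows are variable categories, columns are group labels.  Missing
    variable values are dropped (with a logged count); missing group
    labels are an error.
    """
    labels = pd.Series(list(labels))
    variable = pd.Series(list(variable))
    if len(labels) != len(variable):
        raise ValueError(
            f"labels ({len(labels)}) and variable ({len(variable)}) lengths differ"
        )
    if len(labels) == 0:
        raise ValueError("empty input")
    if labels.isna().any():
        raise ValueError("missing group labels are not allowed")
    keep = variable.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("contingency(%s): dropped %d subjects with missing values", name, n_drop)
    tab = pd.crosstab(variable[keep], labels[keep])
    return ContingencyTable(
        row_labels=tuple(str(i) for i in tab.index),
        col_labels=tuple(str(c) for c in tab.columns),
        counts=tab.to_numpy(),
    )


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateDataError(
            "contingency table has a zero row or column margin"
        )
    res = sps.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        expected=np.asarray(res.expected_freq),
    )


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def _anova_from_sums(ssb: float, ssw: float, k: int, N: int) -> AnovaResult:
    df_b, df_w = k - 1, N - k
    if df_b < 1 or df_w < 1:
        raise DegenerateDataError(
            f"ANOVA needs >=2 groups and residual df >= 1 (k={k}, N={N})"
        )
    msw = ssw / df_w
    if msw <= 0:
        raise DegenerateDataError("within-group variance is zero; F undefined")
    F = (ssb / df_b) / msw
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w,
                       p=float(sps.f.sf(F, df_b, df_w)))


def one_way_anova(values: Sequence[float], labels: Sequence) -> AnovaResult:
    """Classical one-way between/within decomposition."""
    df = pd.DataFrame({"y": pd.Series(list(values), dtype=float), "g": list(labels)})
    df = df.dropna()
    groups = df.groupby("g")["y"]
    ns = groups.size()
    if len(ns) < 2:
        raise DegenerateDataError("one-way ANOVA needs at least 2 groups")
    if (ns < 2).any():
        small = ns[ns < 2].index.tolist()
        raise DegenerateDataError(f"singleton groups: {small}")
    grand = df["y"].mean()
    ssb = float((ns * (groups.mean() - grand) ** 2).sum())
    ssw = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    return _anova_from_sums(ssb, ssw, k=len(ns), N=len(df))


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> AnovaResult:
    """One-way ANOVA from per-group means, SDs and sizes.

    Algebraically identical to :func:`one_way_anova` on any raw sample
    having exactly these summaries.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds, ns must have equal length")
    if (sds <= 0).any():
        raise ValueError("group SDs must be strictly positive")
    if (ns < 2).any():
        raise DegenerateDataError("every group needs n >= 2")
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    return _anova_from_sums(ssb, ssw, k=len(ns), N=N)


# ---------------------------------------------------------------------------
# Linear models


@dataclass
class LinearModelFit:
    """An OLS fit with raw and standardized coefficients.

    ``terms`` excludes the intercept; ``coefficients`` includes it under
    ``"const"``.  ``std_beta`` is the coefficient of the fully z-scored
    fit (undefined for the intercept).
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    std_beta: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r2: float
    n: int
    residual_df: int
    n_dropped: int = 0
    group_coding: dict | None = None
    _results: object = field(default=None, repr=False, compare=False)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "estimate": self.coefficients[t],
                "std_beta": self.std_beta.get(t, np.nan),
                "t": self.t[t],
                "p": self.p[t],
            }
            for t in ("const", *self.terms)
            if t in self.coefficients
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepResult:
    step_index: int
    entered_terms: tuple[str, ...]
    fit: LinearModelFit
    delta_r2: float


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple[str, str]
    estimate: float
    t: float
    p: float


def _design_frame(
    outcome: Sequence[float],
    terms: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame, int]:
    y = pd.Series(list(outcome), dtype=float).reset_index(drop=True)
    X = pd.DataFrame({k: pd.Series(list(v), dtype=float) for k, v in dict(terms).items()})
    X = X.reset_index(drop=True)
    if len(X) != len(y):
        raise ValueError("outcome and terms have different lengths")
    keep = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d rows", n_dropped, len(y))
    return y[keep], X[keep], n_dropped


def _fit_ols(y: pd.Series, X: pd.DataFrame, n_dropped: int = 0) -> LinearModelFit:
    for col in X.columns:
        if float(X[col].std(ddof=0)) == 0.0:
            raise DegenerateDataError(f"term {col!r} has zero variance")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the aliased columns by checking incremental rank
        aliased, seen = [], []
        for col in design.columns:
            seen.append(col)
            if np.linalg.matrix_rank(design[seen].to_numpy()) < len(seen):
                aliased.append(col)
                seen.pop()
        raise CollinearityError(f"design is rank deficient; aliased terms: {aliased}")
    res = sm.OLS(np.asarray(y, dtype=float), design).fit()
    sy = float(y.std(ddof=1))
    std_beta = {}
    for col in X.columns:
        sx = float(X[col].std(ddof=1))
        std_beta[col] = float(res.params[col] * sx / sy) if sy > 0 else np.nan
    return LinearModelFit(
        terms=tuple(X.columns),
        coefficients={k: float(v) for k, v in res.params.items()},
        std_beta=std_beta,
        t={k: float(v) for k, v in res.tvalues.items()},
        p={k: float(v) for k, v in res.pvalues.items()},
        r2=float(res.rsquared),
        n=int(res.nobs),
        residual_df=int(res.df_resid),
        n_dropped=n_dropped,
        _results=res,
    )


def standardize_and_fit(
    outcome: Sequence[float],
    terms: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> LinearModelFit:
    """OLS fit reporting raw coefficients and standardized betas.

    The standardized beta for term j equals b_j * sd(x_j) / sd(y), i.e.
    the slope of the fit after z-scoring outcome and all predictors;
    t statistics and p-values are shared between the two scalings.
    """
    y, X, n_dropped = _design_frame(outcome, terms)
    return _fit_ols(y, X, n_dropped)


def ancova_group_test(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
    reference: str = "CN",
) -> tuple[AnovaResult, LinearModelFit]:
    """Covariate-adjusted group test via a partial F on group indicators.

    The group factor is coded as indicator terms against ``reference``;
    the returned :class:`AnovaResult` is the partial F comparing the full
    model to the model without the group indicators.  With no covariates
    this reproduces the one-way ANOVA exactly.
    """
    y = pd.Series(list(outcome), dtype=float).reset_index(drop=True)
    g = pd.Series([str(v) for v in group]).reset_index(drop=True)
    levels = sorted(g.unique())
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not among levels {levels}")
    if len(levels) < 2:
        raise DegenerateDataError("group factor needs at least 2 levels")

    cov = pd.DataFrame() if covariates is None else pd.DataFrame(
        {k: pd.Series(list(v), dtype=float) for k, v in dict(covariates).items()}
    ).reset_index(drop=True)
    keep = y.notna() & g.notna()
    if len(cov):
        keep &= cov.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("ancova_group_test: listwise deletion dropped %d rows", n_dropped)
    y, g = y[keep], g[keep]
    cov = cov[keep] if len(cov) else cov

    dummy_names = []
    X = pd.DataFrame(index=y.index)
    for lev in levels:
        if lev == reference:
            continue
        name = f"group_{lev}"
        X[name] = (g == lev).astype(float)
        dummy_names.append(name)
    for c in cov.columns:
        X[c] = cov[c]

    full = _fit_ols(y, X, n_dropped)
    res_full = full._results
    if len(cov.columns):
        reduced = _fit_ols(y, X[list(cov.columns)])
        ss_diff = reduced._results.ssr - res_full.ssr
    else:
        ss_diff = res_full.centered_tss - res_full.ssr
    df_num = len(dummy_names)
    df_den = int(res_full.df_resid)
    mse = res_full.ssr / df_den
    if mse <= 0:
        raise DegenerateDataError("residual variance is zero; F undefined")
    F = float(ss_diff / df_num / mse)
    F = max(F, 0.0)
    anova = AnovaResult(F=F, df_between=df_num, df_within=df_den,
                        p=float(sps.f.sf(F, df_num, df_den)))
    full.group_coding = {
        "reference": reference,
        "levels": levels,
        "terms": {lev: f"group_{lev}" for lev in levels if lev != reference},
    }
    return anova, full


def planned_contrasts(
    fit: LinearModelFit, pairs: Iterable[tuple[str, str]]
) -> list[ContrastResult]:
    """Pairwise adjusted-mean differences between group levels.

    ``fit`` must come from :func:`ancova_group_test`.  Each contrast is
    the model-adjusted mean of group a minus group b, with the t and
    two-sided p from the coefficient covariance; no multiplicity
    correction is applied.
    """
    if fit.group_coding is None or fit._results is None:
        raise ValueError("fit does not carry group coding; use ancova_group_test")
    coding = fit.group_coding
    res = fit._results
    exog_names = list(res.model.exog_names)
    results = []
    for a, b in pairs:
        for lev in (a, b):
            if lev not in coding["levels"]:
                raise ValueError(f"group {lev!r} not in model levels {coding['levels']}")
        vec = np.zeros(len(exog_names))
        if a != b:
            if a != coding["reference"]:
                vec[exog_names.index(coding["terms"][a])] += 1.0
            if b != coding["reference"]:
                vec[exog_names.index(coding["terms"][b])] -= 1.0
            tt = res.t_test(vec)
            results.append(
                ContrastResult(
                    pair=(a, b),
                    estimate=float(np.asarray(tt.effect).ravel()[0]),
                    t=float(np.asarray(tt.tvalue).ravel()[0]),
                    p=float(np.asarray(tt.pvalue).ravel()[0]),
                )
            )
        else:
            results.append(ContrastResult(pair=(a, b), estimate=0.0, t=0.0, p=1.0))
    return results


def hierarchical_regression(
    outcome: Sequence[float],
    blocks: Sequence[Sequence[str]],
    data: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> list[StepResult]:
    """Blockwise (hierarchical) OLS: step k fits all terms in blocks 1..k.

    A binary outcome is fitted as a linear probability model.  Listwise
    deletion uses the union of all block terms so every step sees the
    same rows and r2 is non-decreasing across steps.
    """
    if not blocks:
        raise ValueError("at least one block required")
    data = pd.DataFrame(dict(data))
    all_terms: list[str] = []
    for block in blocks:
        for t in block:
            if t in all_terms:
                raise ValueError(f"term {t!r} appears in more than one block")
            all_terms.append(t)
    missing = [t for t in all_terms if t not in data.columns]
    if missing:
        raise KeyError(f"blocks reference terms not in data: {missing}")
    y, X, n_dropped = _design_frame(outcome, data[all_terms])

    steps: list[StepResult] = []
    prev_r2 = 0.0
    cum: list[str] = []
    for k, block in enumerate(blocks, start=1):
        cum.extend(block)
        try:
            fit = _fit_ols(y, X[cum], n_dropped)
        except CollinearityError as exc:
            raise CollinearityError(f"step {k}: {exc}") from exc
        steps.append(
            StepResult(
                step_index=k,
                entered_terms=tuple(block),
                fit=fit,
                delta_r2=max(fit.r2 - prev_r2, 0.0),
            )
        )
        prev_r2 = fit.r2
    return steps


def stepwise_regression(
    outcome: Sequence[float],
    candidates: Sequence[str],
    data: Mapping[str, Sequence[float]] | pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> tuple[LinearModelFit | None, list[str]]:
    """Forward stepwise selection with backward removal.

    At each iteration the candidate with the smallest entry p-value is
    added if below ``p_enter``; any included term whose p-value exceeds
    ``p_remove`` is then removed.  Requires ``p_enter < p_remove`` so a
    just-entered term is never immediately removed.  Returns the final
    fit (None if no term enters) and the entry order.
    """
    if not candidates:
        raise ValueError("at least one candidate term required")
    if not p_enter < p_remove:
        raise ValueError("p_enter must be smaller than p_remove")
    data = pd.DataFrame(dict(data))
    y, X, n_dropped = _design_frame(outcome, data[list(candidates)])

    included: list[str] = []
    entry_order: list[str] = []
    max_iter = 4 * len(candidates) + 10  # guards pathological add/remove cycles
    for _ in range(max_iter):
        changed = False
        remaining = [c for c in candidates if c not in included]
        best_p, best_term = None, None
        for term in remaining:
            try:
                fit = _fit_ols(y, X[included + [term]], n_dropped)
            except (CollinearityError, DegenerateDataError):
                continue
            pv = fit.p[term]
            if best_p is None or pv < best_p:
                best_p, best_term = pv, term
        if best_term is not None and best_p < p_enter:
            included.append(best_term)
            entry_order.append(best_term)
            changed = True
        if included:
            fit = _fit_ols(y, X[included], n_dropped)
            worst = max(included, key=lambda t: fit.p[t])
            if fit.p[worst] > p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            break
    if not included:
        return None, entry_order
    return _fit_ols(y, X[included], n_dropped), entry_order


# ---------------------------------------------------------------------------
# Correlated-endpoints alpha adjustment


@dataclass(frozen=True)
class AdjustedAlpha:
    n_tests: int
    r_bar: float
    alpha_family: float
    m_eff: float
    alpha_adj: float

    def rounded(self, decimals: int) -> float:
        return round(self.alpha_adj, decimals)


def average_intercorrelation(matrix) -> float:
    """Mean of the strictly-upper-triangle pairwise Pearson correlations.

    Raw (signed) correlations, not absolute values.  ``matrix`` is
    subjects x measures; rows with any missing value are dropped.
    """
    X = pd.DataFrame(matrix).dropna().to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 measures")
    if (X.std(axis=0, ddof=0) == 0).any():
        raise DegenerateDataError("a column has zero variance")
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def effective_alpha(
    n_tests: int, r_bar: float, alpha_family: float = 0.05
) -> AdjustedAlpha:
    """Significance threshold for n correlated endpoints.

    m_eff = n^(1 - r̄); alpha_adj = 1 - (1 - alpha)^(1/m_eff).  A
    negative r̄ (possible with raw averaging) is clamped to 0 with a
    warning, which reduces to the ordinary Sidak correction.
    """
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < alpha_family < 1:
        raise ValueError(f"alpha_family must be in (0, 1), got {alpha_family}")
    if r_bar > 1:
        raise ValueError(f"r_bar must be <= 1, got {r_bar}")
    if r_bar < 0:
        logger.warning("negative average intercorrelation %.4f clamped to 0", r_bar)
        r_bar = 0.0
    m_eff = float(n_tests ** (1.0 - r_bar))
    alpha_adj = float(1.0 - (1.0 - alpha_family) ** (1.0 / m_eff))
    return AdjustedAlpha(
        n_tests=int(n_tests),
        r_bar=float(r_bar),
        alpha_family=float(alpha_family),
        m_eff=m_eff,
        alpha_adj=alpha_adj,
    )
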