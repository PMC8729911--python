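"""Inferential statistics for acuity/morphometric tables.

Thin, explicit wrappers around scipy/statsmodels for the three procedures the
acuity comparisons need: Kruskal–Wallis rank sums (with an exact permutation
p-value at very small n), a variance-ratio F-test, and ordinary least squares
with interaction terms assessed by drop-one F-tests respecting marginality
(the interaction is tested against the full model; main effects are tested in
the additive model once a non-significant interaction has been removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "KruskalResult",
    "VarianceRatioResult",
    "Drop1Result",
    "kruskal_wallis",
    "variance_ratio_test",
    "linear_model_drop1",
]

EXACT_PERMUTATION_MAX_N = 8


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p_chi2: float
    p_exact: float | None  # exact permutation p, reported when total n <= 8


@dataclass(frozen=True)
class VarianceRatioResult:
    f: float
    df1: int
    df2: int
    p: float  # two-sided; NaN when the denominator variance is zero


@dataclass
class Drop1Result:
    coefficients: pd.Series
    interaction_f: float
    interaction_p: float
    interaction_dropped: bool
    main_effects: dict[str, tuple[float, float]]  # term -> (F, p), additive model
    residual_summary: dict[str, float]
    model: object = field(repr=False, default=None)


def _h_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H on mid-ranks (matches scipy)."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = _sps.rankdata(all_vals)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0:
        return 0.0  # every observation tied: no rank information
    return h / tie


def _exact_permutation_p(groups: Sequence[np.ndarray], h_obs: float) -> float:
    """Exact permutation p by enumerating all assignments of the pooled
    values to groups of the observed sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    idx_all = list(range(len(pooled)))

    def assignments(remaining: list[int], size_idx: int):
        if size_idx == len(sizes) - 1:
            yield [remaining]
            return
        for combo in combinations(remaining, sizes[size_idx]):
            rest = [i for i in remaining if i not in set(combo)]
            for tail in assignments(rest, size_idx + 1):
                yield [list(combo)] + tail

    count = 0
    total = 0
    for assign in assignments(idx_all, 0):
        h = _h_statistic([pooled[np.array(ix)] for ix in assign])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def kruskal_wallis(*groups: Sequence[float]) -> KruskalResult:
    """Kruskal–Wallis rank-sum test across two or more groups.

    The p-value comes from the chi-square reference distribution with
    (groups - 1) degrees of freedom; for total n <= 8 an exact permutation
    p-value is also reported.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if sum(len(a) for a in arrays) < 2:
        raise ValueError("need at least two observations in total")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = _sps.kruskal(*arrays)
    p_exact = None
    if len(pooled) <= EXACT_PERMUTATION_MAX_N:
        p_exact = _exact_permutation_p(arrays, h)
    return KruskalResult(h=float(h), df=df, p_chi2=float(p), p_exact=p_exact)


def variance_ratio_test(a: Sequence[float], b: Sequence[float]) -> VarianceRatioResult:
    """F-test for homogeneity of variances, F = s_a^2 / s_b^2, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df1, df2 = len(a) - 1, len(b) - 1
    if vb == 0:
        return VarianceRatioResult(f=float("inf") if va > 0 else float("nan"),
                                   df1=df1, df2=df2, p=float("nan"))
    f = va / vb
    dist = _sps.f(df1, df2)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return VarianceRatioResult(f=float(f), df1=df1, df2=df2, p=float(min(p, 1.0)))


def _name_rank_deficient_column(exog: pd.DataFrame) -> str:
    x = exog.to_numpy(dtype=float)
    rank = 0
    for k in range(1, x.shape[1] + 1):
        new_rank = np.linalg.matrix_rank(x[:, :k])
        if new_rank == rank:
            return str(exog.columns[k - 1])
        rank = new_rank
    return "<unknown>"


def linear_model_drop1(
    table: pd.DataFrame,
    response: str,
    continuous: str,
    factor: str,
    interaction_alpha: float = 0.05,
) -> Drop1Result:
    """OLS of ``response ~ continuous * factor`` with drop-one F-tests.

    The interaction is tested by comparing the full model against the
    additive model.  If its p-value is >= ``interaction_alpha`` the additive
    model is refit and each main effect tested by dropping it in turn
    (marginality-respecting, type-II style).  Residual diagnostics are limited
    to summary moments.
    """
    for col in (response, continuous, factor):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    n = len(table)
    full_formula = f"{response} ~ {continuous} * C({factor})"
    full = smf.ols(full_formula, data=table).fit()
    if n <= full.df_model + 1:
        raise ValueError("more parameters than observations")
    exog = pd.DataFrame(full.model.exog, columns=full.model.exog_names)
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError(
            f"design is rank deficient; offending column: {_name_rank_deficient_column(exog)}"
        )

    additive = smf.ols(f"{response} ~ {continuous} + C({factor})", data=table).fit()
    cmp_int = anova_lm(additive, full)
    f_int = float(cmp_int["F"].iloc[1])
    p_int = float(cmp_int["Pr(>F)"].iloc[1])

    dropped = p_int >= interaction_alpha
    main: dict[str, tuple[float, float]] = {}
    final = full
    if dropped:
        final = additive
        no_cont = smf.ols(f"{response} ~ C({factor})", data=table).fit()
        no_fact = smf.ols(f"{response} ~ {continuous}", data=table).fit()
        cmp_c = anova_lm(no_cont, additive)
        cmp_f = anova_lm(no_fact, additive)
        main[continuous] = (float(cmp_c["F"].iloc[1]), float(cmp_c["Pr(>F)"].iloc[1]))
        main[factor] = (float(cmp_f["F"].iloc[1]), float(cmp_f["Pr(>F)"].iloc[1]))

    resid = final.resid.to_numpy()
    residual_summary = {
        "mean": float(resid.mean()),
        "sd": float(resid.std(ddof=1)) if len(resid) > 1 else float("nan"),
        "skew": float(_sps.skew(resid)) if len(resid) > 2 else float("nan"),
        "kurtosis": float(_sps.kurtosis(resid)) if len(resid) > 3 else float("nan"),
    }
    return Drop1Result(
        coefficients=final.params,
        interaction_f=f_int,
        interaction_p=p_int,
        interaction_dropped=dropped,
        main_effects=main,
        residual_summary=residual_summary,
        model=final,
    )
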