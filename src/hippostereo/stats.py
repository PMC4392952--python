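"""Group-comparison and correlation statistics for the study report.

One-way ANOVA with Tukey's HSD post hoc test across the four arms, and
Pearson correlation between covariates and region quantities.  These are
textbook procedures delegated to scipy; the surrounding dataclasses fix the
report structure and input validation, and the unit tests pin the numbers
to independently computed references.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float  # mean(b) - mean(a)
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    pairwise: tuple[TukeyPair, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least two values")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Classical one-way ANOVA: F = MS_between / MS_within."""
    arrays = _validate_groups(groups)
    pooled = np.concatenate(arrays)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    ss_between = sum(g.size * (g.mean() - pooled.mean()) ** 2 for g in arrays)
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("all observations identical: F statistic undefined")
    f, p = _sps.f_oneway(*arrays)
    return GroupComparison(f_statistic=float(f), p_value=float(p))


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> tuple[TukeyPair, ...]:
    """All-pairs Tukey HSD with studentized-range adjusted p values.

    Equal group sizes use the classical test; unbalanced designs fall back
    to the Tukey-Kramer variant (scipy handles both).
    """
    arrays = _validate_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(arrays))]
    res = _sps.tukey_hsd(*arrays)
    pairs = []
    for i, j in combinations(range(len(arrays)), 2):
        p_adj = float(res.pvalue[i, j])
        pairs.append(
            TukeyPair(
                group_a=str(labels[i]),
                group_b=str(labels[j]),
                mean_difference=float(arrays[j].mean() - arrays[i].mean()),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return tuple(pairs)


def group_comparison(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> GroupComparison:
    """ANOVA plus Tukey post hoc in one report entry."""
    base = one_way_anova(groups)
    return GroupComparison(
        f_statistic=base.f_statistic,
        p_value=base.p_value,
        pairwise=tukey_hsd(groups, alpha=alpha, labels=labels),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = _sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), n=int(xa.size), p_value=float(res.pvalue))


def correlation_matrix(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson r over the given columns (long-form rows)."""
    rows = []
    for a, b in combinations(columns, 2):
        res = pearson_r(df[a], df[b])
        rows.append({"x": a, "y": b, "r": res.r, "n": res.n, "p_value": res.p_value})
    return pd.DataFrame(rows)
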