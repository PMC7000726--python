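"""Group statistics: two-sample t-tests and identity–RMSD correlations.

Thin, contract-enforcing wrappers around scipy.stats. The pooled
(equal-variance) Student's t is the default variant; Welch is available
by flag. P-values are two-sided. Category correlations reproduce the
per-category Pearson r between global-alignment identity and
superposition RMSD used to quantify how weakly sequence similarity
predicts structural similarity across extremophile categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = [
    "GroupComparison",
    "CorrelationRecord",
    "t_test",
    "pearson",
    "category_correlations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    infinite_t: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationRecord:
    category: str
    n: int
    r: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r {self.r} outside [-1, 1]")


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "pooled",
    parameter: str = "",
) -> GroupComparison:
    """Two-sample t-test (two-sided).

    ``variant='pooled'`` uses the equal-variance Student statistic;
    ``'welch'`` the unequal-variance form. Degenerate zero-variance
    input is resolved by contract: equal means give t=0, p=1; unequal
    means are flagged as infinite t with p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    mean_a, mean_b = float(np.mean(x)), float(np.mean(y))
    var_x, var_y = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if var_x == 0.0 and var_y == 0.0:
        df = float(x.size + y.size - 2)
        if mean_a == mean_b:
            return GroupComparison(parameter, mean_a, mean_b, 0.0, df, 1.0)
        t = math.inf if mean_a > mean_b else -math.inf
        return GroupComparison(parameter, mean_a, mean_b, t, df, 0.0,
                               infinite_t=True)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    df = float(res.df)
    return GroupComparison(
        parameter, mean_a, mean_b, float(res.statistic), df, float(res.pvalue)
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise InsufficientDataError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def category_correlations(
    pair_table: pd.DataFrame,
    category_col: str = "category",
    x_col: str = "identity_pct",
    y_col: str = "rmsd",
) -> list[CorrelationRecord]:
    """Per-category Pearson r over (identity, RMSD) pairs.

    Categories with fewer than 3 complete pairs are skipped with a
    warning rather than reported.
    """
    records: list[CorrelationRecord] = []
    for category, sub in pair_table.groupby(category_col, sort=True):
        sub = sub.dropna(subset=[x_col, y_col])
        if len(sub) < 3:
            logger.warning(
                "category %s has %d pairs (<3); skipped", category, len(sub)
            )
            continue
        try:
            r = pearson(sub[x_col].to_numpy(), sub[y_col].to_numpy())
        except InsufficientDataError as exc:
            logger.warning("category %s skipped: %s", category, exc)
            continue
        records.append(CorrelationRecord(str(category), len(sub), r))
    return records
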