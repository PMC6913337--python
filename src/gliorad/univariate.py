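"""Univariate association screening.

Each feature is tested against the binary outcome (0 recurrence,
1 necrosis) with Spearman's rank correlation r_s; multiplicity is
handled by a Bonferroni threshold alpha / K. K is passed explicitly by
the caller because the comparison count may be defined at a coarser
grouping than the raw table width (e.g. per statistic family rather than
per grid point).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .handcrafted import FeatureTable


@dataclasses.dataclass
class UnivariateResult:
    feature: str
    r_s: float
    p_value: float
    significant: bool


def spearman_rs(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the
    large-sample t approximation. Constant x -> (0, 1) with a warning."""
    x = np.asarray(x, float)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if np.all(x == x[0]):
        warnings.warn("constant feature: r_s set to 0, p to 1")
        return 0.0, 1.0
    rs, p = stats.spearmanr(x, y)
    return float(rs), float(p)


def bonferroni_threshold(alpha: float, K: int) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    return alpha / K


def screen(
    table: FeatureTable, alpha: float = 0.05, K: int | None = None
) -> pd.DataFrame:
    """Spearman screen of every column; significance at alpha / K.

    K defaults to the table width.
    """
    K = K if K is not None else table.p
    thr = bonferroni_threshold(alpha, K)
    rows = []
    for j, name in enumerate(table.names):
        rs, p = spearman_rs(table.X[:, j], table.y)
        rows.append(
            UnivariateResult(feature=name, r_s=rs, p_value=p, significant=p < thr)
        )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
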