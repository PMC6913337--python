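"""Gain-equation feature reduction.

Stepwise forward reduction of a large feature set to ``target_size``
(default 25) features. At each step the remaining feature j with the
largest gain is selected, where

    Gain_j = gamma * rs_bar_j
           + delta_a * sum_{c=1..d} [2(d-c+1) / (d(d+1))] * (1 - MIC(x_c, x_j))_bar
           + delta_b * (1/D) * sum_{k=1..D} (1 - MIC(x_k, x_j))_bar

with d the number of already-selected features (ordered by selection,
c = 1 first), D the number of remaining features, and every overbarred
term a mean over B imbalance-adjusted bootstrap replicates. rs_bar is
the bootstrap mean of |r_s(x_j, y)| by default (the absolute value keeps
strongly negatively-correlated features selectable; the signed variant
is available via ``signed_rs``). Defaults gamma = 0.5, delta_a = 0.5,
delta_b = 0; the triangular weights sum to 1 for any d >= 1.

The same bootstrap replicates are shared across candidates and across
iterations (variance reduction, and it makes the pairwise MIC terms
cacheable); the final selected list is ordered by descending gain at
selection time.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata

from .handcrafted import FeatureTable
from .mic import mic
from .modeling import imbalance_adjusted_resample


@dataclasses.dataclass
class GainConfig:
    gamma: float = 0.5
    delta_a: float = 0.5
    delta_b: float = 0.0
    B_reduce: int = 1000
    target_size: int = 25
    seed: int = 0
    signed_rs: bool = False
    mic_approx: str = "auto"

    def __post_init__(self):
        if min(self.gamma, self.delta_a, self.delta_b) < 0:
            raise ValueError("gain weights must be >= 0")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if self.B_reduce < 1:
            raise ValueError("B_reduce must be >= 1")


@dataclasses.dataclass
class ReductionState:
    """Selected features (descending gain) and bookkeeping."""

    selected: list[str]
    selection_order: list[str]
    gains: dict[str, float]
    remaining: list[str]

    def __post_init__(self):
        if set(self.selected) & set(self.remaining):
            raise ValueError("selected and remaining sets must be disjoint")


def triangular_weights(d: int) -> np.ndarray:
    """Weights 2(d-c+1)/(d(d+1)) for c = 1..d; they sum to 1."""
    if d < 1:
        raise ValueError("d must be >= 1")
    c = np.arange(1, d + 1)
    return 2.0 * (d - c + 1) / (d * (d + 1))


class GainEngine:
    """Caches the bootstrap-averaged terms of the gain equation.

    All candidates within one call share the same replicate set, and the
    pairwise (1 - MIC) bootstrap means are cached per feature pair, so a
    full reduction computes each pair at most once.
    """

    def __init__(self, table: FeatureTable, config: GainConfig):
        self.table = table
        self.config = config
        self.ensemble = imbalance_adjusted_resample(
            table.y, B=config.B_reduce, seed=config.seed
        )
        self._rs_bar: np.ndarray | None = None
        self._mic_bar: dict[tuple[int, int], float] = {}

    @property
    def rs_bar(self) -> np.ndarray:
        """Bootstrap mean of (|)r_s(x_j, y)(|) for every column."""
        if self._rs_bar is None:
            X, y = self.table.X, self.table.y
            acc = np.zeros(X.shape[1])
            for idx in self.ensemble.in_bag:
                rx = rankdata(X[idx], axis=0)
                ry = rankdata(y[idx])
                rx = rx - rx.mean(axis=0)
                ry = ry - ry.mean()
                denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
                with np.errstate(invalid="ignore", divide="ignore"):
                    rs = (rx.T @ ry) / denom
                rs[~np.isfinite(rs)] = 0.0
                acc += np.abs(rs) if not self.config.signed_rs else rs
            self._rs_bar = acc / self.ensemble.B
        return self._rs_bar

    def mic_bar(self, c: int, j: int) -> float:
        """Bootstrap mean of 1 - MIC(x_c, x_j)."""
        key = (min(c, j), max(c, j))
        if key not in self._mic_bar:
            xc = self.table.X[:, c]
            xj = self.table.X[:, j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # resampled-constant columns
                vals = [
                    1.0 - mic(xc[idx], xj[idx], approx=self.config.mic_approx)
                    for idx in self.ensemble.in_bag
                ]
            self._mic_bar[key] = float(np.mean(vals))
        return self._mic_bar[key]

    def gains(self, remaining: list[int], selected: list[int]) -> np.ndarray:
        cfg = self.config
        g = cfg.gamma * self.rs_bar[remaining]
        if cfg.delta_a > 0 and selected:
            w = triangular_weights(len(selected))
            red = np.zeros(len(remaining))
            for wc, c in zip(w, selected):
                red += wc * np.array([self.mic_bar(c, j) for j in remaining])
            g = g + cfg.delta_a * red
        if cfg.delta_b > 0:
            D = len(remaining)
            term = np.array(
                [
                    np.mean([self.mic_bar(k, j) for k in remaining])
                    for j in remaining
                ]
            )
            g = g + cfg.delta_b * term
            _ = D  # normalisation is the mean over the D remaining features
        return g


def gain(
    candidate: str,
    state: ReductionState,
    table: FeatureTable,
    config: GainConfig,
    engine: GainEngine | None = None,
) -> float:
    """Gain of one remaining candidate given the current reduction state."""
    if candidate not in state.remaining:
        raise ValueError(f"candidate {candidate!r} is not in the remaining set")
    if not state.remaining:
        raise ValueError("remaining set is empty")
    engine = engine or GainEngine(table, config)
    sel_idx = [table.names.index(n) for n in state.selection_order]
    rem_idx = [table.names.index(n) for n in state.remaining]
    j = state.remaining.index(candidate)
    return float(engine.gains(rem_idx, sel_idx)[j])


def reduce_features(
    table: FeatureTable,
    config: GainConfig | None = None,
    engine: GainEngine | None = None,
) -> ReductionState:
    """Stepwise forward reduction to ``config.target_size`` features.

    Ties in gain break lexicographically by feature name. The returned
    ``selected`` list is ordered by descending gain at selection time
    (``selection_order`` preserves pick order).
    """
    config = config or GainConfig()
    if table.p < config.target_size:
        raise ValueError(
            f"table has {table.p} features, fewer than target_size="
            f"{config.target_size}"
        )
    engine = engine or GainEngine(table, config)
    remaining = list(range(table.p))
    selected: list[int] = []
    gains_at_selection: dict[str, float] = {}
    for _ in range(config.target_size):
        g = engine.gains(remaining, selected)
        best = max(
            range(len(remaining)),
            key=lambda i: (g[i], _neg_name(table.names[remaining[i]])),
        )
        j = remaining[best]
        gains_at_selection[table.names[j]] = float(g[best])
        selected.append(j)
        remaining.remove(j)
    order_names = [table.names[j] for j in selected]
    by_gain = sorted(
        order_names, key=lambda n: (-gains_at_selection[n], n)
    )
    return ReductionState(
        selected=by_gain,
        selection_order=order_names,
        gains=gains_at_selection,
        remaining=[table.names[j] for j in remaining],
    )


class _neg_name(str):
    """Reverse-ordering string wrapper so max() breaks ties lexicographically
    toward the smallest name."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def fuse_features(
    reduced_handcrafted: list[str],
    reduced_deep: list[str],
    expected_each: int = 25,
) -> list[str]:
    """Concatenate the two reduced sets, handcrafted first (50 by default)."""
    if len(reduced_handcrafted) != expected_each or len(reduced_deep) != expected_each:
        raise ValueError(
            f"expected {expected_each} features per reduced set, got "
            f"{len(reduced_handcrafted)} and {len(reduced_deep)}"
        )
    overlap = set(reduced_handcrafted) & set(reduced_deep)
    if overlap:
        raise ValueError(f"feature name collision between sets: {sorted(overlap)[:3]}")
    return list(reduced_handcrafted) + list(reduced_deep)
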