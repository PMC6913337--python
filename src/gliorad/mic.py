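"""Maximal information coefficient (MIC).

MIC(X, Y) = max over k x l grids with k*l <= B(n) of
I_grid(X; Y) / log2(min(k, l)), where I_grid is the mutual information of
the induced 2D histogram and B(n) = max(floor(n^0.6), 4). The floor at 4
keeps the 2x2 grid admissible at small n, matching common practice.

Two search strategies are provided:

* ``exhaustive`` -- enumerate every admissible grid whose cut points lie
  between distinct sorted values on both axes (exact; feasible for small
  n, used automatically for n <= 12).
* ``mine`` -- the MINE dynamic-programming approximation: one axis is
  equipartitioned into l rows, the other axis's column boundaries are
  optimized exactly by dynamic programming; both orientations are tried
  and the maximum taken.

For fixed rows the mutual information decomposes into a per-column
additive objective sum_r f(n_cr) - f(n_c) with f(z) = z log2 z, which is
what the DP maximizes.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np


def grid_budget(n: int, alpha: float = 0.6) -> int:
    return max(int(np.floor(n**alpha)), 4)


def _flogf(z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(z, dtype=float)
    pos = z > 0
    out[pos] = z[pos] * np.log2(z[pos])
    return out


def _norm_mi_from_counts(counts: np.ndarray) -> float:
    """I(X;Y)/log2(min(k,l)) for a k x l contingency table of counts."""
    n = counts.sum()
    obj = _flogf(counts).sum() - _flogf(counts.sum(axis=1)).sum()
    i_bits = (obj - _flogf(counts.sum(axis=0)).sum()) / n + np.log2(n)
    denom = np.log2(min(counts.shape))
    return float(i_bits / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# exhaustive search (exact; tiny n)
# ---------------------------------------------------------------------------

def _mic_exhaustive(x: np.ndarray, y: np.ndarray, B: int) -> float:
    n = len(x)
    ox = np.argsort(x, kind="mergesort")
    oy = np.argsort(y, kind="mergesort")
    # candidate cut positions: between distinct consecutive sorted values
    cx = [i for i in range(1, n) if x[ox[i - 1]] != x[ox[i]]]
    cy = [i for i in range(1, n) if y[oy[i - 1]] != y[oy[i]]]
    rank_x = np.empty(n, int)
    rank_x[ox] = np.arange(n)
    rank_y = np.empty(n, int)
    rank_y[oy] = np.arange(n)
    best = 0.0
    for k in range(2, B // 2 + 1):
        if len(cx) < k - 1:
            continue
        for l in range(2, B // k + 1):
            if len(cy) < l - 1:
                continue
            for xc in itertools.combinations(cx, k - 1):
                col = np.searchsorted(np.array(xc), rank_x, side="right")
                for yc in itertools.combinations(cy, l - 1):
                    row = np.searchsorted(np.array(yc), rank_y, side="right")
                    counts = np.zeros((k, l))
                    np.add.at(counts, (col, row), 1.0)
                    best = max(best, _norm_mi_from_counts(counts))
    return best


# ---------------------------------------------------------------------------
# MINE approximation
# ---------------------------------------------------------------------------

def _equipartition(v: np.ndarray, l: int) -> np.ndarray:
    """Assign each sample a row 0..l-1 with near-equal sizes; tied values
    share a row (the row of the group's middle element)."""
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    pos_row = (np.arange(n) * l) // n
    sv = v[order]
    edges = np.concatenate(([0], np.flatnonzero(sv[1:] != sv[:-1]) + 1, [n]))
    mids = (edges[:-1] + edges[1:] - 1) // 2
    rows = np.empty(n, dtype=np.int64)
    rows[order] = np.repeat(pos_row[mids], np.diff(edges))
    return rows


def _best_columns_dp(
    x: np.ndarray, rows: np.ndarray, l: int, kmax: int
) -> dict[int, float]:
    """For each k in 2..kmax, the max normalized MI over x-axis column
    partitions given fixed row assignment (rows in 0..l-1)."""
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    srows = rows[order]
    # boundary prefix positions between distinct x values (plus ends)
    cuts = [0] + [i for i in range(1, n) if sx[i - 1] != sx[i]] + [n]
    cuts = np.array(sorted(set(cuts)))
    m = len(cuts) - 1  # number of indivisible x-blocks
    if m < 2:
        return {}
    onehot = np.zeros((n, l))
    onehot[np.arange(n), srows] = 1.0
    cum = np.zeros((m + 1, l))
    cum[1:] = np.add.reduceat(onehot, cuts[:-1], axis=0).cumsum(axis=0)
    tot = cum.sum(axis=1)
    # val[s, t]: objective of a column spanning blocks (s, t]; only s < t
    # is a legal transition. Counts are integers, so f(z) = z log2 max(z, 1)
    # equals z log2 z with f(0) = 0 (and harmlessly zeroes the illegal
    # negative segments, which the -inf mask removes anyway).
    seg = cum[None, :, :] - cum[:, None, :]  # (m+1, m+1, l)
    val = (seg * np.log2(np.maximum(seg, 1.0))).sum(axis=2)
    segsum = tot[None, :] - tot[:, None]
    val -= segsum * np.log2(np.maximum(segsum, 1.0))
    idx = np.arange(m + 1)
    val[idx[:, None] >= idx[None, :]] = -np.inf
    row_term = _flogf(cum[-1]).sum()
    out: dict[int, float] = {}
    F = val[0, :].copy()  # k = 1: single column ending at block t
    for k in range(2, kmax + 1):
        # F_new[t] = max_s F[s] + val[s, t]
        with np.errstate(invalid="ignore"):
            F = (F[:, None] + val).max(axis=0)
        if not np.isfinite(F[m]):  # fewer than k divisible blocks
            break
        i_bits = (F[m] - row_term) / n + np.log2(n)
        denom = np.log2(min(k, l))
        if denom > 0:
            out[k] = float(i_bits / denom)
    return out


def _mic_mine(x: np.ndarray, y: np.ndarray, B: int) -> float:
    best = 0.0
    for a, b in ((x, y), (y, x)):
        for l in range(2, B // 2 + 1):
            rows = _equipartition(b, l)
            if len(np.unique(rows)) < 2:
                continue
            kmax = B // l
            if kmax < 2:
                continue
            scores = _best_columns_dp(a, rows, l, kmax)
            if scores:
                best = max(best, max(scores.values()))
    return best


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

_EXHAUSTIVE_MAX_N = 12


def mic(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.6,
    approx: str = "auto",
) -> float:
    """MIC between two numeric vectors, in [0, 1].

    approx='auto' uses the exhaustive search for n <= 12 and the MINE
    approximation beyond; 'exhaustive' / 'mine' force a strategy.
    Constant input returns 0 with a warning.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("MIC needs at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: MIC set to 0")
        return 0.0
    B = grid_budget(n, alpha)
    if approx == "auto":
        approx = "exhaustive" if n <= _EXHAUSTIVE_MAX_N else "mine"
    if approx == "exhaustive":
        val = _mic_exhaustive(x, y, B)
    elif approx == "mine":
        val = _mic_mine(x, y, B)
    else:
        raise ValueError(f"approx must be auto/exhaustive/mine, got {approx!r}")
    return float(min(max(val, 0.0), 1.0))
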