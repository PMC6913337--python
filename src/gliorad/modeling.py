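"""Imbalance-adjusted bootstrap resampling, the 0.632+ bootstrap AUC,
stepwise forward model selection, and bootstrap-averaged logistic models.

The prediction model is logistic regression on p selected features,
y(x_i) = a_0 + sum_j a_j x_ij, with class probability
p(y=1|x) = exp(y(x)) / (1 + exp(y(x))). Because the cohort is small and
imbalanced (16 necrosis vs 35 recurrence), every quantity is estimated
over B bootstrap replicates:

* imbalance-adjusted resampling -- each of the N draws first picks a
  class with probability 1/2 and then a uniform member of that class,
  so the minority class is not swamped; a "uniform" mode (plain
  with-replacement draws, expected distinct in-bag fraction 0.632) is
  also provided.
* 0.632+ bootstrap AUC -- per replicate, a model fit in-bag is scored on
  the out-of-bag (OOB) set; the estimate is the mean over replicates of
  (1 - alpha_b) * AUC_apparent + alpha_b * AUC'_b with
  AUC'_b = max(0.5, AUC_oob), alpha_b = 0.632 / (1 - 0.368 R_b) and R_b
  the relative overfitting rate.
* model selection -- greedy forward growth from every starter feature,
  each step adding the feature maximising the 0.632+ AUC; per model
  order (1..10) the best combination over all starters is kept and the
  order with the maximum averaged AUC wins.
* final model -- per-replicate in-bag coefficients averaged element-wise
  (including the intercept).

Features are z-scored with whole-sample statistics before fitting so the
averaged coefficients live on a common scale, and a small ridge penalty
on the slopes keeps fits finite under separation (common at in-bag
n ~ 32 with up to 10 features).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .handcrafted import FeatureTable

DEFAULT_RIDGE = 1e-4
_MAX_RETRIES = 100


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BootstrapEnsemble:
    """B in-bag index multisets (each of size N) with their OOB complements.

    Every retained replicate has both classes in-bag and both classes
    out-of-bag (degenerate draws are redrawn at generation time).
    """

    B: int
    N: int
    in_bag: np.ndarray  # (B, N) int indices
    oob: list[np.ndarray]
    seed: int
    mode: str

    def __post_init__(self):
        if self.in_bag.shape != (self.B, self.N):
            raise ValueError("in_bag must be (B, N)")


def imbalance_adjusted_resample(
    labels: np.ndarray,
    B: int,
    seed: int,
    mode: str = "imbalance",
    max_retries: int = _MAX_RETRIES,
) -> BootstrapEnsemble:
    """Draw B bootstrap replicates of the N patients.

    mode='imbalance': each draw picks a class with probability 1/2, then
    a uniform member of that class. mode='uniform': plain uniform draws
    with replacement (the 51 x 0.632 ~ 32 in-bag / ~ 19 OOB arithmetic).
    Replicates whose in-bag or OOB set lacks a class are redrawn, up to
    ``max_retries`` times each.
    """
    y = np.asarray(labels, int)
    N = len(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to resample")
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("imbalance", "uniform"):
        raise ValueError(f"mode must be 'imbalance' or 'uniform', got {mode!r}")
    rng = np.random.default_rng(seed)

    def draw() -> np.ndarray:
        if mode == "uniform":
            return rng.integers(0, N, size=N)
        pick_pos = rng.random(N) < 0.5
        out = np.empty(N, dtype=np.int64)
        n_pos = int(pick_pos.sum())
        out[pick_pos] = rng.choice(pos, size=n_pos, replace=True)
        out[~pick_pos] = rng.choice(neg, size=N - n_pos, replace=True)
        return out

    # cohorts of >= 2 per class admit the strict contract (both classes
    # in-bag and out-of-bag); tiny degenerate cohorts fall back to the
    # weakest usable requirement (non-empty OOB) so the size contract holds
    strict = min(len(pos), len(neg)) >= 2

    in_bag = np.empty((B, N), dtype=np.int64)
    oob: list[np.ndarray] = []
    for b in range(B):
        fallback = None
        for attempt in range(max_retries + 1):
            bag = draw()
            bag_mask = np.zeros(N, dtype=bool)
            bag_mask[bag] = True
            out = np.flatnonzero(~bag_mask)
            if out.size > 0 and fallback is None:
                fallback = (bag, out)
            ok = (
                out.size > 0
                and len(np.unique(y[out])) == 2
                and len(np.unique(y[bag])) == 2
            )
            if ok:
                break
        else:
            if strict or fallback is None:
                raise RuntimeError(
                    f"replicate {b}: could not draw a valid split in "
                    f"{max_retries} retries"
                )
            warnings.warn(
                "cohort too small for two-class out-of-bag sets; replicate "
                "retained with a degenerate split"
            )
            bag, out = fallback
        in_bag[b] = bag
        oob.append(out)
    return BootstrapEnsemble(B=B, N=N, in_bag=in_bag, oob=oob, seed=seed, mode=mode)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# logistic fitting (IRLS with ridge on slopes)
# ---------------------------------------------------------------------------

def _irls(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 60, tol: float = 1e-9
) -> np.ndarray:
    """Single-problem IRLS. X excludes the intercept column."""
    n, p = X.shape
    # zero-variance columns are zeroed: with zero init and ridge their
    # coefficient stays exactly 0, equivalent to dropping the column
    sd = X.std(axis=0)
    Xw = np.where(sd > 0, X, 0.0)
    A = np.hstack([np.ones((n, 1)), Xw])
    beta = np.zeros(p + 1)
    pen = np.diag([0.0] + [ridge] * p)
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        AtW = A.T * w
        new = np.linalg.solve(AtW @ A + pen, AtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def _irls_batch(
    Xb: np.ndarray, yb: np.ndarray, ridge: float, max_iter: int = 40, tol: float = 1e-8
) -> np.ndarray:
    """Batched IRLS over B replicate designs: Xb (B, n, p), yb (B, n).

    Returns (B, p+1) coefficients (intercept first). Zero-variance
    columns are zeroed per replicate, which pins their coefficient at 0.
    """
    B, n, p = Xb.shape
    sd = Xb.std(axis=1, keepdims=True)  # (B, 1, p)
    Xz = np.where(sd > 0, Xb, 0.0)
    A = np.concatenate([np.ones((B, n, 1)), Xz], axis=2)  # (B, n, p+1)
    beta = np.zeros((B, p + 1))
    pen = np.diag([0.0] + [ridge] * p)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(np.einsum("bnk,bk->bn", A, beta), -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (yb - mu) / w
        AtW = A.transpose(0, 2, 1) * w[:, None, :]  # (B, p+1, n)
        H = AtW @ A + pen[None]
        rhs = np.einsum("bkn,bn->bk", AtW, z)
        new = np.linalg.solve(H, rhs[..., None])[..., 0]
        delta = np.max(np.abs(new - beta), axis=1)
        beta = new
        active = delta >= tol
        if not active.any():
            break
    return beta


def fit_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Ridge-stabilised ML logistic fit; returns (a_0, a_1, ..., a_p).

    The intercept is unpenalised; with p = 0 this reduces to the
    intercept-only fit a_0 = log(n_1 / n_0) as ridge -> 0.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.zeros((len(y), 0))
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a logistic fit")
    return _irls(X, y, ridge)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


# ---------------------------------------------------------------------------
# 0.632+ bootstrap AUC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Auc632Result:
    apparent_auc: float
    oob_auc: np.ndarray        # per-replicate AUC(x*b, x*b(0))
    auc_prime: np.ndarray      # max(0.5, oob_auc)
    R: np.ndarray              # relative overfitting rate, in [0, 1]
    alpha: np.ndarray          # 0.632 / (1 - 0.368 R), in [0.632, 1]
    estimate: float

    def __post_init__(self):
        if not ((self.alpha >= 0.632 - 1e-12) & (self.alpha <= 1 + 1e-12)).all():
            raise ValueError("alpha_b out of [0.632, 1]")
        if not ((self.R >= 0) & (self.R <= 1)).all():
            raise ValueError("R_b out of [0, 1]")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def combine_632plus(
    apparent: float,
    oob_auc: np.ndarray,
    overfitting_rule: str = "standard",
) -> Auc632Result:
    """Apply the 0.632+ weighting to per-replicate OOB AUCs.

    overfitting_rule='standard' uses the relative-overfitting-rate
    reading: R_b interpolates (apparent - oob) / (apparent - 0.5) when
    the OOB AUC lies between 0.5 and the apparent AUC, is 1 when the OOB
    AUC falls below 0.5, and 0 otherwise. overfitting_rule='ratio' keeps
    the literal published condition 1 < apparent/oob < 2 for the
    interpolating branch.
    """
    oob_auc = np.asarray(oob_auc, float)
    auc_prime = np.maximum(0.5, oob_auc)
    R = np.zeros_like(oob_auc)
    below = oob_auc < 0.5
    R[below] = 1.0
    if overfitting_rule == "standard":
        interp = (~below) & (oob_auc < apparent) & (apparent > 0.5)
    elif overfitting_rule == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(oob_auc > 0, apparent / oob_auc, np.inf)
        interp = (~below) & (ratio > 1.0) & (ratio < 2.0) & (apparent > 0.5)
    else:
        raise ValueError("overfitting_rule must be 'standard' or 'ratio'")
    denom = apparent - 0.5
    if denom > 0:
        R[interp] = (apparent - oob_auc[interp]) / denom
    R = np.clip(R, 0.0, 1.0)
    alpha = 0.632 / (1.0 - 0.368 * R)
    estimate = float(np.mean((1.0 - alpha) * apparent + alpha * auc_prime))
    return Auc632Result(
        apparent_auc=float(apparent),
        oob_auc=oob_auc,
        auc_prime=auc_prime,
        R=R,
        alpha=alpha,
        estimate=estimate,
    )


def auc_632plus(
    features: Sequence[str],
    table: FeatureTable,
    ensemble: BootstrapEnsemble,
    ridge: float = DEFAULT_RIDGE,
    overfitting_rule: str = "standard",
) -> Auc632Result:
    """0.632+ bootstrap AUC of the logistic model on ``features``."""
    missing = [f for f in features if f not in table.names]
    if missing:
        raise KeyError(f"features not in table: {missing[:3]}")
    cols = [table.names.index(f) for f in features]
    Xz, _, _ = _standardize(table.X[:, cols])
    y = table.y.astype(float)

    apparent_beta = _irls(Xz, y, ridge)
    apparent_scores = _sigmoid(apparent_beta[0] + Xz @ apparent_beta[1:])
    apparent = auc(apparent_scores, table.y)

    betas = _irls_batch(Xz[ensemble.in_bag], y[ensemble.in_bag], ridge)
    oob_auc = np.empty(ensemble.B)
    for b, out in enumerate(ensemble.oob):
        s = _sigmoid(betas[b, 0] + Xz[out] @ betas[b, 1:])
        oob_auc[b] = auc(s, table.y[out])
    return combine_632plus(apparent, oob_auc, overfitting_rule)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelSearchResult:
    per_order: dict[int, tuple[tuple[str, ...], float]]  # order -> (features, AUC)
    chosen_order: int

    @property
    def chosen_features(self) -> tuple[str, ...]:
        return self.per_order[self.chosen_order][0]

    @property
    def chosen_auc(self) -> float:
        return self.per_order[self.chosen_order][1]


def forward_select(
    reduced: Sequence[str],
    table: FeatureTable,
    ensemble: BootstrapEnsemble,
    orders: Sequence[int] = tuple(range(1, 11)),
    starters: Sequence[str] | None = None,
    ridge: float = DEFAULT_RIDGE,
    overfitting_rule: str = "standard",
) -> ModelSearchResult:
    """Greedy forward growth from every starter, scored by 0.632+ AUC.

    ``reduced`` is the rank-ordered reduced feature set; starters default
    to all of it. Each starter grows greedily to the maximum order; per
    order, the best combination over all starters is retained. Ties break
    toward the earlier reduced-set rank. The chosen order maximises the
    per-order AUC (ties toward the smaller order).
    """
    reduced = list(reduced)
    orders = sorted(orders)
    if orders[-1] > len(reduced):
        raise ValueError(
            f"max order {orders[-1]} exceeds the {len(reduced)} reduced features"
        )
    starters = list(starters) if starters is not None else list(reduced)
    unknown = set(starters) - set(reduced)
    if unknown:
        raise ValueError(f"starters not in the reduced set: {sorted(unknown)[:3]}")
    rank = {name: i for i, name in enumerate(reduced)}

    cache: dict[frozenset, float] = {}

    def score(combo: tuple[str, ...]) -> float:
        key = frozenset(combo)
        if key not in cache:
            cache[key] = auc_632plus(
                combo, table, ensemble, ridge=ridge,
                overfitting_rule=overfitting_rule,
            ).estimate
        return cache[key]

    best_per_order: dict[int, tuple[tuple[str, ...], float]] = {}

    def offer(order: int, combo: tuple[str, ...], val: float) -> None:
        cur = best_per_order.get(order)
        if cur is None or val > cur[1]:
            best_per_order[order] = (combo, val)
        elif val == cur[1]:
            # tie: prefer the combination with earlier reduced-set ranks
            if sorted(rank[f] for f in combo) < sorted(rank[f] for f in cur[0]):
                best_per_order[order] = (combo, val)

    max_order = orders[-1]
    for starter in sorted(starters, key=rank.get):
        combo: tuple[str, ...] = (starter,)
        val = score(combo)
        if 1 in orders:
            offer(1, combo, val)
        for order in range(2, max_order + 1):
            candidates = [f for f in reduced if f not in combo]
            if not candidates:
                break
            best_f, best_v = None, -np.inf
            for f in candidates:  # reduced-rank order: ties keep earliest
                v = score(combo + (f,))
                if v > best_v:
                    best_f, best_v = f, v
            combo = combo + (best_f,)
            val = best_v
            if order in orders:
                offer(order, combo, val)

    return ModelSearchResult(
        per_order=best_per_order, chosen_order=choose_order(best_per_order)
    )


def choose_order(per_order: dict[int, tuple[tuple[str, ...], float]]) -> int:
    """Order with the maximum 0.632+ AUC; ties go to the smaller order."""
    if not per_order:
        raise ValueError("no per-order results")
    best = None
    for order in sorted(per_order):
        val = per_order[order][1]
        if best is None or val > per_order[best][1]:
            best = order
    return best


def exhaustive_select(
    reduced: Sequence[str],
    table: FeatureTable,
    ensemble: BootstrapEnsemble,
    orders: Sequence[int],
    ridge: float = DEFAULT_RIDGE,
) -> ModelSearchResult:
    """Brute-force search over all combinations (small instances only)."""
    per_order: dict[int, tuple[tuple[str, ...], float]] = {}
    for order in sorted(orders):
        best = None
        for combo in itertools.combinations(reduced, order):
            val = auc_632plus(combo, table, ensemble, ridge=ridge).estimate
            if best is None or val > best[1]:
                best = (combo, val)
        per_order[order] = best
    return ModelSearchResult(per_order=per_order, chosen_order=choose_order(per_order))


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FittedModel:
    """Bootstrap-averaged logistic model on standardised features."""

    features: list[str]
    coefficients: np.ndarray  # (p+1,), intercept first, on the z-scale
    feature_means: np.ndarray
    feature_sds: np.ndarray
    ridge: float = DEFAULT_RIDGE
    B: int = 0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape != (len(self.features) + 1,):
            raise ValueError("coefficient count must be p + 1")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    @property
    def order(self) -> int:
        return len(self.features)

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.order:
            raise ValueError(
                f"expected {self.order} features, got {x.shape[1]}"
            )
        z = (x - self.feature_means) / self.feature_sds
        return self.coefficients[0] + z @ self.coefficients[1:]

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "ridge": self.ridge,
            "B": self.B,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            features=list(d["features"]),
            coefficients=np.asarray(d["coefficients"], float),
            feature_means=np.asarray(d["feature_means"], float),
            feature_sds=np.asarray(d["feature_sds"], float),
            ridge=float(d.get("ridge", DEFAULT_RIDGE)),
            B=int(d.get("B", 0)),
        )


def average_coefficients(
    features: Sequence[str],
    table: FeatureTable,
    ensemble: BootstrapEnsemble,
    ridge: float = DEFAULT_RIDGE,
) -> FittedModel:
    """Element-wise mean of per-replicate in-bag coefficients."""
    cols = [table.names.index(f) for f in features]
    Xz, mean, sd = _standardize(table.X[:, cols])
    y = table.y.astype(float)
    betas = _irls_batch(Xz[ensemble.in_bag], y[ensemble.in_bag], ridge)
    return FittedModel(
        features=list(features),
        coefficients=betas.mean(axis=0),
        feature_means=mean,
        feature_sds=sd,
        ridge=ridge,
        B=ensemble.B,
    )


def predict_probability(model: FittedModel, x) -> np.ndarray | float:
    """Class-1 (necrosis) probability via the logistic transform.

    ``x`` may be a mapping feature name -> value, a vector in the model's
    feature order, or a FeatureTable (scored row-wise).
    """
    if isinstance(x, FeatureTable):
        missing = [f for f in model.features if f not in x.names]
        if missing:
            raise KeyError(f"feature {missing[0]!r} missing from table")
        arr = np.column_stack([x.column(f) for f in model.features])
        return _sigmoid(model.linear_predictor(arr))
    if isinstance(x, dict):
        missing = [f for f in model.features if f not in x]
        if missing:
            raise KeyError(f"feature {missing[0]!r} missing from input")
        arr = np.array([[x[f] for f in model.features]])
        return float(_sigmoid(model.linear_predictor(arr))[0])
    arr = np.atleast_2d(np.asarray(x, float))
    out = _sigmoid(model.linear_predictor(arr))
    return float(out[0]) if out.size == 1 else out
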