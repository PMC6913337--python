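"""Ensemble evaluation: per-replicate training/validation metrics and
paired comparisons between feature-set models.

For each bootstrap replicate the model is refit on the in-bag multiset
("training" role) and scored on both the in-bag multiset and the
out-of-bag set ("validation" role). AUC, sensitivity, specificity and
accuracy are recorded per replicate (necrosis = 1 is the positive class;
probability >= threshold predicts positive), then summarised as mean
with both SD and SE of the mean (error bars elsewhere use SE at the 95%
confidence level, i.e. 1.96 SE). Feature-set models aligned on the same
ensemble are compared with paired t-tests.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .handcrafted import FeatureTable
from .modeling import (
    BootstrapEnsemble,
    _irls_batch,
    _sigmoid,
    _standardize,
    auc,
    DEFAULT_RIDGE,
)

METRICS = ("AUC", "Se", "Sp", "Acc")
ROLES = ("training", "validation")


def sens_spec_acc(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at a probability threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(labels, int)
    pred = np.asarray(scores, float) >= threshold
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return tp / n_pos, tn / n_neg, (tp + tn) / len(y)


@dataclasses.dataclass
class MetricSet:
    """Per-replicate metric vectors for both roles, with summaries."""

    values: dict[tuple[str, str], np.ndarray]  # (role, metric) -> (B,)
    B: int

    def __post_init__(self):
        for key, v in self.values.items():
            if v.shape != (self.B,):
                raise ValueError(f"vector for {key} must have length B={self.B}")
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"metric {key} outside [0, 1]")

    def mean(self, role: str, metric: str) -> float:
        return float(self.values[(role, metric)].mean())

    def sd(self, role: str, metric: str) -> float:
        return float(self.values[(role, metric)].std(ddof=1))

    def se(self, role: str, metric: str) -> float:
        return self.sd(role, metric) / np.sqrt(self.B)

    def summary(self) -> pd.DataFrame:
        rows = []
        for role in ROLES:
            for metric in METRICS:
                rows.append(
                    {
                        "role": role,
                        "metric": metric,
                        "mean": self.mean(role, metric),
                        "sd": self.sd(role, metric),
                        "se": self.se(role, metric),
                        "ci95_half_width": 1.96 * self.se(role, metric),
                        "B": self.B,
                    }
                )
        return pd.DataFrame(rows)


def evaluate_ensemble(
    features: Sequence[str],
    table: FeatureTable,
    ensemble: BootstrapEnsemble,
    threshold: float = 0.5,
    ridge: float = DEFAULT_RIDGE,
) -> MetricSet:
    """Refit per replicate; training metrics in-bag, validation OOB."""
    cols = [table.names.index(f) for f in features]
    Xz, _, _ = _standardize(table.X[:, cols])
    y = table.y
    betas = _irls_batch(
        Xz[ensemble.in_bag], y[ensemble.in_bag].astype(float), ridge
    )
    vals = {
        (role, metric): np.empty(ensemble.B) for role in ROLES for metric in METRICS
    }
    for b in range(ensemble.B):
        for role, idx in (
            ("training", ensemble.in_bag[b]),
            ("validation", ensemble.oob[b]),
        ):
            s = _sigmoid(betas[b, 0] + Xz[idx] @ betas[b, 1:])
            vals[(role, "AUC")][b] = auc(s, y[idx])
            se_, sp_, acc_ = sens_spec_acc(s, y[idx], threshold)
            vals[(role, "Se")][b] = se_
            vals[(role, "Sp")][b] = sp_
            vals[(role, "Acc")][b] = acc_
    return MetricSet(values=vals, B=ensemble.B)


@dataclasses.dataclass
class ComparisonResult:
    metric: str
    t_statistic: float
    p_value: float
    n_replicates: int
    degenerate: bool = False


def paired_ttest(
    metric_a: np.ndarray, metric_b: np.ndarray, metric: str = ""
) -> ComparisonResult:
    """Two-sided paired t-test of replicate-aligned metric vectors.

    Identical vectors (zero-variance, zero-mean differences) return
    p = 1 with the degenerate flag; zero-variance differences around a
    nonzero mean return p = 0 (the t statistic diverges).
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must be equal-length with >= 2 replicates")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return ComparisonResult(metric, 0.0, 1.0, a.size, degenerate=True)
        sign = np.sign(d.mean())
        return ComparisonResult(metric, float(sign * np.inf), 0.0, a.size,
                                degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return ComparisonResult(metric, float(t), float(p), a.size)


def compare_metricsets(
    ms_a: MetricSet, ms_b: MetricSet, role: str = "validation"
) -> pd.DataFrame:
    rows = []
    for metric in METRICS:
        r = paired_ttest(ms_a.values[(role, metric)], ms_b.values[(role, metric)],
                         metric)
        rows.append(dataclasses.asdict(r))
    return pd.DataFrame(rows)


def auc_trace(metricset: MetricSet) -> pd.DataFrame:
    """Long-format (replicate, role, AUC) table, one row per replicate/role."""
    rows = []
    for role in ROLES:
        v = metricset.values[(role, "AUC")]
        for b in range(metricset.B):
            rows.append({"replicate": b, "role": role, "AUC": v[b]})
    return pd.DataFrame(rows)
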