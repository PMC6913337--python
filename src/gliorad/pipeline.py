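"""End-to-end orchestration.

Binds the stages -- simulate/extract -> univariate screen -> gain
reduction -> fusion -> 0.632+ forward selection -> bootstrap-averaged
fit -> ensemble evaluation -- under a single declarative config with one
master seed. Per-stage seeds are derived from the master seed via
``numpy.random.SeedSequence`` so any stage can be reproduced in
isolation, and every artifact records the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import numpy as np
import yaml

from .evaluation import evaluate_ensemble
from .handcrafted import FeatureTable, default_grid, small_grid
from .modeling import (
    average_coefficients,
    forward_select,
    imbalance_adjusted_resample,
)
from .reduction import GainConfig, fuse_features, reduce_features
from .synthetic import TableSpec, generate_feature_table
from .univariate import screen

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    output_dir: str = "gliorad_out"
    seed: int = 0
    # exactly one input route: a feature CSV, study directories, or synthesis
    feature_csv: str | None = None
    deep_feature_csv: str | None = None
    study_dirs: list[str] | None = None
    synthetic: dict | None = None
    grid: str = "small"  # 'small' | 'default' (texture grid for extraction)
    deep_backend: str | None = "stub-alexnet"
    gain: GainConfig = dataclasses.field(default_factory=GainConfig)
    B: int = 1000
    resample_mode: str = "imbalance"
    orders: tuple[int, ...] = tuple(range(1, 11))
    n_starters: int | None = None
    threshold: float = 0.5
    alpha: float = 0.05

    def validate(self) -> None:
        routes = [
            self.feature_csv is not None,
            self.study_dirs is not None,
            self.synthetic is not None,
        ]
        if sum(routes) != 1:
            raise ValueError(
                "exactly one of feature_csv / study_dirs / synthetic must be set"
            )
        if self.feature_csv and not os.path.exists(self.feature_csv):
            raise FileNotFoundError(self.feature_csv)
        if self.deep_feature_csv and not os.path.exists(self.deep_feature_csv):
            raise FileNotFoundError(self.deep_feature_csv)
        for d in self.study_dirs or []:
            if not os.path.isdir(d):
                raise FileNotFoundError(d)
        if self.grid not in ("small", "default"):
            raise ValueError("grid must be 'small' or 'default'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gain"] = dataclasses.asdict(self.gain)
        d["orders"] = list(self.orders)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "gain" in d and isinstance(d["gain"], dict):
            d["gain"] = GainConfig(**d["gain"])
        if "orders" in d:
            d["orders"] = tuple(d["orders"])
        if "study_dirs" in d and d["study_dirs"] is not None:
            d["study_dirs"] = list(d["study_dirs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is where
        artifacts land, not part of what they contain)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _load_tables(
    config: PipelineConfig, seeds: list[int]
) -> tuple[FeatureTable, FeatureTable | None]:
    """Resolve (handcrafted_table, deep_table-or-None) from the input route."""
    if config.feature_csv is not None:
        hand = FeatureTable.from_csv(config.feature_csv)
        deep = (
            FeatureTable.from_csv(config.deep_feature_csv)
            if config.deep_feature_csv
            else None
        )
        return hand, deep
    if config.study_dirs is not None:
        from .deep import extract_deep_table, get_backend
        from .handcrafted import extract_handcrafted_table
        from .synthetic import load_study

        studies = [load_study(d) for d in config.study_dirs]
        grid = default_grid() if config.grid == "default" else small_grid()
        hand = extract_handcrafted_table(studies, grid=grid)
        deep = (
            extract_deep_table(studies, get_backend(config.deep_backend))
            if config.deep_backend
            else None
        )
        return hand, deep
    spec = dict(config.synthetic or {})
    spec.setdefault("seed", seeds[0])
    informative = spec.pop("informative_idx", (0, 1, 2))
    hand = generate_feature_table(
        TableSpec(informative_idx=tuple(informative), **spec)
    )
    deep_spec = dict(spec)
    deep_spec["seed"] = seeds[0] + 1
    deep_spec["name_prefix"] = "d"
    deep = generate_feature_table(
        TableSpec(informative_idx=tuple(informative), **deep_spec)
    )
    return hand, deep


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all intermediate artifacts.

    Returns the run report (also written to ``report.json``).
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731
    meta = {"config_hash": config.config_hash(), "seed": config.seed}

    hand, deep = _load_tables(config, seeds)
    hand.to_csv(out("features_handcrafted.csv"))
    if deep is not None:
        deep.to_csv(out("features_deep.csv"))
    logger.info("tables: handcrafted %dx%d, deep %s", hand.n, hand.p,
                f"{deep.n}x{deep.p}" if deep is not None else "none")

    uni = screen(hand, alpha=config.alpha)
    uni.to_csv(out("univariate.csv"), index=False)

    gain_cfg = dataclasses.replace(config.gain, seed=seeds[1])
    red_hand = reduce_features(hand, gain_cfg)
    reduced_payload = {
        "handcrafted": {"selected": red_hand.selected, "gains": red_hand.gains},
        **meta,
    }
    if deep is not None:
        red_deep = reduce_features(deep, dataclasses.replace(gain_cfg, seed=seeds[2]))
        fused = fuse_features(
            red_hand.selected, red_deep.selected,
            expected_each=gain_cfg.target_size,
        )
        reduced_payload["deep"] = {
            "selected": red_deep.selected, "gains": red_deep.gains
        }
        reduced_payload["fused"] = fused
        work_table = FeatureTable.concat(hand, deep).subset(fused)
        pool = fused
    else:
        work_table = hand.subset(red_hand.selected)
        pool = red_hand.selected
    with open(out("reduced.json"), "w") as fh:
        json.dump(reduced_payload, fh, indent=1)

    ensemble = imbalance_adjusted_resample(
        work_table.y, B=config.B, seed=seeds[3], mode=config.resample_mode
    )
    orders = tuple(o for o in config.orders if o <= len(pool))
    starters = pool[: config.n_starters] if config.n_starters else None
    search = forward_select(
        pool, work_table, ensemble, orders=orders, starters=starters
    )
    with open(out("selection.json"), "w") as fh:
        json.dump(
            {
                "per_order": {
                    str(o): {"features": list(c), "auc_632plus": v}
                    for o, (c, v) in sorted(search.per_order.items())
                },
                "chosen_order": search.chosen_order,
                **meta,
            },
            fh,
            indent=1,
        )

    model = average_coefficients(search.chosen_features, work_table, ensemble)
    with open(out("model.json"), "w") as fh:
        json.dump({**model.to_dict(), **meta}, fh, indent=1)

    metrics = evaluate_ensemble(
        search.chosen_features, work_table, ensemble, threshold=config.threshold
    )
    metrics.summary().to_csv(out("metrics.csv"), index=False)

    report = {
        **meta,
        "n_patients": hand.n,
        "n_handcrafted": hand.p,
        "n_deep": deep.p if deep is not None else 0,
        "reduced_size": len(red_hand.selected),
        "pool_size": len(pool),
        "chosen_order": search.chosen_order,
        "chosen_features": list(search.chosen_features),
        "auc_632plus": search.chosen_auc,
        "validation_auc_mean": metrics.mean("validation", "AUC"),
        "validation_auc_se": metrics.se("validation", "AUC"),
        "training_auc_mean": metrics.mean("training", "AUC"),
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report
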