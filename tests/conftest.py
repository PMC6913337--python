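import numpy as np
import pytest

import gliorad as g


@pytest.fixture(scope="session")
def phantom_pair():
    """One study per class on a small grid (shared across tests)."""
    cfg = g.PhantomConfig(grid_shape=(24, 24, 24), lesion_radius=6.0, seed=5)
    return g.generate_phantom(cfg, 0), g.generate_phantom(cfg, 1)


@pytest.fixture(scope="session")
def informative_table():
    """51-patient (16/35) table, 12 features, 3 informative at effect 2."""
    return g.generate_feature_table(
        g.TableSpec(
            n_pos=16, n_neg=35, p_features=12,
            informative_idx=(0, 1, 2), effect_size=2.0, seed=1,
        )
    )


@pytest.fixture(scope="session")
def small_ensemble(informative_table):
    return g.imbalance_adjusted_resample(informative_table.y, B=100, seed=3)


def make_roi(seed: int, shape=(4, 4, 4), n_gray: int = 3, p_mask: float = 0.7):
    """Random small quantized ROI for oracle comparisons."""
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_gray + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return levels, mask
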