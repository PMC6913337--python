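"""Deep-feature extraction contract with pluggable backends.

The pipeline's deep path forwards an RGB image -- three consecutive
axial slices around the largest tumor area, cropped to the bounding box
and resized to the network's input side -- through a fixed pretrained
CNN and reads a late layer: FC7 for an AlexNet-style backend (4,096
units, 227 px input) or the average-pooling layer for an Inception-v3
style backend (2,048 units, 299 px input). Per study the per-modality
vectors are concatenated, so four modalities give 16,384 AlexNet-style
or 8,192 Inception-style features (24,576 with both).

Pretrained weights are deliberately not bundled. The registry ships a
deterministic stub backend -- a seeded random linear projection of the
downsampled input -- which honours the dimension contract and is
approximately distance-preserving, so class-separable images map to
class-separable features; any user-supplied callable with the right
output dimension can be registered as a real backend.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize

from .preprocess import SliceTriplet, largest_area_slice_triplet
from .synthetic import MultimodalStudy


@dataclasses.dataclass
class DeepBackendSpec:
    """Contract for one deep-feature backend.

    ``extractor`` maps a (side, side, 3) float image in [0, 1] to a 1D
    vector of length ``dim`` and must be deterministic for fixed input.
    ``layer_tag`` is used in feature names (e.g. 'F7' so names read like
    F7_T1C_0618, following the layer_neuron convention).
    """

    name: str
    side: int
    dim: int
    extractor: Callable[[np.ndarray], np.ndarray]
    layer_tag: str = "deep"

    def __post_init__(self):
        if self.dim <= 0 or self.side <= 0:
            raise ValueError("side and dim must be positive")


def assemble_rgb_input(triplet: SliceTriplet, side: int) -> np.ndarray:
    """Stack (previous, central, next) as channels, resize, scale to [0,1].

    Each channel is bilinearly resized to side x side and min-max scaled
    independently; a zero-range channel becomes all zeros with a warning.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    channels = []
    for name, sl in (
        ("previous", triplet.previous),
        ("central", triplet.central),
        ("next", triplet.next),
    ):
        r = resize(
            np.asarray(sl, float), (side, side), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        lo, hi = r.min(), r.max()
        if hi > lo:
            r = (r - lo) / (hi - lo)
        else:
            warnings.warn(f"zero-range {name} slice: channel set to zeros")
            r = np.zeros_like(r)
        channels.append(r)
    return np.stack(channels, axis=-1)


def _stub_extractor(name: str, side: int, dim: int) -> Callable[[np.ndarray], np.ndarray]:
    """Seeded random projection: downsample to 16x16x3, project to `dim`.

    The projection matrix is derived from the backend name and dimension
    only, so features are reproducible across sessions and machines.
    """
    seed_words = [abs(hash_str(name)) % (2**31), dim, side]
    rng = np.random.default_rng(np.random.SeedSequence(seed_words))
    k = 16 * 16 * 3
    W = rng.standard_normal((k + 1, dim)) / np.sqrt(k)

    def extract(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, float)
        if img.shape != (side, side, 3):
            raise ValueError(f"expected ({side}, {side}, 3) input, got {img.shape}")
        small = resize(img, (16, 16, 3), order=1, mode="edge",
                       anti_aliasing=True, preserve_range=True)
        x = np.concatenate([small.ravel(), [1.0]])
        return x @ W

    return extract


def hash_str(s: str) -> int:
    """Stable (non-salted) string hash, unlike builtin hash()."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def stub_backend(kind: str = "alexnet") -> DeepBackendSpec:
    if kind == "alexnet":
        return DeepBackendSpec(
            name="stub-alexnet", side=227, dim=4096,
            extractor=_stub_extractor("stub-alexnet", 227, 4096), layer_tag="F7",
        )
    if kind == "inception":
        return DeepBackendSpec(
            name="stub-inception", side=299, dim=2048,
            extractor=_stub_extractor("stub-inception", 299, 2048),
            layer_tag="avg_pool",
        )
    raise ValueError(f"unknown stub kind {kind!r}; use 'alexnet' or 'inception'")


_REGISTRY: dict[str, Callable[[], DeepBackendSpec]] = {
    "stub": lambda: stub_backend("alexnet"),
    "stub-alexnet": lambda: stub_backend("alexnet"),
    "stub-inception": lambda: stub_backend("inception"),
}


def register_backend(name: str, factory: Callable[[], DeepBackendSpec]) -> None:
    _REGISTRY[name] = factory


def get_backend(name: str) -> DeepBackendSpec:
    if name in _REGISTRY:
        return _REGISTRY[name]()
    if name in ("alexnet", "inception"):
        raise RuntimeError(
            f"backend {name!r} requires pretrained weights that are not "
            f"bundled; use 'stub-{name}' for the deterministic stub, or "
            f"register_backend() with your own extractor"
        )
    raise KeyError(f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}")


def extract_deep(
    study: MultimodalStudy,
    backend: DeepBackendSpec,
    modalities: Sequence[str] | None = None,
) -> dict[str, float]:
    """One backend-dimension vector per modality, concatenated.

    Feature names encode layer tag, modality and unit index, e.g.
    ``F7_T1C_0618``.
    """
    modalities = list(modalities or study.volumes.keys())
    out: dict[str, float] = {}
    for modality in modalities:
        triplet = largest_area_slice_triplet(study, modality)
        img = assemble_rgb_input(triplet, backend.side)
        vec = np.asarray(backend.extractor(img), dtype=float).ravel()
        if vec.shape != (backend.dim,):
            raise ValueError(
                f"backend {backend.name!r} returned {vec.shape}, expected "
                f"({backend.dim},)"
            )
        width = len(str(backend.dim - 1))
        for i, v in enumerate(vec):
            out[f"{backend.layer_tag}_{modality}_{i:0{width}d}"] = float(v)
    return out


def extract_deep_table(
    studies: Sequence[MultimodalStudy],
    backend: DeepBackendSpec,
    modalities: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
):
    from .handcrafted import FeatureTable

    rows = [extract_deep(s, backend, modalities=modalities) for s in studies]
    names = list(rows[0].keys())
    X = np.array([[r[n] for n in names] for r in rows], dtype=float)
    ids = list(ids) if ids is not None else [f"P{i + 1:03d}" for i in range(len(rows))]
    y = np.array([s.label for s in studies], dtype=int)
    return FeatureTable(ids=ids, names=names, X=X, y=y)
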