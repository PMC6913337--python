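"""Deterministic ROI geometry and image-conditioning operators.

These feed both feature-extraction paths: the handcrafted texture grid
(wavelet band-pass -> isotropic resampling -> gray-level quantization)
and the deep path (largest-area axial slice triplet inside the tumor
bounding box).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pywt
from scipy import ndimage
from scipy.stats import rankdata

from .synthetic import MultimodalStudy

logger = logging.getLogger(__name__)

QUANTIZERS = ("Equal", "Uniform", "Lloyd")

WAVELET = "sym8"  # basis for the band-pass weighting filter


@dataclasses.dataclass(frozen=True)
class Box:
    """Axis-aligned inclusive voxel bounding box."""

    mins: tuple[int, int, int]
    maxs: tuple[int, int, int]

    def __post_init__(self):
        if any(lo > hi for lo, hi in zip(self.mins, self.maxs)):
            raise ValueError(f"degenerate box {self.mins}..{self.maxs}")

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, hi + 1) for lo, hi in zip(self.mins, self.maxs))


@dataclasses.dataclass
class SliceTriplet:
    """Previous / central / next axial slices around the largest tumor area."""

    previous: np.ndarray
    central: np.ndarray
    next: np.ndarray
    central_index: int

    def __post_init__(self):
        if not (self.previous.shape == self.central.shape == self.next.shape):
            raise ValueError("triplet slices must share one shape")


@dataclasses.dataclass(frozen=True)
class ExtractionParams:
    """One point of the texture-extraction parameter grid.

    ratio_R weights the lowest (LLL) and highest (HHH) wavelet sub-bands
    relative to the six band-pass sub-bands; scale_mm is the isotropic
    resampling target; quantizer/n_gray control gray-level quantization.
    """

    ratio_R: float = 1.0
    scale_mm: float = 1.0
    quantizer: str = "Equal"
    n_gray: int = 32

    def __post_init__(self):
        if self.ratio_R < 0:
            raise ValueError("ratio_R must be >= 0")
        if self.scale_mm <= 0:
            raise ValueError("scale_mm must be > 0")
        if self.quantizer not in QUANTIZERS:
            raise ValueError(f"quantizer must be one of {QUANTIZERS}")
        if self.n_gray < 2:
            raise ValueError("n_gray must be >= 2")

    def tag(self) -> str:
        return f"R{self.ratio_R:g}_S{self.scale_mm:g}_{self.quantizer}_G{self.n_gray}"


def bounding_box(mask: np.ndarray) -> Box:
    """Tightest axis-aligned box containing every mask voxel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot bound an empty mask")
    mins, maxs = [], []
    for axis in range(mask.ndim):
        proj = mask.any(axis=tuple(a for a in range(mask.ndim) if a != axis))
        idx = np.flatnonzero(proj)
        mins.append(int(idx[0]))
        maxs.append(int(idx[-1]))
    return Box(mins=tuple(mins), maxs=tuple(maxs))


def largest_area_slice_triplet(
    study: MultimodalStudy, modality: str, axis: int = 2
) -> SliceTriplet:
    """Central slice = axial slice with the most in-mask voxels.

    Ties break to the smallest index; the previous/next neighbours are
    clamped (duplicated) at the box boundary. Slices are cropped to the
    3D bounding box's in-plane footprint.
    """
    if modality not in study.volumes:
        raise KeyError(f"modality {modality!r} not in study")
    box = bounding_box(study.mask)
    sub_vol = study.volumes[modality][box.slices()]
    sub_mask = study.mask[box.slices()]
    areas = sub_mask.sum(axis=tuple(a for a in range(3) if a != axis))
    central = int(np.argmax(areas))  # argmax takes the first maximum
    n = sub_vol.shape[axis]
    prev_i = max(central - 1, 0)
    next_i = min(central + 1, n - 1)

    def take(i):
        return np.take(sub_vol, i, axis=axis)

    return SliceTriplet(
        previous=take(prev_i),
        central=take(central),
        next=take(next_i),
        central_index=central + box.mins[axis],
    )


def resample_isotropic(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    scale_mm: float,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample to an isotropic grid: trilinear intensities, nearest mask.

    Raises ValueError if the resampled mask comes out empty (lesion
    smaller than the target voxel), which callers treat as a degenerate
    parameter combination.
    """
    spacing = np.asarray(spacing, dtype=float)
    if scale_mm <= 0 or np.any(spacing <= 0):
        raise ValueError("spacing and scale_mm must be positive")
    zoom = spacing / scale_mm
    new_spacing = (scale_mm,) * 3
    if np.allclose(zoom, 1.0):
        return np.asarray(volume, float), np.asarray(mask, bool), new_spacing
    # grid_mode=True treats voxels as cells so the effective spacing is
    # exactly spacing/zoom, preserving physical extent
    out_vol = ndimage.zoom(
        np.asarray(volume, float), zoom, order=1, mode="nearest", grid_mode=True
    )
    out_mask = ndimage.zoom(
        np.asarray(mask, dtype=np.uint8), zoom, order=0, mode="nearest",
        grid_mode=True,
    ).astype(bool)
    if out_mask.shape != out_vol.shape:  # defensive; zoom rounds identically
        raise RuntimeError("resampled volume/mask shapes diverged")
    if not out_mask.any():
        raise ValueError(
            f"mask empty after resampling to {scale_mm} mm; lesion too small"
        )
    return out_vol, out_mask, new_spacing


def wavelet_bandpass(volume: np.ndarray, ratio_R: float) -> np.ndarray:
    """One-level 3D wavelet band-pass weighting.

    The LLL (all-lowpass) and HHH (all-highpass) sub-bands are weighted
    by ``ratio_R``; the six mixed band-pass sub-bands keep weight 1. With
    ratio_R = 1 the transform is the identity up to reconstruction error.
    Periodized sym8 transform; output is cropped back to the input shape.
    """
    if ratio_R < 0:
        raise ValueError("ratio_R must be >= 0")
    vol = np.asarray(volume, dtype=float)
    coeffs = pywt.dwtn(vol, WAVELET, mode="periodization")
    coeffs["aaa"] = coeffs["aaa"] * ratio_R
    coeffs["ddd"] = coeffs["ddd"] * ratio_R
    rec = pywt.idwtn(coeffs, WAVELET, mode="periodization")
    return rec[tuple(slice(0, s) for s in vol.shape)]


# ---------------------------------------------------------------------------
# gray-level quantization
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, quantizer: str, n_gray: int) -> np.ndarray:
    """Quantize intensities to integer levels 1..n_gray.

    Equal   -- equal-probability (quantile) bins, computed from average
               ranks so that tied values share a level and, for distinct
               values, bin counts differ by at most one.
    Uniform -- equal-width bins over [min, max].
    Lloyd   -- Lloyd-Max iterative scalar quantizer (1D k-means with
               quantile initialisation), levels ordered by centroid.

    Constant input maps everything to level 1 with a logged warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 1:
        raise ValueError("need at least one value to quantize")
    if n_gray < 2:
        raise ValueError("n_gray must be >= 2")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        logger.warning("constant ROI: all voxels mapped to gray level 1")
        return np.ones(values.size, dtype=np.int64)
    if quantizer == "Equal":
        ranks = rankdata(values, method="average") - 1.0  # 0..n-1
        levels = np.floor(ranks * n_gray / values.size).astype(np.int64) + 1
        return np.clip(levels, 1, n_gray)
    if quantizer == "Uniform":
        levels = np.floor((values - vmin) / (vmax - vmin) * n_gray).astype(np.int64) + 1
        return np.clip(levels, 1, n_gray)
    if quantizer == "Lloyd":
        return _lloyd_max(values, n_gray)
    raise ValueError(f"unknown quantizer {quantizer!r}; choose from {QUANTIZERS}")


def _lloyd_max(values: np.ndarray, n_gray: int, max_iter: int = 100) -> np.ndarray:
    """Lloyd-Max on the empirical distribution (deterministic)."""
    # quantile init keeps centroids inside the data support
    q = (np.arange(n_gray) + 0.5) / n_gray
    centroids = np.quantile(values, q)
    assign = np.zeros(values.size, dtype=np.int64)
    for _ in range(max_iter):
        edges = (centroids[:-1] + centroids[1:]) / 2.0
        new_assign = np.searchsorted(edges, values)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(n_gray):
            sel = assign == k
            if sel.any():
                centroids[k] = values[sel].mean()
        order = np.argsort(centroids)
        centroids = centroids[order]
    return assign + 1
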