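"""Handcrafted radiomic features.

Four nontexture (shape) features computed once per patient from the
tumor mask, plus a factorial texture grid per modality: each grid point
applies wavelet band-pass weighting, isotropic resampling and gray-level
quantization, then computes 43 texture statistics (3 global histogram
moments, 9 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM). The default grid has
5 band-pass ratios x 4 scales x 3 quantizers x 4 gray-level counts =
240 parameter combinations, i.e. 240 x 43 = 10,320 texture features per
modality and 4 + 4 x 10,320 = 41,284 handcrafted features for a
four-modality study.

All texture matrices are 3D: gray-level pairs are aggregated over the 13
unique 3D directions at distance 1 into a single merged matrix per
family; zones use 26-connectivity. Statistics that are undefined on a
degenerate ROI (e.g. correlation of a constant region) are imputed as 0
with a logged warning so the feature table stays rectangular.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from skimage.morphology import convex_hull_image

from .preprocess import (
    ExtractionParams,
    bounding_box,
    quantize,
    resample_isotropic,
    wavelet_bandpass,
)
from .synthetic import MultimodalStudy

logger = logging.getLogger(__name__)

# 13 unique 3D directions at distance 1 (half of the 26-neighbourhood)
DIRECTIONS_13 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
]
assert len(DIRECTIONS_13) == 13

GLOBAL_STATS = ("Variance", "Skewness", "Kurtosis")
GLCM_STATS = (
    "Energy", "Contrast", "Entropy", "Homogeneity", "Correlation",
    "SumAverage", "Variance", "Dissimilarity", "AutoCorrelation",
)
GLRLM_STATS = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
)
GLSZM_STATS = (
    "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
)
NGTDM_STATS = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

STAT_NAMES = (
    tuple(f"Global_{s}" for s in GLOBAL_STATS)
    + tuple(f"GLCM_{s}" for s in GLCM_STATS)
    + tuple(f"GLRLM_{s}" for s in GLRLM_STATS)
    + tuple(f"GLSZM_{s}" for s in GLSZM_STATS)
    + tuple(f"NGTDM_{s}" for s in NGTDM_STATS)
)
assert len(STAT_NAMES) == 43

NONTEXTURE_NAMES = ("Volume", "Size", "Solidity", "Eccentricity")

_EPS = 1e-6  # small-epsilon stabilizer for NGTDM ratios


# ---------------------------------------------------------------------------
# feature table container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FeatureTable:
    """Patients x named features with binary labels."""

    ids: list[str]
    names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(set(self.names)) != len(self.names):
            dupes = [n for n in self.names if self.names.count(n) > 1][:3]
            raise ValueError(f"duplicate feature names, e.g. {dupes}")
        if self.X.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.names)} names"
            )
        if self.y.shape != (len(self.ids),):
            raise ValueError("label vector length must equal the number of rows")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix must be finite after extraction")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.names.index(n) for n in names]
        return FeatureTable(
            ids=list(self.ids), names=list(names), X=self.X[:, idx], y=self.y.copy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "patient_id", self.ids)
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "patient_id" not in df.columns or "label" not in df.columns:
            raise ValueError("feature CSV needs 'patient_id' and 'label' columns")
        names = [c for c in df.columns if c not in ("patient_id", "label")]
        return cls(
            ids=df["patient_id"].astype(str).tolist(),
            names=names,
            X=df[names].to_numpy(float),
            y=df["label"].to_numpy(int),
        )

    @classmethod
    def concat(cls, a: "FeatureTable", b: "FeatureTable") -> "FeatureTable":
        if a.ids != b.ids or not np.array_equal(a.y, b.y):
            raise ValueError("tables must share patients and labels to concatenate")
        return cls(
            ids=list(a.ids),
            names=list(a.names) + list(b.names),
            X=np.hstack([a.X, b.X]),
            y=a.y.copy(),
        )


@dataclasses.dataclass
class TextureGrid:
    """Full factorial texture-extraction grid."""

    params: list[ExtractionParams]
    stat_names: tuple[str, ...] = STAT_NAMES

    @property
    def features_per_modality(self) -> int:
        return len(self.params) * len(self.stat_names)


def default_grid() -> TextureGrid:
    """240-combination default grid (240 x 43 = 10,320 features/modality)."""
    ratios = (0.5, 2.0 / 3.0, 1.0, 1.5, 2.0)
    scales = (1.0, 2.0, 3.0, 4.0)
    quantizers = ("Equal", "Uniform", "Lloyd")
    grays = (8, 16, 32, 64)
    params = [
        ExtractionParams(ratio_R=r, scale_mm=s, quantizer=q, n_gray=g)
        for r in ratios
        for s in scales
        for q in quantizers
        for g in grays
    ]
    return TextureGrid(params=params)


def small_grid() -> TextureGrid:
    """A 4-combination grid for quick runs (4 x 43 = 172 features/modality)."""
    params = [
        ExtractionParams(ratio_R=1.0, scale_mm=1.0, quantizer="Equal", n_gray=8),
        ExtractionParams(ratio_R=1.0, scale_mm=2.0, quantizer="Uniform", n_gray=16),
        ExtractionParams(ratio_R=1.5, scale_mm=1.0, quantizer="Equal", n_gray=16),
        ExtractionParams(ratio_R=0.5, scale_mm=2.0, quantizer="Lloyd", n_gray=8),
    ]
    return TextureGrid(params=params)


# ---------------------------------------------------------------------------
# nontexture (shape) features
# ---------------------------------------------------------------------------

def nontexture_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Volume (mm^3), Size (max surface-to-surface distance, mm), Solidity
    (mask volume over convex-hull volume), Eccentricity of the
    second-moment ellipsoid, sqrt(1 - shortest^2/longest^2).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    nvox = int(mask.sum())
    volume = nvox * float(np.prod(spacing))

    coords = np.argwhere(mask) * spacing
    if nvox == 1:
        return {"Volume": volume, "Size": 0.0, "Solidity": 1.0, "Eccentricity": 0.0}

    # Size: max pairwise distance between surface voxel centers; restrict to
    # convex-hull vertices since the diameter is attained there.
    eroded = ndimage.binary_erosion(mask)
    surface = mask & ~eroded
    pts = np.argwhere(surface) * spacing
    try:
        hull_pts = pts[ConvexHull(pts).vertices] if len(pts) > 4 else pts
    except QhullError:  # coplanar/collinear masks
        hull_pts = pts
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    size = float(np.sqrt((diff**2).sum(-1)).max())

    box = bounding_box(mask)
    sub = mask[box.slices()]
    hull_img = convex_hull_image(sub) if sub.sum() > 1 else sub
    solidity = float(nvox / max(int(hull_img.sum()), nvox))

    cov = np.cov(coords.T)
    eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))
    if eig[-1] <= 0:
        ecc = 0.0
    else:
        ecc = float(np.sqrt(max(0.0, 1.0 - eig[0] / eig[-1])))
    return {"Volume": volume, "Size": size, "Solidity": solidity, "Eccentricity": ecc}


# ---------------------------------------------------------------------------
# global histogram moments
# ---------------------------------------------------------------------------

def global_stats(values: np.ndarray) -> dict[str, float]:
    """Population variance, skewness, and (Pearson, non-excess) kurtosis."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need >= 2 values")
    var = float(v.var())
    if var == 0:
        logger.warning("constant ROI: skewness/kurtosis imputed as 0")
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    return {
        "Variance": var,
        "Skewness": float(_skew(v)),
        "Kurtosis": float(_kurtosis(v, fisher=False)),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_gray: int) -> np.ndarray:
    """Merged symmetric co-occurrence matrix over the 13 3D directions at
    distance 1, restricted to in-mask voxel pairs, normalized to sum 1."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    counts = np.zeros((n_gray, n_gray), dtype=float)
    for d in DIRECTIONS_13:
        sl_a, sl_b = _shift_slices(levels.shape, d)
        in_a = mask[sl_a] & mask[sl_b]
        if not in_a.any():
            continue
        a = levels[sl_a][in_a] - 1
        b = levels[sl_b][in_a] - 1
        np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pair for the co-occurrence matrix")
    return counts / total


def _shift_slices(shape, d):
    sl_a, sl_b = [], []
    for n, step in zip(shape, d):
        if step == 0:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
        elif step > 0:
            sl_a.append(slice(0, n - step))
            sl_b.append(slice(step, n))
        else:
            sl_a.append(slice(-step, n))
            sl_b.append(slice(0, n + step))
    return tuple(sl_a), tuple(sl_b)


def glcm_stats_from_matrix(P: np.ndarray) -> dict[str, float]:
    G = P.shape[0]
    i = np.arange(1, G + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    nz = P > 0
    mu = float((I * P).sum())  # symmetric P: row mean == col mean
    var = float(((I - mu) ** 2 * P).sum())
    if var > 0:
        corr = float((((I - mu) * (J - mu) * P).sum()) / var)
    else:
        corr = 0.0
    return {
        "Energy": float((P**2).sum()),
        "Contrast": float(((I - J) ** 2 * P).sum()),
        "Entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "Homogeneity": float((P / (1.0 + np.abs(I - J))).sum()),
        "Correlation": corr,
        "SumAverage": float(((I + J) * P).sum()),
        "Variance": var,
        "Dissimilarity": float((np.abs(I - J) * P).sum()),
        "AutoCorrelation": float((I * J * P).sum()),
    }


def glcm_stats(levels, mask, n_gray) -> dict[str, float]:
    return glcm_stats_from_matrix(glcm_matrix(levels, mask, n_gray))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_gray: int) -> np.ndarray:
    """Run-length counts merged over the 13 3D directions.

    A run is a maximal collinear sequence of in-mask voxels sharing one
    gray level; each of the 13 direction axes contributes its runs to a
    single (gray level x run length) count matrix.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in levels.shape)))) + 1
    counts = np.zeros((n_gray, max_len), dtype=float)
    coords_all = np.argwhere(mask)
    lv = levels
    shape = np.array(levels.shape)
    for d in DIRECTIONS_13:
        dvec = np.array(d)
        # run starts: in-mask voxels whose predecessor along -d is outside
        # the grid, outside the mask, or a different level
        prev = coords_all - dvec
        valid_prev = ((prev >= 0) & (prev < shape)).all(axis=1)
        is_start = np.ones(len(coords_all), dtype=bool)
        if valid_prev.any():
            pv = prev[valid_prev]
            same = mask[pv[:, 0], pv[:, 1], pv[:, 2]] & (
                lv[pv[:, 0], pv[:, 1], pv[:, 2]]
                == lv[
                    coords_all[valid_prev, 0],
                    coords_all[valid_prev, 1],
                    coords_all[valid_prev, 2],
                ]
            )
            is_start[np.flatnonzero(valid_prev)[same]] = False
        starts = coords_all[is_start]
        start_levels = lv[starts[:, 0], starts[:, 1], starts[:, 2]]
        lengths = np.ones(len(starts), dtype=int)
        cur = starts + dvec
        alive = np.arange(len(starts))
        while alive.size:
            inside = ((cur >= 0) & (cur < shape)).all(axis=1)
            ok = np.zeros(len(alive), dtype=bool)
            if inside.any():
                c = cur[inside]
                ok[inside] = mask[c[:, 0], c[:, 1], c[:, 2]] & (
                    lv[c[:, 0], c[:, 1], c[:, 2]] == start_levels[alive[inside]]
                )
            lengths[alive[ok]] += 1
            alive = alive[ok]
            cur = cur[ok] + dvec
        np.add.at(counts, (start_levels - 1, lengths - 1), 1.0)
    return counts


def glrlm_stats_from_matrix(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = R.sum()
    if n_runs == 0:
        raise ValueError("no runs: empty ROI")
    p = R / n_runs
    G, L = p.shape
    g = np.arange(1, G + 1)[:, None].astype(float)
    ln = np.arange(1, L + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_g = float((g[:, 0] * pg).sum())
    mu_l = float((ln[0] * pl).sum())
    return {
        "SRE": float((p / ln**2).sum()),
        "LRE": float((p * ln**2).sum()),
        "GLN": float((pg**2).sum()),
        "RLN": float((pl**2).sum()),
        "RP": float(n_runs / (n_voxels * len(DIRECTIONS_13))),
        "LGRE": float((p / g**2).sum()),
        "HGRE": float((p * g**2).sum()),
        "SRLGE": float((p / (g**2 * ln**2)).sum()),
        "SRHGE": float((p * g**2 / ln**2).sum()),
        "LRLGE": float((p * ln**2 / g**2).sum()),
        "LRHGE": float((p * g**2 * ln**2).sum()),
        "GLV": float((pg * (g[:, 0] - mu_g) ** 2).sum()),
        "RLV": float((pl * (ln[0] - mu_l) ** 2).sum()),
    }


def glrlm_stats(levels, mask, n_gray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    return glrlm_stats_from_matrix(
        glrlm_matrix(levels, mask, n_gray), int(mask.sum())
    )


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_gray: int) -> np.ndarray:
    """Size-zone counts: 26-connected constant-level zones per gray level."""
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    counts = np.zeros((n_gray, n_vox), dtype=float)
    present = np.unique(np.asarray(levels)[mask])
    for gl in present:
        binary = mask & (levels == gl)
        lab, n_zones = ndimage.label(binary, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[gl - 1, s - 1] += 1.0
    return counts


def glszm_stats_from_matrix(S: np.ndarray) -> dict[str, float]:
    n_zones = S.sum()
    if n_zones == 0:
        raise ValueError("no zones: empty ROI")
    n_vox = float((S * np.arange(1, S.shape[1] + 1)[None, :]).sum())
    p = S / n_zones
    G, Z = p.shape
    g = np.arange(1, G + 1)[:, None].astype(float)
    z = np.arange(1, Z + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    pz = p.sum(axis=0)
    mu_g = float((g[:, 0] * pg).sum())
    mu_z = float((z[0] * pz).sum())
    return {
        "SZE": float((p / z**2).sum()),
        "LZE": float((p * z**2).sum()),
        "GLN": float((pg**2).sum()),
        "ZSN": float((pz**2).sum()),
        "ZP": float(n_zones / n_vox),
        "LGZE": float((p / g**2).sum()),
        "HGZE": float((p * g**2).sum()),
        "SZLGE": float((p / (g**2 * z**2)).sum()),
        "SZHGE": float((p * g**2 / z**2).sum()),
        "LZLGE": float((p * z**2 / g**2).sum()),
        "LZHGE": float((p * g**2 * z**2).sum()),
        "GLV": float((pg * (g[:, 0] - mu_g) ** 2).sum()),
        "ZSV": float((pz * (z[0] - mu_z) ** 2).sum()),
    }


def glszm_stats(levels, mask, n_gray) -> dict[str, float]:
    return glszm_stats_from_matrix(glszm_matrix(levels, mask, n_gray))


# ---------------------------------------------------------------------------
# NGTDM (Amadasun-King)
# ---------------------------------------------------------------------------

def ngtdm_vectors(
    levels: np.ndarray, mask: np.ndarray, n_gray: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n(g) and summed deviations s(g).

    For every in-mask voxel with at least one in-mask 26-neighbour,
    A_i = mean neighbour level; s(g) accumulates |g - A_i| over voxels of
    level g. Voxels without in-mask neighbours are excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    lv = np.where(mask, np.asarray(levels, float), 0.0)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0)
    if not valid.any():
        raise ValueError("only isolated voxels: NGTDM undefined")
    A = nbr_sum[valid] / nbr_cnt[valid]
    g = np.asarray(levels)[valid]
    n_g = np.bincount(g - 1, minlength=n_gray).astype(float)
    s_g = np.zeros(n_gray)
    np.add.at(s_g, g - 1, np.abs(g - A))
    return n_g, s_g


def ngtdm_stats_from_vectors(n_g: np.ndarray, s_g: np.ndarray) -> dict[str, float]:
    N = n_g.sum()
    p = n_g / N
    idx = np.flatnonzero(p > 0)
    gi = (idx + 1).astype(float)
    pi = p[idx]
    si = s_g[idx]
    Ngp = len(idx)
    coarseness = 1.0 / (_EPS + float((pi * si).sum()))
    if Ngp > 1:
        D2 = (gi[:, None] - gi[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * D2).sum() / (Ngp * (Ngp - 1))
        ) * float(s_g.sum() / N)
        denom = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        busyness = float((pi * si).sum() / denom) if denom > 0 else 0.0
        psum = pi[:, None] + pi[None, :]
        complexity = float(
            (
                np.abs(gi[:, None] - gi[None, :])
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (N * psum)
            ).sum()
        )
        strength = float((psum * D2).sum() / (_EPS + s_g.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def ngtdm_stats(levels, mask, n_gray) -> dict[str, float]:
    return ngtdm_stats_from_vectors(*ngtdm_vectors(levels, mask, n_gray))


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def texture_stats(levels_vol: np.ndarray, mask: np.ndarray, n_gray: int) -> dict[str, float]:
    """All 43 statistics for one quantized ROI; degenerate families -> 0."""
    out: dict[str, float] = {}
    values = levels_vol[mask]
    for k, v in global_stats(values).items():
        out[f"Global_{k}"] = v
    try:
        for k, v in glcm_stats(levels_vol, mask, n_gray).items():
            out[f"GLCM_{k}"] = v
    except ValueError:
        logger.warning("GLCM degenerate (no voxel pair); statistics imputed 0")
        out.update({f"GLCM_{k}": 0.0 for k in GLCM_STATS})
    for k, v in glrlm_stats(levels_vol, mask, n_gray).items():
        out[f"GLRLM_{k}"] = v
    for k, v in glszm_stats(levels_vol, mask, n_gray).items():
        out[f"GLSZM_{k}"] = v
    try:
        for k, v in ngtdm_stats(levels_vol, mask, n_gray).items():
            out[f"NGTDM_{k}"] = v
    except ValueError:
        logger.warning("NGTDM degenerate (isolated voxels); statistics imputed 0")
        out.update({f"NGTDM_{k}": 0.0 for k in NGTDM_STATS})
    return out


def extract_handcrafted(
    study: MultimodalStudy,
    grid: TextureGrid | None = None,
    modalities: Sequence[str] | None = None,
) -> dict[str, float]:
    """Extract the full handcrafted feature vector for one study.

    Per modality and grid point: wavelet band-pass -> isotropic
    resampling -> quantization -> 43 texture statistics, with the 4
    nontexture features computed once from the mask. Parameter
    combinations degenerate for this lesion (e.g. the lesion vanishes at
    a coarse resampling scale) have their 43 statistics imputed as 0.
    """
    grid = grid or default_grid()
    modalities = list(modalities or study.volumes.keys())
    box = bounding_box(study.mask)
    sub_mask = study.mask[box.slices()]

    features: dict[str, float] = {}
    for k, v in nontexture_features(study.mask, study.spacing).items():
        features[f"nontexture|{k}"] = v

    by_ratio: dict[str, list[ExtractionParams]] = {}
    for ep in grid.params:
        by_ratio.setdefault(f"{ep.ratio_R:g}", []).append(ep)

    for modality in modalities:
        sub_vol = study.volumes[modality][box.slices()]
        for ratio_key, plist in by_ratio.items():
            filtered = wavelet_bandpass(sub_vol, plist[0].ratio_R)
            by_scale: dict[float, list[ExtractionParams]] = {}
            for ep in plist:
                by_scale.setdefault(ep.scale_mm, []).append(ep)
            for scale_mm, eps in by_scale.items():
                try:
                    rvol, rmask, _ = resample_isotropic(
                        filtered, sub_mask, study.spacing, scale_mm
                    )
                except ValueError:
                    rvol = rmask = None
                for ep in eps:
                    prefix = f"{modality}|{ep.tag()}"
                    if rvol is None:
                        logger.warning(
                            "%s: degenerate resampling; statistics imputed 0", prefix
                        )
                        stats = {k: 0.0 for k in STAT_NAMES}
                    else:
                        levels = np.zeros(rvol.shape, dtype=np.int64)
                        levels[rmask] = quantize(rvol[rmask], ep.quantizer, ep.n_gray)
                        stats = texture_stats(levels, rmask, ep.n_gray)
                    for k, v in stats.items():
                        features[f"{prefix}|{k}"] = v
    return features


def extract_handcrafted_table(
    studies: Sequence[MultimodalStudy],
    grid: TextureGrid | None = None,
    modalities: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
) -> FeatureTable:
    """Extract handcrafted features for a cohort into a FeatureTable."""
    rows = [extract_handcrafted(s, grid=grid, modalities=modalities) for s in studies]
    names = list(rows[0].keys())
    X = np.array([[r[n] for n in names] for r in rows], dtype=float)
    X[~np.isfinite(X)] = 0.0
    ids = list(ids) if ids is not None else [f"P{i + 1:03d}" for i in range(len(rows))]
    y = np.array([s.label for s in studies], dtype=int)
    return FeatureTable(ids=ids, names=names, X=X, y=y)
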