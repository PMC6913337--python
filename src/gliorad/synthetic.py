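"""Synthetic imaging studies and feature tables.

The real cohort behind this pipeline (51 glioma patients, 16 radiation
necrosis / 35 recurrence, four co-registered MRI modalities each) is not
publicly deposited, so every downstream stage is exercised on synthetic
data with the statistical structure the analysis assumes:

* ``generate_phantom`` builds a four-modality volume with a compact
  ellipsoidal lesion whose in-mask texture differs by class (smoothed
  Gaussian noise with class-specific mean / SD / correlation length).
* ``generate_feature_table`` builds a patient x feature matrix with a
  small informative subset (standardised mean shift between classes)
  against block-correlated noise features, with a configurable 16:35
  class ratio.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITIES = ("T1", "T1C", "T2", "FLAIR")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MultimodalStudy:
    """One patient's registered multi-modality volumes plus tumor mask.

    Attributes
    ----------
    volumes : mapping of modality name -> 3D float array.
    mask : 3D boolean array, same shape as every volume, >= 1 voxel.
    spacing : (3,) voxel size in mm.
    label : 0 = recurrence, 1 = necrosis.
    """

    volumes: Mapping[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float]
    label: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {m: v.shape for m, v in self.volumes.items()}
        for m, shp in shapes.items():
            if shp != self.mask.shape:
                raise ValueError(
                    f"volume {m!r} shape {shp} differs from mask shape "
                    f"{self.mask.shape}"
                )
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")


@dataclasses.dataclass(frozen=True)
class TextureParams:
    """Texture-field parameters for one class and modality."""

    mean: float
    sd: float
    corr_mm: float  # spatial correlation length of the smoothed noise field


@dataclasses.dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius: float = 8.0  # mm
    modalities: Sequence[str] = MODALITIES
    class_texture_params: Mapping[int, Mapping[str, TextureParams]] | None = None
    noise_sd: float = 2.0
    background_mean: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_texture_params is None:
            self.class_texture_params = default_texture_params(self.modalities)
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if len(self.class_texture_params) < 2:
            raise ValueError("need texture parameters for both classes")
        half_extent = min(
            n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)
        )
        if self.lesion_radius >= half_extent:
            raise ValueError(
                f"lesion radius {self.lesion_radius} mm does not fit inside a "
                f"grid of half-extent {half_extent} mm; enlarge grid_shape or "
                f"shrink lesion_radius"
            )


def default_texture_params(
    modalities: Sequence[str] = MODALITIES,
) -> dict[int, dict[str, TextureParams]]:
    """Class/modality texture defaults with class-separable statistics.

    Necrosis (label 1) is given a coarser (longer correlation length) and
    more dispersed texture than recurrence (label 0), with the contrast
    most pronounced on T1C/FLAIR -- a caricature of the enhancement-pattern
    differences radiologists describe, sufficient for texture matrices to
    separate the classes.
    """
    base = {
        "T1": (110.0, 95.0),
        "T1C": (130.0, 150.0),
        "T2": (140.0, 120.0),
        "FLAIR": (125.0, 145.0),
    }
    out: dict[int, dict[str, TextureParams]] = {0: {}, 1: {}}
    for i, m in enumerate(modalities):
        m0, m1 = base.get(m, (100.0 + 5 * i, 120.0 + 5 * i))
        out[0][m] = TextureParams(mean=m0, sd=12.0, corr_mm=1.2)
        out[1][m] = TextureParams(mean=m1, sd=22.0, corr_mm=2.8)
    return out


def generate_phantom(config: PhantomConfig, label: int) -> MultimodalStudy:
    """Generate one synthetic study with an ellipsoidal central lesion.

    In-mask intensities are drawn from the label's texture field per
    modality: white Gaussian noise smoothed to the class correlation
    length, then affinely mapped to the class mean/SD. Outside the mask
    the volume is flat background plus additive noise. Deterministic
    given ``config.seed`` and ``label``.
    """
    if label not in config.class_texture_params:
        raise ValueError(f"no texture parameters for class {label}")
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing, dtype=float)
    center = (np.array(shape) - 1) / 2.0
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    )
    dist2 = (((coords - center) * spacing) ** 2).sum(axis=-1)
    mask = dist2 <= config.lesion_radius**2
    if not mask.any():
        raise ValueError("lesion mask empty; lesion_radius smaller than a voxel")

    ss = np.random.SeedSequence([int(config.seed), int(label)])
    children = ss.spawn(len(config.modalities) + 1)
    volumes: dict[str, np.ndarray] = {}
    for child, modality in zip(children, config.modalities):
        rng = np.random.default_rng(child)
        params = config.class_texture_params[label][modality]
        field = rng.standard_normal(shape)
        sigma_vox = params.corr_mm / spacing
        smooth = ndimage.gaussian_filter(field, sigma=sigma_vox)
        s = smooth.std()
        if s > 0:
            smooth = (smooth - smooth.mean()) / s
        vol = config.background_mean + config.noise_sd * rng.standard_normal(shape)
        vol[mask] = params.mean + params.sd * smooth[mask]
        volumes[modality] = vol
    return MultimodalStudy(
        volumes=volumes, mask=mask, spacing=tuple(spacing), label=int(label)
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TableSpec:
    """Specification for a synthetic patient x feature table.

    Defaults mirror the study cohort: 16 necrosis (label 1) vs 35
    recurrence (label 0). ``informative_idx`` columns get a between-class
    mean shift of ``effect_size`` standard deviations; the remaining
    columns are pure noise with ``block_correlation`` within blocks of
    ``block_size`` consecutive features.
    """

    n_pos: int = 16
    n_neg: int = 35
    p_features: int = 200
    informative_idx: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 2.0
    block_correlation: float = 0.3
    block_size: int = 10
    name_prefix: str = "f"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one patient")
        if self.p_features < len(self.informative_idx):
            raise ValueError(
                f"p_features={self.p_features} smaller than the "
                f"{len(self.informative_idx)} informative features"
            )
        if any(i < 0 or i >= self.p_features for i in self.informative_idx):
            raise ValueError("informative_idx out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not abs(self.block_correlation) < 1:
            raise ValueError("|block_correlation| must be < 1")


def generate_feature_table(spec: TableSpec):
    """Draw a feature table per ``spec``; deterministic given seed.

    Returns a :class:`gliorad.handcrafted.FeatureTable` with positives
    (label 1) first.
    """
    from .handcrafted import FeatureTable

    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    p = spec.p_features
    y = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])

    X = rng.standard_normal((n, p))
    rho = spec.block_correlation
    if rho != 0.0:
        # equicorrelated blocks: x = sqrt(rho)*shared + sqrt(1-rho)*own
        for start in range(0, p, spec.block_size):
            stop = min(start + spec.block_size, p)
            shared = rng.standard_normal((n, 1))
            sgn = np.sign(rho)
            X[:, start:stop] = (
                sgn * np.sqrt(abs(rho)) * shared
                + np.sqrt(1 - abs(rho)) * X[:, start:stop]
            )
    for j in spec.informative_idx:
        X[y == 1, j] += spec.effect_size
    names = [f"{spec.name_prefix}{j:04d}" for j in range(p)]
    ids = [f"P{i + 1:03d}" for i in range(n)]
    return FeatureTable(ids=ids, names=names, X=X, y=y)


# ---------------------------------------------------------------------------
# NIfTI output
# ---------------------------------------------------------------------------

def save_study(study: MultimodalStudy, directory: str | os.PathLike) -> dict[str, str]:
    """Write one file per modality plus ``mask.nii`` with spacing in the affine."""
    os.makedirs(directory, exist_ok=True)
    affine = np.diag(list(study.spacing) + [1.0])
    written = {}
    for modality, vol in study.volumes.items():
        path = os.path.join(directory, f"{modality}.nii")
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), path)
        written[modality] = path
    mpath = os.path.join(directory, "mask.nii")
    nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), affine), mpath)
    written["mask"] = mpath
    lpath = os.path.join(directory, "label.txt")
    with open(lpath, "w") as fh:
        fh.write(f"{study.label}\n")
    written["label"] = lpath
    return written


def load_study(directory: str | os.PathLike) -> MultimodalStudy:
    """Read a study written by :func:`save_study` (or equivalent layout)."""
    directory = os.fspath(directory)
    files = [f for f in os.listdir(directory) if f.endswith((".nii", ".nii.gz"))]
    mask_file = next((f for f in files if f.split(".")[0] == "mask"), None)
    if mask_file is None:
        raise FileNotFoundError(f"no mask.nii[.gz] in {directory}")
    img = nib.load(os.path.join(directory, mask_file))
    mask = np.asarray(img.dataobj) > 0
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    volumes = {}
    for f in sorted(files):
        name = f.split(".")[0]
        if name == "mask":
            continue
        volumes[name] = np.asarray(
            nib.load(os.path.join(directory, f)).dataobj, dtype=float
        )
    if not volumes:
        raise FileNotFoundError(f"no modality volumes in {directory}")
    label = 0
    lpath = os.path.join(directory, "label.txt")
    if os.path.exists(lpath):
        with open(lpath) as fh:
            label = int(fh.read().strip())
    else:
        warnings.warn(f"{lpath} missing; defaulting label to 0")
    return MultimodalStudy(volumes=volumes, mask=mask, spacing=spacing, label=label)
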