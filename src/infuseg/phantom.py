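"""Synthetic infusion-image generator with known ground truth.

Emulates intra-operative T1-weighted FLASH acquisitions of a gadolinium
co-infusion: a hyperintense quasi-ellipsoidal infusate over a darker,
mildly heterogeneous brain background, on an anisotropic grid (default
0.7 mm in-plane, 1 mm slices). The sharp ellipsoid edge is blurred with a
Gaussian to create the sloped intensity "shoulder" that makes manual edge
placement ambiguous, then additive Gaussian noise is applied. Optional
bright distractor blobs near the volume border stand in for fat and other
hyperintense structures an operator's bounding box is meant to exclude.

Ground truth is the pre-blur infusate region: the shoulder is a property
of the imaging, not of where the infusate is, so volume-recovery error
measures how the segmentation resolves that ambiguity. The region itself
is quasi-ellipsoidal — the requested ellipsoid regularized at the voxel
scale by a spheroidal opening — because a mathematical ellipsoid sampled
on an anisotropic grid has single-voxel jaggies that no physical infusion
front exhibits and no element-scale morphology can represent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image_model import BinaryMask, BoundingBox, VoxelGrid
from .metrics import mask_volume
from .morphology import make_spheroid_element

__all__ = ["PhantomSpec", "PhantomResult", "generate_phantom", "generate_study", "default_box"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic infusion volume.

    Intensities are in normalized units (the generator's output is later
    min-max normalized by the pipeline like any scan). ``semi_axes_mm``
    and ``shoulder_sigma_mm`` are in millimetres and converted per-axis by
    the voxel spacing. ``bg_texture_amp`` scales a smooth random field
    that makes the background heterogeneous like real tissue.
    """

    shape: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (0.7, 0.7, 1.0)
    center: Optional[Tuple[float, float, float]] = None  # voxel coords; None = volume centre
    semi_axes_mm: Tuple[float, float, float] = (5.0, 4.5, 4.0)
    shoulder_sigma_mm: float = 0.5  # PSF-scale blur: FWHM ~ in-plane voxel size
    fg_mean: float = 0.75
    bg_mean: float = 0.25
    noise_sigma: float = 0.05
    bg_texture_amp: float = 0.03
    bg_texture_scale_mm: float = 3.0
    n_background_blobs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fg_mean <= self.bg_mean:
            raise ValueError("fg_mean must exceed bg_mean")
        if self.noise_sigma < 0 or self.shoulder_sigma_mm < 0 or self.bg_texture_amp < 0:
            raise ValueError("noise, shoulder and texture amplitudes must be >= 0")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")

    def resolved_center(self) -> Tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple((n - 1) / 2.0 for n in self.shape)


@dataclass(frozen=True)
class PhantomResult:
    grid: VoxelGrid
    truth_mask: BinaryMask
    truth_volume_ul: float
    spec: PhantomSpec


def _ellipsoid_mask(shape, spacing, center_vox, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    dist2 = sum(
        (((g - c) * s) / a) ** 2
        for g, c, s, a in zip(grids, center_vox, spacing, semi_axes_mm)
    )
    return dist2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render one phantom; fully reproducible from ``spec.seed``."""
    center = spec.resolved_center()
    # the infusate must sit inside the volume
    for c, a, s, n in zip(center, spec.semi_axes_mm, spec.spacing, spec.shape):
        if c - a / s < 0 or c + a / s > n - 1:
            raise ValueError(
                f"ellipsoid (centre {center}, semi-axes {spec.semi_axes_mm} mm) "
                f"exceeds the {spec.shape} volume"
            )
    rng = np.random.default_rng(spec.seed)
    ellipsoid = _ellipsoid_mask(spec.shape, spec.spacing, center, spec.semi_axes_mm)
    # quasi-ellipsoidal infusate: regularize voxel-scale jaggies away so the
    # region is smooth at the scale of an imaging point-spread / diffusion front
    truth = ndimage.binary_opening(ellipsoid, structure=make_spheroid_element())

    image = np.full(spec.shape, spec.bg_mean, dtype=np.float64)
    if spec.bg_texture_amp > 0:
        sigma_vox = [spec.bg_texture_scale_mm / s for s in spec.spacing]
        texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma_vox)
        std = texture.std()
        if std > 0:
            image += spec.bg_texture_amp * texture / std

    for _ in range(spec.n_background_blobs):
        image = _add_distractor(image, spec, rng)

    image[truth] = spec.fg_mean
    if spec.shoulder_sigma_mm > 0:
        sigma_vox = [spec.shoulder_sigma_mm / s for s in spec.spacing]
        image = ndimage.gaussian_filter(image, sigma_vox)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, spec.shape)

    grid = VoxelGrid(image, spec.spacing)
    mask = BinaryMask(truth, spec.spacing)
    return PhantomResult(grid=grid, truth_mask=mask, truth_volume_ul=mask_volume(mask), spec=spec)


def _add_distractor(image: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Place a small bright blob in the outer shell of the volume.

    Distractors mimic fat and vessel hyperintensities; they are kept near
    the border so that a bounding box drawn around the central infusate
    excludes them — the box's stated purpose.
    """
    shape = np.array(spec.shape)
    # random position within the outer 15% shell of the two in-plane axes
    pos = []
    for n in shape:
        margin = max(2, int(0.15 * n))
        side = rng.integers(0, 2)
        p = rng.integers(1, margin) if side == 0 else rng.integers(n - margin, n - 1)
        pos.append(float(p))
    radius_mm = (2.0, 2.0, 1.5)
    blob = _ellipsoid_mask(spec.shape, spec.spacing, pos, radius_mm)
    out = image.copy()
    out[blob] = spec.fg_mean * 1.1
    return out


def default_box(result: PhantomResult, margin_mm: float = 3.0) -> BoundingBox:
    """Operator-style bounding box: the truth ellipsoid plus a margin."""
    spec = result.spec
    center = spec.resolved_center()
    lo, hi = [], []
    for c, a, s, n in zip(center, spec.semi_axes_mm, spec.spacing, spec.shape):
        half = (a + margin_mm) / s
        lo.append(max(0, int(np.floor(c - half))))
        hi.append(min(n, int(np.ceil(c + half)) + 1))
    return BoundingBox(tuple(lo), tuple(hi))


def generate_study(
    n_subjects: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> List[PhantomResult]:
    """A reproducible cohort of phantoms with jittered geometry and noise.

    Semi-axes are jittered by +/-20%, the centre by up to 2 voxels per
    axis and the noise level by +/-20% around the base spec, emulating
    subject-to-subject variation in infusion size, placement and image
    quality.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    base_center = base_spec.resolved_center()
    for i in range(n_subjects):
        axes = tuple(a * rng.uniform(0.8, 1.2) for a in base_spec.semi_axes_mm)
        center = tuple(c + rng.uniform(-2, 2) for c in base_center)
        noise = base_spec.noise_sigma * rng.uniform(0.8, 1.2)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base_spec,
            semi_axes_mm=axes,
            center=center,
            noise_sigma=noise,
            seed=sub_seed,
        )
        cohort.append(generate_phantom(spec))
    return cohort
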