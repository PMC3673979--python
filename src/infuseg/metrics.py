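"""Volume and inter-operator agreement statistics.

Distribution volume Vd is the voxel count of the infusate mask times the
voxel volume; with spacing in mm, 1 mm^3 = 1 uL. The Vd/Vi ratio relates
Vd to the pump-reported infusion volume Vi. Inter-operator variability is
summarised as the coefficient of variance (CoV): the sample standard
deviation of the operators' volumes divided by their mean, as a percent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .gmm import FitResult
from .image_model import BinaryMask, BoundingBox

__all__ = [
    "SegmentationReport",
    "mask_volume",
    "vd_vi_ratio",
    "coefficient_of_variance",
    "variability_improvement",
]


def mask_volume(mask: BinaryMask) -> float:
    """Volume of the true voxels in uL (voxel count x dx dy dz mm^3)."""
    dx, dy, dz = mask.spacing
    return float(mask.n_voxels) * dx * dy * dz


def vd_vi_ratio(vd_ul: float, vi_ul: float) -> float:
    """Distribution volume over infusion volume; Vi must be positive."""
    if vi_ul <= 0:
        raise ValueError(f"Vi must be > 0 uL, got {vi_ul}")
    return vd_ul / vi_ul


def coefficient_of_variance(volumes: Sequence[float]) -> float:
    """CoV in percent: 100 x sample std (n-1) / mean, for >= 2 volumes.

    The sample (n-1) standard deviation is used; across four operators it
    is the convention that reproduces the worked inter-operator examples
    (25% putamen, 19% thalamus manual; 2% putamen automated).
    """
    v = np.asarray(volumes, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CoV requires at least 2 volumes")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError(f"CoV requires a positive mean, got {mean}")
    return 100.0 * float(v.std(ddof=1)) / mean


def variability_improvement(cov_manual: float, cov_auto: float) -> float:
    """Percent reduction in CoV: 100 x (manual - auto) / manual."""
    if cov_manual <= 0:
        raise ValueError(f"manual CoV must be > 0, got {cov_manual}")
    return 100.0 * (cov_manual - cov_auto) / cov_manual


@dataclass
class SegmentationReport:
    """Per-dataset summary: volumes, ratio, fit diagnostics, provenance."""

    vd_ul: float
    voxel_count: int
    box: BoundingBox
    vi_ul: Optional[float] = None
    vd_vi: Optional[float] = None
    iterations: int = 0
    converged: bool = False
    collapsed: bool = False
    final_nll: float = float("nan")
    alpha: float = float("nan")
    mu0: float = float("nan")
    sigma0: float = float("nan")
    mu1: float = float("nan")
    sigma1: float = float("nan")

    @classmethod
    def from_results(
        cls,
        mask: BinaryMask,
        fit: FitResult,
        box: BoundingBox,
        vi_ul: Optional[float] = None,
    ) -> "SegmentationReport":
        vd = mask_volume(mask)
        p = fit.params
        return cls(
            vd_ul=vd,
            voxel_count=mask.n_voxels,
            box=box,
            vi_ul=vi_ul,
            vd_vi=vd_vi_ratio(vd, vi_ul) if vi_ul and vi_ul > 0 else None,
            iterations=fit.iterations,
            converged=fit.converged,
            collapsed=fit.collapsed,
            final_nll=fit.final_nll,
            alpha=p.alpha,
            mu0=p.mu0,
            sigma0=p.sigma0,
            mu1=p.mu1,
            sigma1=p.sigma1,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box"] = {"lo": list(self.box.lo), "hi": list(self.box.hi)}
        return d
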