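"""End-to-end segmentation: normalize, fit the mixture in the box, classify, refine.

The full workflow mirrors intra-operative use: the operator supplies a 3D
bounding box around the infusion target; intensities are min-max
normalized over the scan; the two-class Gaussian mixture is fitted by EM
to the boxed voxels only; each boxed voxel is assigned by the posterior
rule; and the resulting mask is cleaned by spheroidal closing/opening and
largest-component retention. Everything outside the box is background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as _io
from .gmm import DEFAULT_INIT, FitResult, classify, fit_em
from .image_model import (
    BinaryMask,
    BoundingBox,
    DegenerateRangeError,
    VoxelGrid,
    extract_box,
    normalize_intensities,
)
from .metrics import SegmentationReport, coefficient_of_variance
from .morphology import DEFAULT_ELEMENT_WIDTHS, make_spheroid_element, refine_mask

__all__ = ["RunConfig", "segment_infusion", "run_batch"]

logger = logging.getLogger("infuseg")


@dataclass
class RunConfig:
    """Tunable knobs of one segmentation run (defaults are the validated ones)."""

    tol: float = 1e-3               # relative NLL change stopping threshold (0.1%)
    max_iter: int = 500
    element_widths: Tuple[int, int, int] = DEFAULT_ELEMENT_WIDTHS
    keep_largest: bool = True
    normalize_within_box: bool = False
    posterior: bool = True          # posterior (alpha-weighted) classification rule
    vi_ul: Optional[float] = None
    input_path: Optional[str] = None
    dataset_id: str = ""
    box: Optional[Tuple[Tuple[int, int, int], Tuple[int, int, int]]] = None
    out_mask: Optional[str] = None
    out_report: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if any(w % 2 == 0 or w <= 0 for w in self.element_widths):
            raise ValueError("element widths must be odd positive integers")


def _empty_result(grid: VoxelGrid, box: BoundingBox, config: RunConfig,
                  reason: str) -> Tuple[BinaryMask, SegmentationReport]:
    logger.warning("segmentation degenerate (%s); returning empty mask", reason)
    mask = BinaryMask(np.zeros(grid.shape, dtype=bool), grid.spacing)
    fit = FitResult(params=DEFAULT_INIT, nll_trace=[float("nan")], iterations=0,
                    converged=False, collapsed=True)
    report = SegmentationReport.from_results(mask, fit, box, vi_ul=config.vi_ul)
    return mask, report


def segment_infusion(
    grid: VoxelGrid,
    box: BoundingBox,
    config: Optional[RunConfig] = None,
) -> Tuple[BinaryMask, SegmentationReport]:
    """Segment one infusion volume inside the operator's bounding box.

    Deterministic for fixed inputs. Degenerate inputs (constant image,
    zero spread inside the box, class collapse during EM) yield an empty
    mask with the collapse flagged in the report rather than an exception.
    """
    config = config or RunConfig()
    box.check_within(grid.shape)

    try:
        if config.normalize_within_box:
            values_raw, index_map = extract_box(grid, box)
            lo, hi = values_raw.min(), values_raw.max()
            if hi <= lo:
                raise DegenerateRangeError("constant intensities inside the box")
            values = (values_raw - lo) / (hi - lo)
        else:
            norm = normalize_intensities(grid)
            values, index_map = extract_box(norm, box)
    except DegenerateRangeError as exc:
        return _empty_result(grid, box, config, str(exc))

    if float(np.ptp(values)) == 0.0 or values.size < 10:
        return _empty_result(grid, box, config, "no intensity spread inside the box")

    fit = fit_em(values, rel_tol=config.tol, max_iter=config.max_iter)
    logger.info(
        "EM: %d iterations, converged=%s, NLL=%.3f, alpha=%.4f, "
        "mu0=%.4f, sigma0=%.4f, mu1=%.4f, sigma1=%.4f",
        fit.iterations, fit.converged, fit.final_nll, fit.params.alpha,
        fit.params.mu0, fit.params.sigma0, fit.params.mu1, fit.params.sigma1,
    )
    logger.debug("NLL trace: %s", fit.nll_trace)
    if fit.collapsed:
        return _empty_result(grid, box, config, "class collapse during EM")

    raw_mask = classify(values, index_map, fit.params, grid.shape,
                        spacing=grid.spacing, posterior=config.posterior)
    elem = make_spheroid_element(config.element_widths)
    mask = refine_mask(raw_mask, elem, keep_largest=config.keep_largest)
    report = SegmentationReport.from_results(mask, fit, box, vi_ul=config.vi_ul)
    logger.info("Vd = %.1f uL (%d voxels)", report.vd_ul, report.voxel_count)
    return mask, report


def run_batch(configs: Sequence[RunConfig],
              out_csv: Optional[str] = None,
              out_json: Optional[str] = None) -> pd.DataFrame:
    """Run many datasets; one report row each, failures logged and skipped.

    Appends cohort summaries (mean Vd, Vd/Vi and their CoV where computable)
    as dataframe attributes and to the JSON report.
    """
    rows: List[dict] = []
    errors: List[dict] = []
    for i, cfg in enumerate(configs):
        ds_id = cfg.dataset_id or f"dataset_{i}"
        try:
            if cfg.input_path is None or cfg.box is None:
                raise ValueError("config needs input_path and box")
            grid = _io.read_volume(cfg.input_path)
            box = BoundingBox(*cfg.box)
            mask, report = segment_infusion(grid, box, cfg)
            if cfg.out_mask:
                _io.write_mask(mask, cfg.out_mask, reference=grid)
            if cfg.out_report:
                _io.write_report_json(report.to_dict(), cfg.out_report)
            row = {"id": ds_id, "vd_ul": report.vd_ul, "vi_ul": report.vi_ul,
                   "vd_vi": report.vd_vi, "voxel_count": report.voxel_count,
                   "converged": report.converged, "iterations": report.iterations}
            rows.append(row)
        except Exception as exc:  # fault isolation: one bad dataset must not kill the batch
            logger.error("dataset %s failed: %s", ds_id, exc)
            errors.append({"id": ds_id, "error": str(exc)})
    table = pd.DataFrame(rows)
    summary: dict = {"n_ok": len(rows), "n_failed": len(errors), "errors": errors}
    if len(rows) >= 2:
        summary["cov_vd_percent"] = coefficient_of_variance(table["vd_ul"].tolist())
        summary["mean_vd_ul"] = float(table["vd_ul"].mean())
        ratios = table["vd_vi"].dropna()
        if len(ratios) >= 1:
            summary["mean_vd_vi"] = float(ratios.mean())
    table.attrs["summary"] = summary
    if out_csv:
        table.to_csv(out_csv, index=False)
    if out_json:
        _io.write_report_json({"datasets": rows, "summary": summary}, out_json)
    return table
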