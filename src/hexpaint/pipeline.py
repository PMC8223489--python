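"""End-to-end convenience pipeline: filter -> detect ROIs -> call sites.

Thin orchestration over the analysis modules, used by the acceptance
benchmarks and the analysis drivers.  All steps are individually importable;
this module only wires them together with consistent defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .designs import DesignSpec
from .loc_filter import FilterParams, FilterReport, apply_drift, estimate_drift, filter_localizations
from .loc_io import LocalizationTable
from .roi_detect import OrigamiROI, RoiParams, detect_rois
from .site_quant import PatternSummary, SiteDetection, SiteParams, detect_sites, summarize_patterns

__all__ = ["PipelineResult", "analyze", "default_roi_params"]


@dataclass
class PipelineResult:
    table: LocalizationTable
    filter_report: FilterReport
    rois: list[OrigamiROI]
    detections: list[SiteDetection]
    summary: PatternSummary


def default_roi_params(
    expected_locs_per_site: float | None = None, n_sites: int = 6
) -> RoiParams:
    """ROI QC bounds scaled from the expected localization budget.

    The lower bound is 0.2x the expected count of a *single* site, so
    structures carrying only one occupied site are retained regardless of
    occupancy; the upper bound is 5x a fully occupied structure.  Permissive
    defaults when no expectation is known.
    """
    if expected_locs_per_site is None:
        return RoiParams()
    return RoiParams(
        min_locs=max(1, int(0.2 * expected_locs_per_site)),
        max_locs=int(5 * n_sites * expected_locs_per_site) or None,
    )


def analyze(
    table: LocalizationTable,
    design: DesignSpec,
    filter_params: FilterParams | None = None,
    roi_params: RoiParams | None = None,
    site_params: SiteParams | None = None,
    drift_correct: bool = False,
) -> PipelineResult:
    """Run quality filtering, optional drift correction, ROI detection and
    per-ROI site calling on one localization table of a single design."""
    filter_params = filter_params or FilterParams()
    filtered, report = filter_localizations(table, filter_params)
    if drift_correct:
        trace = estimate_drift(filtered, filter_params.drift_segment_frames)
        filtered = apply_drift(filtered, trace)
    rois = [r for r in detect_rois(filtered, roi_params) if r.qc_pass]
    detections = [detect_sites(filtered, r, design, site_params) for r in rois]
    if detections:
        summary = summarize_patterns(detections, design)
    else:
        summary = PatternSummary(design.name, 0, {}, float("nan"), np.zeros(0), float("nan"), float("nan"))
    return PipelineResult(filtered, report, rois, detections, summary)
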