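"""End-to-end granule segmentation pipeline.

Runs the whole method on one image: iterative threshold -> binary mask
-> chamfer distance -> watershed -> region measurement -> roundness
flagging -> GVF critical-point test on the pending segments -> final
classification -> ROI grouping -> fuzzy c-means merge -> granule
report.  Every intermediate is retained on the result object, and the
run is fully deterministic for a given image and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from . import (
    chamfer_watershed,
    fcm_merge,
    gvf_field,
    io_formats,
    region_metrics,
    thresholding,
)
from .io_formats import GrayImage, LabelMap
from .region_metrics import CORE, SegmentRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All free parameters of the method, with their defaults.

    YAML configs may use either nested mappings (``threshold: {eps: 0.2}``)
    or dotted keys (``threshold.eps``).
    """

    threshold_t0: Optional[float] = None  # None -> image mean
    threshold_eps: float = thresholding.DEFAULT_EPS
    threshold_polarity: str = "dark_foreground"
    chamfer_weights: tuple[int, int] = chamfer_watershed.DEFAULT_WEIGHTS
    watershed_connectivity: int = 8
    roundness_threshold: float = region_metrics.ROUNDNESS_THRESHOLD
    min_area: int = region_metrics.MIN_AREA
    gvf_mu: float = gvf_field.DEFAULT_MU
    gvf_max_iter: int = gvf_field.DEFAULT_MAX_ITER
    gvf_tol: float = gvf_field.DEFAULT_TOL
    gvf_sigma: float = gvf_field.DEFAULT_SIGMA
    critical_sim_threshold: float = gvf_field.SIM_THRESHOLD
    critical_min_directions: int = gvf_field.MIN_DIRECTIONS
    critical_search_radius_factor: float = gvf_field.SEARCH_RADIUS_FACTOR
    fcm_m: float = fcm_merge.DEFAULT_M
    fcm_tol: float = fcm_merge.DEFAULT_TOL
    fcm_max_iter: int = fcm_merge.DEFAULT_MAX_ITER
    fcm_weights: tuple[float, float, float] = fcm_merge.DEFAULT_WEIGHTS
    fcm_use_centroid_coords: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.roundness_threshold <= 1):
            raise ValueError("roundness threshold must lie in (0, 1]")
        if self.threshold_eps <= 0 or self.gvf_mu <= 0 or self.fcm_m <= 1:
            raise ValueError("threshold_eps > 0, gvf_mu > 0 and fcm_m > 1 required")
        if not (0 <= self.critical_sim_threshold <= 1):
            raise ValueError("similarity threshold must lie in [0, 1]")
        if not (1 <= self.critical_min_directions <= 8):
            raise ValueError("min_directions must lie in 1..8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}

        def _walk(prefix: str, node) -> None:
            if isinstance(node, dict):
                for k, v in node.items():
                    _walk(f"{prefix}.{k}" if prefix else str(k), v)
            else:
                flat[prefix] = node

        _walk("", raw)
        rename = {
            "threshold.t0": "threshold_t0",
            "threshold.eps": "threshold_eps",
            "threshold.polarity": "threshold_polarity",
            "chamfer.weights": "chamfer_weights",
            "watershed.connectivity": "watershed_connectivity",
            "roundness.threshold": "roundness_threshold",
            "min_area": "min_area",
            "gvf.mu": "gvf_mu",
            "gvf.max_iter": "gvf_max_iter",
            "gvf.tol": "gvf_tol",
            "gvf.sigma": "gvf_sigma",
            "critical.sim_threshold": "critical_sim_threshold",
            "critical.min_directions": "critical_min_directions",
            "critical.search_radius_factor": "critical_search_radius_factor",
            "fcm.m": "fcm_m",
            "fcm.tol": "fcm_tol",
            "fcm.max_iter": "fcm_max_iter",
            "fcm.weights": "fcm_weights",
            "fcm.use_centroid_coords": "fcm_use_centroid_coords",
        }
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for k, v in flat.items():
            name = rename.get(k, k.replace(".", "_"))
            if name not in known:
                raise ValueError(f"unknown config key: {k}")
            if name in ("chamfer_weights", "fcm_weights") and isinstance(v, list):
                v = tuple(v)
            kwargs[name] = v
        return cls(**kwargs)


@dataclass(frozen=True)
class PipelineResult:
    """Every stage artifact of one pipeline run."""

    threshold_state: thresholding.ThresholdState
    mask: thresholding.BinaryMask
    distance: chamfer_watershed.DistanceMap
    watershed: chamfer_watershed.WatershedResult
    records_pre: list[SegmentRecord]
    records: list[SegmentRecord]  # after final classification
    critical_results: dict[int, gvf_field.CriticalPointResult]
    groups: list[fcm_merge.MergeGroup]
    merged_labels: LabelMap
    granule_records: list[SegmentRecord]  # remeasured on merged labels

    @property
    def n_granules(self) -> int:
        return self.merged_labels.n_segments

    @property
    def n_core(self) -> int:
        return sum(1 for r in self.records if r.classification == CORE)


def run_pipeline(image: GrayImage, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full segmentation method on one image."""
    state = thresholding.iterative_threshold(
        image, t0=config.threshold_t0, eps=config.threshold_eps
    )
    logger.info("threshold converged: T0=%.1f -> T=%.2f (%d iterations)",
                state.t0, state.t, state.n_iter)
    mask = thresholding.binarize(
        image, state, dark_foreground=config.threshold_polarity == "dark_foreground"
    )
    if not mask.mask.any():
        logger.warning("empty foreground: nothing to segment")
        empty = LabelMap(mask.mask.astype(int))
        return PipelineResult(
            threshold_state=state,
            mask=mask,
            distance=chamfer_watershed.DistanceMap(mask.mask.astype(float)),
            watershed=chamfer_watershed.WatershedResult(empty, 0, []),
            records_pre=[],
            records=[],
            critical_results={},
            groups=[],
            merged_labels=empty,
            granule_records=[],
        )
    dmap = chamfer_watershed.chamfer_distance(mask, weights=config.chamfer_weights)
    ws = chamfer_watershed.watershed_segment(
        dmap, mask, connectivity=config.watershed_connectivity
    )
    logger.info("watershed: %d segments", ws.n_segments)
    measured = region_metrics.measure_regions(ws.labels, image)
    flagged = region_metrics.flag_by_roundness(
        measured, threshold=config.roundness_threshold, min_area=config.min_area
    )
    pending = [r for r in flagged if r.classification == region_metrics.PENDING]
    critical: dict[int, gvf_field.CriticalPointResult] = {}
    if pending:
        f = gvf_field.edge_map(image, sigma=config.gvf_sigma)
        vf = gvf_field.compute_gvf(
            f, mu=config.gvf_mu, max_iter=config.gvf_max_iter, tol=config.gvf_tol
        )
        for r in pending:
            critical[r.label] = gvf_field.find_critical_point(
                vf,
                r,
                ws.labels,
                search_radius=max(
                    3.0, config.critical_search_radius_factor * r.equivalent_diameter / 2.0
                ),
                sim_threshold=config.critical_sim_threshold,
                min_directions=config.critical_min_directions,
            )
    records = gvf_field.classify_segments(flagged, critical)
    n_core = sum(1 for r in records if r.classification == CORE)
    logger.info("classification: %d core / %d oversegment",
                n_core, len(records) - n_core)
    groups = fcm_merge.build_merge_groups(ws.labels, mask, records)
    merged = fcm_merge.merge_oversegments(
        ws.labels,
        groups,
        records,
        weights=config.fcm_weights,
        m=config.fcm_m,
        tol=config.fcm_tol,
        max_iter=config.fcm_max_iter,
        use_centroid_coords=config.fcm_use_centroid_coords,
    )
    granules = region_metrics.measure_regions(merged, image)
    granules = [replace(r, classification=CORE) for r in granules]
    logger.info("final granule count: %d", merged.n_segments)
    return PipelineResult(
        threshold_state=state,
        mask=mask,
        distance=dmap,
        watershed=ws,
        records_pre=measured,
        records=records,
        critical_results=critical,
        groups=groups,
        merged_labels=merged,
        granule_records=granules,
    )


def merge_only(
    image: GrayImage, labels: LabelMap, config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the classification + merge tail on a precomputed label map.

    Equals the tail of a full run whose watershed output matches
    ``labels``.  The foreground mask is taken as the labelled support.
    """
    labels = labels.compact()
    mask = thresholding.BinaryMask(labels.labels > 0)
    state = thresholding.iterative_threshold(image, eps=config.threshold_eps)
    dmap = chamfer_watershed.chamfer_distance(mask, weights=config.chamfer_weights)
    ws = chamfer_watershed.WatershedResult(labels, labels.n_segments, [])
    measured = region_metrics.measure_regions(labels, image)
    flagged = region_metrics.flag_by_roundness(
        measured, threshold=config.roundness_threshold, min_area=config.min_area
    )
    pending = [r for r in flagged if r.classification == region_metrics.PENDING]
    critical: dict[int, gvf_field.CriticalPointResult] = {}
    if pending:
        f = gvf_field.edge_map(image, sigma=config.gvf_sigma)
        vf = gvf_field.compute_gvf(
            f, mu=config.gvf_mu, max_iter=config.gvf_max_iter, tol=config.gvf_tol
        )
        for r in pending:
            critical[r.label] = gvf_field.find_critical_point(
                vf,
                r,
                labels,
                search_radius=max(
                    3.0, config.critical_search_radius_factor * r.equivalent_diameter / 2.0
                ),
                sim_threshold=config.critical_sim_threshold,
                min_directions=config.critical_min_directions,
            )
    records = gvf_field.classify_segments(flagged, critical)
    groups = fcm_merge.build_merge_groups(labels, mask, records)
    merged = fcm_merge.merge_oversegments(
        labels,
        groups,
        records,
        weights=config.fcm_weights,
        m=config.fcm_m,
        tol=config.fcm_tol,
        max_iter=config.fcm_max_iter,
        use_centroid_coords=config.fcm_use_centroid_coords,
    )
    granules = region_metrics.measure_regions(merged, image)
    granules = [replace(r, classification=CORE) for r in granules]
    return PipelineResult(
        threshold_state=state,
        mask=mask,
        distance=dmap,
        watershed=ws,
        records_pre=measured,
        records=records,
        critical_results=critical,
        groups=groups,
        merged_labels=merged,
        granule_records=granules,
    )
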