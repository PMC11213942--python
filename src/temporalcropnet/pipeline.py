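"""End-to-end extraction: point cloud in, per-plant records out.

Chains the processing stages: statistical outlier removal, tiling,
progressive-TIN-densification ground classification per tile, TIN height
normalization, CHM rasterization with gap filling, variable-window-filter
top detection, marker-based watershed delineation, segment pruning and
per-plant record extraction, plus cross-date matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chm as chm_mod
from . import crowns as crowns_mod
from . import ground as ground_mod
from . import pointcloud as pc_mod
from .crowns import GrowthSeries, PlantRecord
from .pointcloud import PointClass, PointCloud

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ExtractionResult", "extract_records", "extract_growth_series"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the extraction pipeline (all in meters/degrees)."""

    k_neighbors: int = 8
    std_multiplier: float = 3.0
    tile_size: float = 20.0
    tile_overlap: float = 1.0
    seed_grid: float = 1.0
    ptd_max_dist: float = 0.05
    ptd_max_angle: float = 30.0
    ptd_max_iters: int = 50
    chm_resolution: float = 0.015
    fill_window: int = 3
    fill_passes: int = 2
    vwf_radius_intercept: float = 0.10
    vwf_radius_slope: float = 0.3
    min_height: float = 0.10
    match_max_shift: float = 0.3


@dataclass
class ExtractionResult:
    """Artifacts of a single-date extraction."""

    records: list[PlantRecord]
    chm: chm_mod.CHMRaster
    labels: crowns_mod.LabelRaster
    tops: list[crowns_mod.CrownTop]
    cloud: PointCloud  # outlier-filtered, ground-classified, normalized
    removed_outliers: int


def classify_cloud(cloud: PointCloud, cfg: PipelineConfig) -> tuple[PointCloud, int]:
    """Outlier removal plus tile-wise PTD ground classification."""
    cloud, removed = pc_mod.remove_outliers(cloud, cfg.k_neighbors, cfg.std_multiplier)
    labels = np.full(len(cloud), int(PointClass.UNCLASSIFIED), dtype=np.uint8)
    for tile in pc_mod.tile_cloud(cloud, cfg.tile_size, cfg.tile_overlap):
        if len(tile.cloud) == 0:
            continue
        try:
            seeds = ground_mod.select_seeds(tile, cfg.seed_grid)
            tile_labels = ground_mod.classify_ground_ptd(
                tile, seeds, cfg.ptd_max_dist, cfg.ptd_max_angle, cfg.ptd_max_iters
            )
        except ValueError as exc:
            logger.warning("tile %s skipped: %s", tile.core_bounds, exc)
            continue
        labels[tile.indices[tile.core_mask]] = tile_labels[tile.core_mask]
    return cloud.with_labels(labels), removed


def extract_records(
    cloud: PointCloud, cfg: PipelineConfig | None = None, date_index: int = 1
) -> ExtractionResult:
    """Run the full single-date pipeline on one cloud."""
    cfg = cfg or PipelineConfig()
    if len(cloud) == 0:
        raise ValueError("cannot extract records from an empty cloud")
    classified, removed = classify_cloud(cloud, cfg)
    tin = ground_mod.build_ground_tin(classified)
    normalized = ground_mod.normalize_heights(classified, tin)
    raster = chm_mod.rasterize_chm(normalized, cfg.chm_resolution)
    for _ in range(cfg.fill_passes):
        raster = chm_mod.fill_chm_gaps(raster, cfg.fill_window)
    tops = crowns_mod.detect_crown_tops(
        raster, cfg.vwf_radius_intercept, cfg.vwf_radius_slope, cfg.min_height
    )
    if not tops:
        logger.warning("date %d: no crown tops detected", date_index)
        empty = crowns_mod.LabelRaster(raster.origin, raster.resolution, np.zeros(raster.shape))
        return ExtractionResult([], raster, empty, [], normalized, removed)
    labels = crowns_mod.segment_crowns(raster, tops, cfg.min_height)
    labels = crowns_mod.prune_segments(labels, tops)
    records = crowns_mod.extract_plant_records(labels, raster, tops, date_index)
    return ExtractionResult(records, raster, labels, tops, normalized, removed)


def extract_growth_series(
    clouds_by_date: list[tuple[int, PointCloud]], cfg: PipelineConfig | None = None
) -> tuple[list[GrowthSeries], list[ExtractionResult]]:
    """Per-date extraction plus cross-date plant matching."""
    cfg = cfg or PipelineConfig()
    results = [extract_records(cloud, cfg, date) for date, cloud in clouds_by_date]
    if len(results) < 2:
        return [], results
    series = crowns_mod.match_plants_across_dates(
        [r.records for r in results], cfg.match_max_shift
    )
    return series, results
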