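"""Synthetic multi-date TLS fields and growth tables with known truth.

The generator emulates a terrestrial-laser-scanned vegetable plot: a gently
sloping ground surface with Gaussian micro-roughness, plants on a regular
planting grid whose height follows per-plant logistic growth across
acquisition dates, crowns as surface-sampled half-ellipsoid caps (a scanner
sees surfaces, not volumes) with footprint radius proportional to height,
and sparse outlier returns in a band above the canopy (support
infrastructure and boundary-tree multipath produce high spurious returns;
near-ground noise is already covered by the roughness term).

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .crowns import GrowthSeries, PlantRecord
from .pointcloud import PointCloud

__all__ = [
    "FieldConfig",
    "well_separated_preset",
    "generate_field_series",
    "generate_growth_dataset",
    "logistic_height",
]


def logistic_height(h_inf, rate, midpoint, t):
    """Logistic growth curve H / (1 + exp(-r (t - t0)))."""
    return np.asarray(h_inf) / (1.0 + np.exp(-np.asarray(rate) * (np.asarray(t) - midpoint)))


@dataclass(frozen=True)
class FieldConfig:
    """Study-condition parameters of the synthetic field.

    Plants sit on an ``n_rows x n_cols`` grid with ``spacing`` meters
    between neighbours; the plot extends ``margin`` beyond the outermost
    plants.  Heights follow per-plant logistic growth (asymptote drawn
    uniformly from ``h_inf_range``) over ``n_dates`` acquisition dates at
    unit date spacing; crown footprint radius is ``crown_ratio * height``.
    """

    n_rows: int = 10
    n_cols: int = 10
    spacing: float = 1.0
    margin: float = 1.0
    n_dates: int = 4
    ground_slope: tuple[float, float] = (0.02, 0.01)
    roughness: float = 0.01
    h_inf_range: tuple[float, float] = (0.3, 1.0)
    growth_rate: float = 1.2
    midpoint: float = 2.0
    crown_ratio: float = 0.3
    crown_shell_sd: float = 0.05  # fractional radial depth of foliage returns
    ground_density: float = 200.0  # points per m^2
    points_per_plant: int = 800
    outlier_rate: float = 0.001  # fraction of structural points
    outlier_zband: tuple[float, float] = (1.5, 3.0)  # above local ground
    seed: int = 0

    @property
    def n_plants(self) -> int:
        return self.n_rows * self.n_cols


def well_separated_preset(**overrides) -> FieldConfig:
    """Preset with plant spacing far above twice the maximum crown radius.

    Asymptote heights are drawn from [0.7, 1.0] m so that even first-date
    plants (~0.16-0.23 m) stand clearly above the canopy-mask threshold and
    the ground-filter buffer (~0.1 m), and crowns (radius <= 0.3 m) never
    touch at 1 m spacing.  Dense sampling (2000 points/plant) keeps
    per-cell coverage high at centimetre-scale CHM resolutions.
    """
    cfg = FieldConfig(h_inf_range=(0.7, 1.0), points_per_plant=2000)
    return replace(cfg, **overrides)


def _ground_plane(cfg: FieldConfig, x, y):
    sx, sy = cfg.ground_slope
    return sx * np.asarray(x) + sy * np.asarray(y)


def generate_field_series(
    cfg: FieldConfig,
) -> tuple[list[tuple[int, PointCloud]], pd.DataFrame]:
    """Per-date point clouds plus the per-plant/date truth table.

    Returns ``(clouds, truth)`` where ``clouds`` is a list of
    ``(date_index, PointCloud)`` (date_index 1-based) and ``truth`` a
    DataFrame with columns plant_id, date_index, true_height,
    true_crown_area, true_x, true_y.
    """
    rng = np.random.default_rng(cfg.seed)
    # fixed per-plant positions and growth parameters
    px, py = np.meshgrid(
        cfg.margin + cfg.spacing * np.arange(cfg.n_cols),
        cfg.margin + cfg.spacing * np.arange(cfg.n_rows),
    )
    px = px.ravel()
    py = py.ravel()
    h_inf = rng.uniform(*cfg.h_inf_range, size=cfg.n_plants)
    extent_x = 2 * cfg.margin + cfg.spacing * max(cfg.n_cols - 1, 0)
    extent_y = 2 * cfg.margin + cfg.spacing * max(cfg.n_rows - 1, 0)
    n_ground = max(int(cfg.ground_density * extent_x * extent_y), 10)

    clouds = []
    truth_rows = []
    for date in range(1, cfg.n_dates + 1):
        heights = logistic_height(h_inf, cfg.growth_rate, cfg.midpoint, date)
        radii = cfg.crown_ratio * heights
        gx = rng.uniform(0, extent_x, n_ground)
        gy = rng.uniform(0, extent_y, n_ground)
        gz = _ground_plane(cfg, gx, gy) + rng.normal(0, cfg.roughness, n_ground)
        parts = [np.stack([gx, gy, gz], axis=1)]
        for pid in range(cfg.n_plants):
            h, r = heights[pid], radii[pid]
            n_pts = cfg.points_per_plant
            # surface of the upper half-ellipsoid (semi-axes r, r, h)
            cos_t = rng.uniform(0, 1, n_pts)
            sin_t = np.sqrt(1 - cos_t**2)
            phi = rng.uniform(0, 2 * np.pi, n_pts)
            # laser returns scatter radially inward from the crown hull
            # (foliage has depth); the hull itself is the structural truth
            depth = np.clip(1.0 - np.abs(rng.normal(0, cfg.crown_shell_sd, n_pts)), 0.3, 1.0)
            cx = px[pid] + depth * r * sin_t * np.cos(phi)
            cy = py[pid] + depth * r * sin_t * np.sin(phi)
            cz = _ground_plane(cfg, cx, cy) + depth * h * cos_t
            parts.append(np.stack([cx, cy, cz], axis=1))
            truth_rows.append((pid + 1, date, h, np.pi * r**2, px[pid], py[pid]))
        structural = np.concatenate(parts, axis=0)
        n_out = int(round(cfg.outlier_rate * len(structural)))
        if n_out:
            ox = rng.uniform(0, extent_x, n_out)
            oy = rng.uniform(0, extent_y, n_out)
            oz = _ground_plane(cfg, ox, oy) + rng.uniform(*cfg.outlier_zband, n_out)
            structural = np.concatenate([structural, np.stack([ox, oy, oz], axis=1)])
        clouds.append((date, PointCloud(structural, crs_note="synthetic local grid")))
    truth = pd.DataFrame(
        truth_rows,
        columns=["plant_id", "date_index", "true_height", "true_crown_area", "true_x", "true_y"],
    )
    return clouds, truth


def generate_growth_dataset(
    n_plants: int,
    h_inf_range: tuple[float, float] = (0.3, 1.0),
    growth_rate: float = 1.2,
    midpoint: float = 2.0,
    noise_sd: float = 0.05,
    n_stages: int = 4,
    crown_ratio: float = 0.3,
    seed: int = 0,
) -> list[GrowthSeries]:
    """Tabular growth series: logistic heights with multiplicative noise.

    height_t = H_inf / (1 + exp(-r (t - t0))) * (1 + eps),
    crown_area_t = pi * (crown_ratio * height_t)^2 * (1 + eps'),
    with eps, eps' ~ N(0, noise_sd^2) independent per plant and stage.
    Stage times are the date indices 1..n_stages.
    """
    if n_stages < 3:
        raise ValueError("need at least 3 stages (inputs plus a forecast target)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    h_inf = rng.uniform(*h_inf_range, size=n_plants)
    series = []
    grid = int(np.ceil(np.sqrt(n_plants)))
    for pid in range(n_plants):
        records = []
        cx, cy = float(pid % grid), float(pid // grid)
        for t in range(1, n_stages + 1):
            h = float(
                logistic_height(h_inf[pid], growth_rate, midpoint, t)
                * (1.0 + rng.normal(0, noise_sd))
            )
            base_area = np.pi * (crown_ratio * h) ** 2
            a = float(base_area * (1.0 + rng.normal(0, noise_sd)))
            records.append(
                PlantRecord(
                    plant_id=pid + 1,
                    date_index=t,
                    height=max(h, 1e-6),
                    crown_area=max(a, 1e-9),
                    centroid=(cx, cy),
                )
            )
        series.append(GrowthSeries(pid + 1, records))
    return series
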