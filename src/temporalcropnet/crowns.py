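"""Crown-top detection, watershed crown delineation and per-plant records.

The variable window filter (VWF) marks a CHM cell as a plant top when it is
the strict maximum within an adaptive radius ``r(h) = max(r_min, c * h)``
around it — short plants get the minimum window, taller plants a window
proportional to their height (vegetable crown radius is roughly 30% of
height).  Tops seed a marker-based watershed on the negated CHM restricted
to the canopy mask ``CHM >= min_height``; segments that end up without a
top are pruned as over-segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from .chm import CHMRaster

logger = logging.getLogger(__name__)

__all__ = [
    "CrownTop",
    "LabelRaster",
    "PlantRecord",
    "GrowthSeries",
    "detect_crown_tops",
    "segment_crowns",
    "prune_segments",
    "extract_plant_records",
    "match_plants_across_dates",
    "records_to_dataframe",
    "records_from_dataframe",
]


@dataclass(frozen=True)
class CrownTop:
    """A detected plant apex: raster cell, its center coordinates, height."""

    row: int
    col: int
    x: float
    y: float
    height: float


@dataclass
class LabelRaster:
    """Integer plant labels (>=1) on the CHM grid; 0 is background."""

    origin: tuple[float, float]
    resolution: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def to_geotiff(self, path) -> None:
        import tifffile

        from .chm import _GDAL_NODATA, _MODEL_PIXEL_SCALE, _MODEL_TIEPOINT

        rows = self.shape[0]
        x0, y0 = self.origin
        tifffile.imwrite(
            path,
            np.flipud(self.labels).astype(np.int32),
            extratags=[
                (_MODEL_PIXEL_SCALE, "d", 3, (self.resolution, self.resolution, 0.0)),
                (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0 + rows * self.resolution, 0.0)),
                (_GDAL_NODATA, "s", 0, "0"),
            ],
        )


@dataclass
class PlantRecord:
    """Structural parameters of one plant at one acquisition date."""

    plant_id: int
    date_index: int
    height: float
    crown_area: float
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(f"plant {self.plant_id}: height must be > 0")
        if self.crown_area <= 0:
            raise ValueError(f"plant {self.plant_id}: crown_area must be > 0")


@dataclass
class GrowthSeries:
    """One plant's records ordered by date_index (length >= 2)."""

    plant_id: int
    records: list[PlantRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("a growth series needs at least 2 records")
        dates = [r.date_index for r in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("date_index must be strictly increasing")
        if any(r.plant_id != self.plant_id for r in self.records):
            raise ValueError("all records must share the series plant_id")

    def __len__(self) -> int:
        return len(self.records)

    def values(self, features: tuple[str, ...] = ("height", "crown_area")) -> np.ndarray:
        """(n_dates, n_features) array of the requested record fields."""
        return np.array([[getattr(r, f) for f in features] for r in self.records])


# ---------------------------------------------------------------------------
# Variable window filter


def detect_crown_tops(
    chm: CHMRaster,
    radius_intercept: float = 0.10,
    radius_slope: float = 0.3,
    min_height: float = 0.10,
) -> list[CrownTop]:
    """Adaptive-radius local maxima of the CHM.

    A cell is a top iff its value is >= ``min_height`` and strictly greater
    than every other valid cell whose center lies within
    ``r = max(radius_intercept, radius_slope * h)`` of its own center
    (``h`` the cell's value).  Equal-valued cells inside one window keep
    only the first in row-major order.
    """
    if radius_intercept < chm.resolution:
        raise ValueError("radius_intercept must be at least one cell size")
    if radius_slope < 0:
        raise ValueError("radius_slope must be >= 0")
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    values = chm.values
    valid = chm.valid
    rows, cols = chm.shape
    res = chm.resolution
    tops: list[CrownTop] = []
    cand_rows, cand_cols = np.nonzero(valid & (values >= min_height))
    # circular offset masks cached by the exact radius in cell units
    mask_cache: dict[float, tuple[int, np.ndarray, np.ndarray]] = {}

    def window_offsets(radius: float):
        key = round(radius / res, 9)
        if key not in mask_cache:
            r_cells = int(np.floor(radius / res + 1e-12))
            di, dj = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
            within = (di**2 + dj**2) * res**2 <= radius**2 + 1e-12
            within[r_cells, r_cells] = False
            earlier = (di < 0) | ((di == 0) & (dj < 0))
            mask_cache[key] = (r_cells, within, earlier & within)
        return mask_cache[key]

    for i, j in zip(cand_rows.tolist(), cand_cols.tolist()):
        h = values[i, j]
        radius = max(radius_intercept, radius_slope * h)
        r_cells, within_full, earlier_full = window_offsets(radius)
        i0, i1 = max(0, i - r_cells), min(rows, i + r_cells + 1)
        j0, j1 = max(0, j - r_cells), min(cols, j + r_cells + 1)
        wi0, wj0 = i0 - (i - r_cells), j0 - (j - r_cells)
        within = within_full[wi0 : wi0 + (i1 - i0), wj0 : wj0 + (j1 - j0)]
        earlier = earlier_full[wi0 : wi0 + (i1 - i0), wj0 : wj0 + (j1 - j0)]
        patch = values[i0:i1, j0:j1]
        pvalid = valid[i0:i1, j0:j1]
        neigh = within & pvalid
        if np.any(patch[neigh] > h):
            continue
        if np.any(patch[earlier & pvalid] == h):
            continue  # row-major tie-break: an earlier equal cell wins
        x, y = chm.cell_center(i, j)
        tops.append(CrownTop(i, j, float(x), float(y), float(h)))
    return tops


# ---------------------------------------------------------------------------
# Watershed segmentation


def segment_crowns(
    chm: CHMRaster, tops: list[CrownTop], min_height: float = 0.10
) -> LabelRaster:
    """Marker-based watershed of the negated CHM restricted to the canopy mask."""
    if not tops:
        raise ValueError("segment_crowns needs at least one crown top")
    mask = chm.valid & (chm.values >= min_height)
    markers = np.zeros(chm.shape, dtype=np.int32)
    for k, top in enumerate(tops, start=1):
        if not mask[top.row, top.col]:
            raise ValueError(
                f"crown top at ({top.row}, {top.col}) lies outside the canopy mask"
            )
        markers[top.row, top.col] = k
    # peaks become basins on the negated surface; classic watershed
    elevation = np.where(chm.valid, -chm.values, 0.0)
    labels = watershed(elevation, markers=markers, mask=mask, compactness=0)
    return LabelRaster(chm.origin, chm.resolution, labels)


def prune_segments(labels: LabelRaster, tops: list[CrownTop]) -> LabelRaster:
    """Drop segments without a crown top; renumber survivors in top order."""
    lab = labels.labels
    mapping = np.zeros(lab.max() + 1, dtype=np.int32)
    next_id = 1
    for top in tops:
        old = lab[top.row, top.col]
        if old > 0 and mapping[old] == 0:
            mapping[old] = next_id
            next_id += 1
    kept = mapping[lab]
    dropped = len(np.unique(lab)) - 1 - (next_id - 1)
    if dropped:
        logger.info("pruned %d segments without crown tops", dropped)
    return LabelRaster(labels.origin, labels.resolution, kept)


def extract_plant_records(
    labels: LabelRaster, chm: CHMRaster, tops: list[CrownTop], date_index: int
) -> list[PlantRecord]:
    """Per-segment height (max CHM), crown area (cell count x res^2), centroid."""
    if labels.shape != chm.shape:
        raise ValueError("label raster and CHM geometries differ")
    lab = labels.labels
    n = int(lab.max())
    records: list[PlantRecord] = []
    res = labels.resolution
    rows_idx, cols_idx = np.nonzero(lab > 0)
    ids = lab[rows_idx, cols_idx]
    heights = chm.values[rows_idx, cols_idx]
    x, y = chm.cell_center(rows_idx, cols_idx)
    for plant_id in range(1, n + 1):
        sel = ids == plant_id
        if not sel.any():
            continue
        records.append(
            PlantRecord(
                plant_id=plant_id,
                date_index=date_index,
                height=float(heights[sel].max()),
                crown_area=float(sel.sum()) * res * res,
                centroid=(float(x[sel].mean()), float(y[sel].mean())),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cross-date matching


def match_plants_across_dates(
    records_by_date: list[list[PlantRecord]], max_shift: float = 0.3
) -> list[GrowthSeries]:
    """Greedy nearest-centroid matching of plants across acquisition dates.

    Plants do not move between dates; consecutive-date records whose
    centroids are within ``max_shift`` are chained (closest pairs first).
    Only plants present at every date yield a series; the rest are dropped
    with a logged count.
    """
    if len(records_by_date) < 2:
        raise ValueError("matching needs at least 2 dates")
    chains: list[list[PlantRecord]] = [[r] for r in records_by_date[0]]
    for nxt in records_by_date[1:]:
        if not nxt:
            chains = []
            break
        tails = np.array([c[-1].centroid for c in chains]) if chains else np.empty((0, 2))
        heads = np.array([r.centroid for r in nxt])
        pairs = []
        if len(tails):
            tree = cKDTree(heads)
            for ci, tail in enumerate(tails):
                for hi in tree.query_ball_point(tail, max_shift):
                    d = float(np.hypot(*(tail - heads[hi])))
                    pairs.append((d, ci, hi))
        pairs.sort()
        used_c: set[int] = set()
        used_h: set[int] = set()
        new_chains: list[list[PlantRecord]] = []
        for d, ci, hi in pairs:
            if ci in used_c or hi in used_h:
                continue
            used_c.add(ci)
            used_h.add(hi)
            new_chains.append(chains[ci] + [nxt[hi]])
        chains = new_chains
    n_first = len(records_by_date[0])
    if len(chains) < n_first:
        logger.info("dropped %d plants not matched across all dates", n_first - len(chains))
    series = []
    for chain in chains:
        pid = chain[0].plant_id
        recs = [
            PlantRecord(pid, r.date_index, r.height, r.crown_area, r.centroid)
            for r in chain
        ]
        series.append(GrowthSeries(pid, recs))
    return series


# ---------------------------------------------------------------------------
# Tabular I/O (PlantRecord CSV schema)

_CSV_COLUMNS = [
    "plant_id",
    "date_index",
    "height_m",
    "crown_area_m2",
    "centroid_x",
    "centroid_y",
]


def records_to_dataframe(series: list[GrowthSeries]):
    """Flatten series to the PlantRecord CSV schema."""
    import pandas as pd

    rows = [
        (s.plant_id, r.date_index, r.height, r.crown_area, r.centroid[0], r.centroid[1])
        for s in series
        for r in s.records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def records_from_dataframe(df) -> list[GrowthSeries]:
    """Rebuild GrowthSeries from the PlantRecord CSV schema."""
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    series = []
    for pid, grp in df.groupby("plant_id"):
        grp = grp.sort_values("date_index")
        recs = [
            PlantRecord(
                int(pid),
                int(row.date_index),
                float(row.height_m),
                float(row.crown_area_m2),
                (float(row.centroid_x), float(row.centroid_y)),
            )
            for row in grp.itertuples()
        ]
        if len(recs) >= 2:
            series.append(GrowthSeries(int(pid), recs))
    return series
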