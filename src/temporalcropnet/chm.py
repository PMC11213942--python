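"""Canopy height model rasterization and raster I/O.

Raster convention: south-west origin, row-major grid, row 0 southernmost;
cell (i, j) covers the half-open square
``[x0 + j*res, x0 + (j+1)*res) x [y0 + i*res, y0 + (i+1)*res)``.
The internal nodata sentinel is -1.0.  GeoTIFF I/O flips rows at the file
boundary (TIFF row 0 is the north edge) and tags pixel scale, tiepoint and
nodata so GIS tools georeference the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .pointcloud import PointClass, PointCloud

logger = logging.getLogger(__name__)

__all__ = ["CHMRaster", "rasterize_chm", "fill_chm_gaps"]

NODATA = -1.0

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


@dataclass
class CHMRaster:
    """Regular grid of canopy heights (m) above ground.

    ``origin`` is the south-west corner; ``values`` is (rows, cols) with
    row 0 southernmost.  Non-nodata values are >= 0.
    """

    origin: tuple[float, float]
    resolution: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return self.values != self.nodata

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        return (
            x0 + (np.asarray(col) + 0.5) * self.resolution,
            y0 + (np.asarray(row) + 0.5) * self.resolution,
        )

    # -- I/O ---------------------------------------------------------------

    def to_geotiff(self, path) -> None:
        rows = self.shape[0]
        x0, y0 = self.origin
        y_top = y0 + rows * self.resolution
        data = np.flipud(self.values).astype(np.float32)  # file row 0 = north
        tifffile.imwrite(
            path,
            data,
            extratags=[
                (_MODEL_PIXEL_SCALE, "d", 3, (self.resolution, self.resolution, 0.0)),
                (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y_top, 0.0)),
                (_GDAL_NODATA, "s", 0, str(self.nodata)),
            ],
        )

    @classmethod
    def from_geotiff(cls, path) -> "CHMRaster":
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
        try:
            sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
            tie = tags[_MODEL_TIEPOINT]
        except KeyError as exc:
            raise IOError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        if abs(sx - sy) > 1e-12:
            raise IOError(f"{path}: anisotropic pixels unsupported")
        nodata = float(tags.get(_GDAL_NODATA, NODATA))
        x0 = float(tie[3])
        y0 = float(tie[4]) - data.shape[0] * float(sx)
        values = np.flipud(np.asarray(data, dtype=np.float64))
        return cls((x0, y0), float(sx), values, nodata)

    def to_csv(self, path) -> None:
        """Plain-grid CSV export (row 0 southernmost) for inspection."""
        np.savetxt(path, self.values, fmt="%.4f", delimiter=",")


def rasterize_chm(
    cloud: PointCloud,
    resolution: float,
    extent: tuple[float, float, float, float] | None = None,
) -> CHMRaster:
    """Rasterize a height-normalized cloud to a CHM.

    Cell value is the maximum normalized height among ABOVE_GROUND points in
    the cell; cells containing only GROUND points get 0; empty cells get
    nodata.  NOISE points are ignored.  An unlabelled cloud is treated as
    all above-ground.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    if extent is None:
        xmin, ymin, xmax, ymax = cloud.bounds()
    else:
        xmin, ymin, xmax, ymax = extent
    cols = max(1, int(np.ceil((xmax - xmin) / resolution)))
    rows = max(1, int(np.ceil((ymax - ymin) / resolution)))
    col = np.floor((cloud.x - xmin) / resolution).astype(np.int64)
    row = np.floor((cloud.y - ymin) / resolution).astype(np.int64)
    inside = (col >= 0) & (col < cols) & (row >= 0) & (row < rows)
    # points exactly on the max edge belong to the last cell
    col = np.clip(col, 0, cols - 1)
    row = np.clip(row, 0, rows - 1)
    on_edge = (
        (cloud.x >= xmin) & (cloud.x <= xmax) & (cloud.y >= ymin) & (cloud.y <= ymax)
    )
    inside |= on_edge

    if cloud.labels is None:
        above = np.ones(len(cloud), dtype=bool)
        ground = np.zeros(len(cloud), dtype=bool)
    else:
        above = cloud.labels == int(PointClass.ABOVE_GROUND)
        ground = cloud.labels == int(PointClass.GROUND)

    flat = row * cols + col
    values = np.full(rows * cols, -np.inf)
    sel = inside & above
    np.maximum.at(values, flat[sel], cloud.z[sel])
    has_ground = np.zeros(rows * cols, dtype=bool)
    has_ground[flat[inside & ground]] = True
    values[(values == -np.inf) & has_ground] = 0.0
    values[values == -np.inf] = NODATA
    values = np.maximum(values, 0.0, where=values != NODATA, out=values)
    return CHMRaster((xmin, ymin), resolution, values.reshape(rows, cols))


def fill_chm_gaps(chm: CHMRaster, window: int = 3) -> CHMRaster:
    """Fill isolated nodata cells by the median of their valid neighbours.

    A nodata cell is filled when at least half of its ``window x window``
    neighbourhood (excluding itself) is valid.  Applied once, no iteration,
    so interiors of large gaps stay nodata.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    rows, cols = chm.shape
    half = window // 2
    padded = np.full((rows + 2 * half, cols + 2 * half), chm.nodata)
    padded[half:-half, half:-half] = chm.values
    offsets = [
        (di, dj)
        for di in range(-half, half + 1)
        for dj in range(-half, half + 1)
        if (di, dj) != (0, 0)
    ]
    stack = np.empty((len(offsets), rows, cols))
    for k, (di, dj) in enumerate(offsets):
        stack[k] = padded[half + di : half + di + rows, half + dj : half + dj + cols]
    valid = stack != chm.nodata
    count = valid.sum(axis=0)
    target = (chm.values == chm.nodata) & (count >= len(offsets) / 2)
    out = chm.values.copy()
    if target.any():
        sub = np.where(valid[:, target], stack[:, target], np.nan)
        out[target] = np.nanmedian(sub, axis=0)
    return CHMRaster(chm.origin, chm.resolution, out, chm.nodata)
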