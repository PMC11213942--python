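"""Point-cloud container, file I/O, statistical outlier removal and tiling.

Clouds are plain ``(N, 3)`` float arrays of x/y/z in meters (projected CRS)
with an optional per-point classification.  Class codes follow the LAS
convention so that LAS round-trips are lossless:

====================  ====
UNCLASSIFIED             1
GROUND                   2
ABOVE_GROUND             5
NOISE                    7
====================  ====
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _las

logger = logging.getLogger(__name__)

__all__ = [
    "PointClass",
    "PointCloud",
    "Tile",
    "read_point_cloud",
    "write_point_cloud",
    "remove_outliers",
    "tile_cloud",
]


class PointClass(IntEnum):
    """Per-point classification; values are the LAS classification codes."""

    UNCLASSIFIED = 1
    GROUND = 2
    ABOVE_GROUND = 5
    NOISE = 7


@dataclass
class PointCloud:
    """A set of 3-D points in meters with optional class labels.

    Parameters
    ----------
    xyz : (N, 3) float array
        Point coordinates; all values must be finite.
    labels : (N,) integer array, optional
        Per-point :class:`PointClass` codes.
    crs_note : str
        Free-text tag describing the projected CRS (not interpreted).
    """

    xyz: np.ndarray
    labels: np.ndarray | None = None
    crs_note: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (N, 3), got {self.xyz.shape}")
        if not np.isfinite(self.xyz).all():
            raise ValueError("point coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.uint8)
            if self.labels.shape != (len(self.xyz),):
                raise ValueError("labels must have one entry per point")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the xy footprint."""
        if len(self) == 0:
            raise ValueError("empty cloud has no bounds")
        return (
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()),
            float(self.y.max()),
        )

    def take(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at ``index`` (order preserved), labels carried along."""
        labels = None if self.labels is None else self.labels[index]
        return PointCloud(self.xyz[index], labels, self.crs_note)

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz.copy(), np.asarray(labels), self.crs_note)


@dataclass
class Tile:
    """One tile of a larger cloud.

    ``bounds`` is the buffered footprint (core plus overlap margin) and
    ``core_bounds`` the exclusive core; both are half-open on their max
    edges.  ``indices`` maps tile points back to the parent cloud and
    ``core_mask`` flags the points whose core this tile owns.
    """

    cloud: PointCloud
    bounds: tuple[float, float, float, float]
    core_bounds: tuple[float, float, float, float]
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    core_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


# ---------------------------------------------------------------------------
# File I/O


_EXT_FORMAT = {
    ".las": "las",
    ".laz": "laz",
    ".ply": "ply",
    ".xyz": "xyz",
    ".csv": "xyz",
    ".txt": "xyz",
}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer point-cloud format from extension {path.suffix!r}"
        ) from None


def read_point_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a point cloud from LAS, PLY or XYZ/CSV.

    ``format='auto'`` dispatches on the file extension.  LAZ is recognized
    but not supported (compressed LAS requires an external decoder).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"point-cloud file not found: {path}")
    fmt = _resolve_format(path, format)
    if fmt == "laz":
        raise IOError("LAZ (compressed LAS) is not supported; decompress to LAS first")
    if fmt == "las":
        xyz, classification = _las.read_las(path)
        return PointCloud(xyz, classification)
    if fmt == "ply":
        return PointCloud(_read_ply(path))
    if fmt == "xyz":
        return PointCloud(_read_xyz(path))
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path: str | Path, format: str = "auto") -> None:
    """Write a cloud to LAS, PLY or XYZ/CSV.

    Labels are stored in the LAS classification field; PLY and XYZ have no
    classification slot, so labels are dropped with a logged warning.
    """
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "laz":
        raise IOError("LAZ output is not supported; write LAS instead")
    if fmt == "las":
        _las.write_las(path, cloud.xyz, cloud.labels)
        return
    if cloud.labels is not None:
        logger.warning("format %s has no classification field; labels dropped", fmt)
    if fmt == "ply":
        _write_ply(path, cloud.xyz)
    elif fmt == "xyz":
        np.savetxt(path, cloud.xyz, fmt="%.6f", delimiter=",", header="x,y,z", comments="")
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")


def _read_xyz(path: Path) -> np.ndarray:
    """Comma- or whitespace-separated x y z; header auto-detected."""
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "," if "," in sample.splitlines()[0] else None
        first = sample.splitlines()[0]
        tokens = first.split(",") if delimiter else first.split()
        skip = 0
        try:
            [float(t) for t in tokens[:3]]
        except ValueError:
            skip = 1
        data = np.loadtxt(fh, delimiter=delimiter, skiprows=skip, ndmin=2)
    if data.shape[1] < 3:
        raise IOError(f"{path}: expected at least 3 columns, got {data.shape[1]}")
    return data[:, :3]


def _read_ply(path: Path) -> np.ndarray:
    """Vertex x/y/z from ascii or binary_little_endian PLY."""
    _PLY_TYPES = {
        "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
        "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
        "short": "<i2", "ushort": "<u2", "char": "i1", "uchar": "u1",
        "int8": "i1", "uint8": "u1", "int16": "<i2", "uint16": "<u2",
    }
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise IOError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise IOError(f"{path}: truncated PLY header")
            parts = line.decode("ascii", "replace").split()
            if not parts:
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    n_vertex = int(parts[2])
            elif parts[0] == "property" and in_vertex:
                if parts[1] == "list":
                    raise IOError(f"{path}: list properties on vertices unsupported")
                props.append((parts[2], _PLY_TYPES[parts[1]]))
            elif parts[0] == "end_header":
                break
        if n_vertex is None:
            raise IOError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise IOError(f"{path}: vertex element lacks property {axis!r}")
        if fmt == "ascii":
            rows = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
            cols = [names.index(a) for a in ("x", "y", "z")]
            return rows[:, cols].astype(np.float64)
        if fmt == "binary_little_endian":
            dtype = np.dtype(props)
            data = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype)
            return np.stack([data[a].astype(np.float64) for a in ("x", "y", "z")], axis=1)
        raise IOError(f"{path}: unsupported PLY format {fmt!r}")


def _write_ply(path: Path, xyz: np.ndarray) -> None:
    with open(path, "wb") as fh:
        fh.write(
            (
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(xyz)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                "end_header\n"
            ).encode("ascii")
        )
        np.savetxt(fh, xyz, fmt="%.8f")


# ---------------------------------------------------------------------------
# Neighbourhood-threshold outlier removal


def remove_outliers(
    cloud: PointCloud, k_neighbors: int = 8, std_multiplier: float = 3.0
) -> tuple[PointCloud, int]:
    """Statistical outlier removal on k-nearest-neighbour mean distances.

    For each point the mean distance ``d_i`` to its ``k_neighbors`` nearest
    neighbours is computed; points with
    ``d_i > mean(d) + std_multiplier * sd(d)`` are excised (not relabelled).
    Returns the filtered cloud and the number of points removed.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if std_multiplier <= 0:
        raise ValueError("std_multiplier must be > 0")
    if len(cloud) <= k_neighbors:
        logger.warning(
            "cloud has %d points <= k_neighbors=%d; outlier removal skipped",
            len(cloud),
            k_neighbors,
        )
        return cloud, 0
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=k_neighbors + 1)
    mean_d = dist[:, 1:].mean(axis=1)  # drop self-distance column
    threshold = mean_d.mean() + std_multiplier * mean_d.std()
    keep = mean_d <= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d outlier points (threshold %.4f m)", removed, threshold)
    return cloud.take(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# Tiling


def tile_cloud(cloud: PointCloud, tile_size: float, overlap: float = 0.0) -> list[Tile]:
    """Split a cloud into a regular grid of overlapping tiles.

    Core bounds are half-open on their max edges; every point belongs to
    exactly one tile's core (points on the global max edge are owned by the
    last row/column).  Each tile's cloud additionally contains the points in
    the overlap buffer around its core.
    """
    if not tile_size > 2 * overlap:
        raise ValueError("tile_size must exceed 2 * overlap")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if len(cloud) == 0:
        return []
    xmin, ymin, xmax, ymax = cloud.bounds()
    nx = max(1, math.ceil((xmax - xmin) / tile_size)) if xmax > xmin else 1
    ny = max(1, math.ceil((ymax - ymin) / tile_size)) if ymax > ymin else 1
    # Core ownership: floor index, clipped so the max-edge points fall in the
    # last row/column.
    ix = np.clip(((cloud.x - xmin) / tile_size).astype(np.intp), 0, nx - 1)
    iy = np.clip(((cloud.y - ymin) / tile_size).astype(np.intp), 0, ny - 1)
    tiles: list[Tile] = []
    for j in range(ny):
        for i in range(nx):
            cx0 = xmin + i * tile_size
            cy0 = ymin + j * tile_size
            cx1 = cx0 + tile_size
            cy1 = cy0 + tile_size
            bx0, by0 = cx0 - overlap, cy0 - overlap
            bx1, by1 = cx1 + overlap, cy1 + overlap
            in_core = (ix == i) & (iy == j)
            in_bounds = in_core | (
                (cloud.x >= bx0) & (cloud.x < bx1) & (cloud.y >= by0) & (cloud.y < by1)
            )
            idx = np.flatnonzero(in_bounds)
            tiles.append(
                Tile(
                    cloud=cloud.take(idx),
                    bounds=(bx0, by0, bx1, by1),
                    core_bounds=(cx0, cy0, cx1, cy1),
                    indices=idx,
                    core_mask=in_core[idx],
                )
            )
    return tiles
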