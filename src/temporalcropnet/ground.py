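"""Ground/above-ground classification and height normalization.

Implements progressive TIN densification (PTD): a triangulated ground
surface is grown from per-cell lowest seed points; an unclassified point is
accepted as ground when it is close to the TIN facet below it and the line
to the facet's nearest vertex makes a shallow angle with the facet.  Heights
are then normalized by subtracting the interpolated TIN ground elevation
(the furrow-level datum).

Defaults target short vegetable crops (0.1-1 m plants on ~1 m planting
grids): seed_grid 1.0 m, max_dist 0.10 m, max_angle 30 deg.  Forest-scale
PTD parameterizations are far too coarse at this scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .pointcloud import PointClass, PointCloud, Tile

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTIN",
    "select_seeds",
    "classify_ground_ptd",
    "build_ground_tin",
    "ground_elevation",
    "normalize_heights",
]


@dataclass
class GroundTIN:
    """Delaunay triangulation (in xy) of classified ground points."""

    vertices: np.ndarray  # (M, 3)
    triangles: np.ndarray  # (K, 3) indices into vertices
    _delaunay: Delaunay = field(repr=False, default=None)
    _kdtree: cKDTree = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._delaunay is None:
            self._delaunay = Delaunay(self.vertices[:, :2])
            self.triangles = self._delaunay.simplices
        if self._kdtree is None:
            self._kdtree = cKDTree(self.vertices[:, :2])


def select_seeds(tile: Tile, seed_grid: float = 1.0) -> np.ndarray:
    """Indices (into the tile's cloud) of the lowest point per seed cell.

    The tile footprint is divided into ``seed_grid`` x ``seed_grid`` cells
    anchored at the tile's min corner; ties on z go to the smallest index.
    """
    if seed_grid <= 0:
        raise ValueError("seed_grid must be > 0")
    cloud = tile.cloud
    if len(cloud) == 0:
        raise ValueError("cannot select seeds from an empty tile")
    x0, y0 = tile.bounds[0], tile.bounds[1]
    ci = np.floor((cloud.x - x0) / seed_grid).astype(np.int64)
    cj = np.floor((cloud.y - y0) / seed_grid).astype(np.int64)
    cell = ci * (cj.max() + 1 if len(cj) else 1) + cj
    # stable lexsort (cell, z, index): first hit per cell is the lowest-z,
    # earliest-index point.
    order = np.lexsort((np.arange(len(cloud)), cloud.z, cell))
    sorted_cell = cell[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = sorted_cell[1:] != sorted_cell[:-1]
    return np.sort(order[first])


def classify_ground_ptd(
    tile: Tile,
    seeds: np.ndarray,
    max_dist: float = 0.10,
    max_angle: float = 30.0,
    max_iters: int = 50,
    max_facet_slope: float = 45.0,
) -> np.ndarray:
    """Progressive TIN densification over one tile.

    Returns per-point labels (:class:`PointClass` codes): seeds and accepted
    points GROUND, the rest ABOVE_GROUND.  Acceptance requires both the
    perpendicular distance to the containing TIN facet <= ``max_dist`` and
    the angle between the facet and the segment to the facet's nearest
    vertex <= ``max_angle`` degrees.

    Facets steeper than ``max_facet_slope`` degrees never accept points:
    near-vertical sliver facets (which arise along canopy fringes) would
    otherwise ladder the densification up any dense off-terrain surface,
    since a point straight above a vertical facet passes both criteria.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    if not 0 < max_angle < 90:
        raise ValueError("max_angle must be in (0, 90) degrees")
    if not 0 < max_facet_slope <= 90:
        raise ValueError("max_facet_slope must be in (0, 90] degrees")
    cloud = tile.cloud
    xyz = cloud.xyz
    n = len(xyz)
    ground = np.zeros(n, dtype=bool)
    ground[np.asarray(seeds, dtype=np.intp)] = True
    if ground.sum() < 3:
        raise ValueError("PTD needs at least 3 seed points")
    tan_max = np.tan(np.radians(max_angle))

    for _ in range(max_iters):
        gidx = np.flatnonzero(ground)
        try:
            tri = Delaunay(xyz[gidx, :2])
        except Exception as exc:  # qhull failure on degenerate seeds
            raise ValueError(f"ground points are degenerate (collinear?): {exc}") from exc
        cand = np.flatnonzero(~ground)
        if len(cand) == 0:
            break
        simplex = tri.find_simplex(xyz[cand, :2])
        inside = simplex >= 0
        # outside the current hull (boundary strips) the facet rule cannot
        # apply; accept against the nearest ground vertex instead, with the
        # same distance bound and the angle measured from the horizontal
        outside = cand[~inside]
        newly = np.zeros(0, dtype=np.intp)
        if len(outside):
            kdt = cKDTree(xyz[gidx, :2])
            hdist, nearest = kdt.query(xyz[outside, :2])
            dz = np.abs(xyz[outside, 2] - xyz[gidx[nearest], 2])
            ok = (dz <= max_dist) & (dz <= tan_max * np.maximum(hdist, 1e-12))
            newly = outside[ok]
        cand = cand[inside]
        if len(cand) == 0 and len(newly) == 0:
            break
        if len(cand) == 0:
            ground[newly] = True
            continue
        tri_idx = tri.simplices[simplex[inside]]  # (m, 3) into gidx
        verts = xyz[gidx[tri_idx]]  # (m, 3, 3)
        p = xyz[cand]
        # facet plane normal
        e1 = verts[:, 1] - verts[:, 0]
        e2 = verts[:, 2] - verts[:, 0]
        normal = np.cross(e1, e2)
        norm = np.linalg.norm(normal, axis=1)
        norm[norm == 0] = np.inf
        # facet slope from the vertical component of the unit normal
        cos_slope = np.abs(normal[:, 2]) / norm
        gentle = cos_slope >= np.cos(np.radians(max_facet_slope))
        dist = np.abs(np.einsum("ij,ij->i", normal, p - verts[:, 0])) / norm
        # nearest facet vertex and the segment angle to the facet plane
        d2v = np.linalg.norm(p[:, None, :] - verts, axis=2)  # (m, 3)
        seg = d2v.min(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            horiz = np.sqrt(np.maximum(seg**2 - dist**2, 0.0))
            tan_angle = np.where(horiz > 0, dist / horiz, np.inf)
        tan_angle[seg == 0] = 0.0  # duplicate of a vertex: trivially ground
        accept = gentle & (dist <= max_dist) & (tan_angle <= tan_max)
        if not accept.any() and len(newly) == 0:
            break
        ground[cand[accept]] = True
        ground[newly] = True

    # final buffer pass: densification under the angle criterion is
    # conservative at scanner densities (a noisy ground return a few sigma
    # above a locally dense TIN is geometrically indistinguishable from low
    # vegetation), so points within max_dist of the converged surface are
    # classified ground even if the iteration never accepted them.
    rest = np.flatnonzero(~ground)
    if len(rest):
        gidx = np.flatnonzero(ground)
        tri = Delaunay(xyz[gidx, :2])
        simplex = tri.find_simplex(xyz[rest, :2])
        inside = simplex >= 0
        if inside.any():
            tri_idx = tri.simplices[simplex[inside]]
            verts = xyz[gidx[tri_idx]]
            p = xyz[rest[inside]]
            normal = np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0])
            norm = np.linalg.norm(normal, axis=1)
            norm[norm == 0] = np.inf
            dist = np.abs(np.einsum("ij,ij->i", normal, p - verts[:, 0])) / norm
            ground[rest[inside][dist <= max_dist]] = True
        if (~inside).any():
            kdt = cKDTree(xyz[gidx, :2])
            out = rest[~inside]
            _, nearest = kdt.query(xyz[out, :2])
            dz = np.abs(xyz[out, 2] - xyz[gidx[nearest], 2])
            ground[out[dz <= max_dist]] = True

    labels = np.full(n, int(PointClass.ABOVE_GROUND), dtype=np.uint8)
    labels[ground] = int(PointClass.GROUND)
    return labels


def build_ground_tin(cloud: PointCloud) -> GroundTIN:
    """Delaunay TIN (in xy) over the cloud's GROUND-labelled points."""
    if cloud.labels is None:
        raise ValueError("cloud has no labels; run ground classification first")
    gmask = cloud.labels == int(PointClass.GROUND)
    if gmask.sum() < 3:
        raise ValueError("need at least 3 ground points to build a TIN")
    vertices = cloud.xyz[gmask]
    try:
        dela = Delaunay(vertices[:, :2])
    except Exception as exc:
        raise ValueError(f"ground points do not triangulate: {exc}") from exc
    return GroundTIN(vertices=vertices, triangles=dela.simplices, _delaunay=dela)


def ground_elevation(
    tin: GroundTIN, x: np.ndarray | float, y: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Ground elevation at query xy by barycentric interpolation.

    Queries outside the convex hull return the nearest vertex's elevation
    and are flagged in the second (boolean ``extrapolated``) return.
    Accepts scalars or arrays; always returns arrays.
    """
    xq = np.atleast_1d(np.asarray(x, dtype=np.float64))
    yq = np.atleast_1d(np.asarray(y, dtype=np.float64))
    pts = np.stack([xq, yq], axis=1)
    dela = tin._delaunay
    simplex = dela.find_simplex(pts)
    z = np.empty(len(pts), dtype=np.float64)
    extrapolated = simplex < 0
    inside = ~extrapolated
    if inside.any():
        s = simplex[inside]
        # barycentric coordinates from the cached affine transforms
        T = dela.transform[s]
        b2 = np.einsum("ijk,ik->ij", T[:, :2, :], pts[inside] - T[:, 2, :])
        bary = np.concatenate([b2, 1.0 - b2.sum(axis=1, keepdims=True)], axis=1)
        z[inside] = np.einsum("ij,ij->i", bary, tin.vertices[dela.simplices[s], 2])
    if extrapolated.any():
        _, nearest = tin._kdtree.query(pts[extrapolated])
        z[extrapolated] = tin.vertices[nearest, 2]
    return z, extrapolated


def normalize_heights(cloud: PointCloud, tin: GroundTIN) -> PointCloud:
    """Replace z by height above the TIN ground surface.

    Negative results (sensor noise below the fitted ground) are clamped to
    zero; the clamp count is logged.
    """
    gz, _ = ground_elevation(tin, cloud.x, cloud.y)
    h = cloud.z - gz
    clamped = int((h < 0).sum())
    if clamped:
        logger.info("clamped %d negative normalized heights to 0", clamped)
    out = cloud.xyz.copy()
    out[:, 2] = np.maximum(h, 0.0)
    labels = None if cloud.labels is None else cloud.labels.copy()
    return PointCloud(out, labels, cloud.crs_note)
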