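"""Ground classification (PTD), TIN interpolation, normalization, CHM."""

import numpy as np
import pytest

from temporalcropnet import (
    CHMRaster,
    PointClass,
    PointCloud,
    build_ground_tin,
    classify_ground_ptd,
    fill_chm_gaps,
    ground_elevation,
    normalize_heights,
    rasterize_chm,
    select_seeds,
    tile_cloud,
)
from temporalcropnet.chm import NODATA


def _plane_cloud(rng, n=2000, extent=5.0, slope=(0.0, 0.0), noise=0.0):
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    z = slope[0] * x + slope[1] * y + (rng.normal(0, noise, n) if noise else 0.0)
    return PointCloud(np.stack([x, y, z], axis=1))


class TestSeeds:
    def test_flat_plane_one_seed_per_cell(self, rng):
        cloud = _plane_cloud(rng, n=500, extent=5.0)
        tile = tile_cloud(cloud, 20.0)[0]
        seeds = select_seeds(tile, seed_grid=5.0)
        assert len(seeds) == 1
        assert cloud.z[seeds[0]] == cloud.z.min()

    def test_seeds_are_per_cell_minima(self, small_field):
        cfg, clouds, truth = small_field
        cloud = clouds[-1][1]
        tile = tile_cloud(cloud, 50.0)[0]
        seeds = select_seeds(tile, seed_grid=1.0)
        # brute-force oracle: per-cell argmin
        x0, y0 = tile.bounds[0], tile.bounds[1]
        ci = np.floor((cloud.x - x0) / 1.0).astype(int)
        cj = np.floor((cloud.y - y0) / 1.0).astype(int)
        expected = set()
        for key in set(zip(ci.tolist(), cj.tolist())):
            members = np.flatnonzero((ci == key[0]) & (cj == key[1]))
            expected.add(members[np.lexsort((members, cloud.z[members]))[0]])
        assert set(seeds.tolist()) == expected

    def test_tie_goes_to_earlier_index(self):
        xyz = np.array([[0.5, 0.5, 1.0], [0.6, 0.6, 1.0], [0.4, 0.4, 2.0]])
        tile = tile_cloud(PointCloud(xyz), 10.0)[0]
        seeds = select_seeds(tile, seed_grid=10.0)
        assert seeds.tolist() == [0]


class TestPTD:
    def test_seed_only_cloud_all_ground(self, rng):
        cloud = _plane_cloud(rng, n=30, extent=5.0)
        tile = tile_cloud(cloud, 20.0)[0]
        seeds = np.arange(len(cloud))
        labels = classify_ground_ptd(tile, seeds, 0.1, 30.0)
        assert (labels == PointClass.GROUND).all()

    @pytest.mark.parametrize("slope", [(0.0, 0.0), (np.tan(np.radians(5.0)), 0.0)])
    def test_plane_plus_plants_separated(self, rng, slope):
        ground = _plane_cloud(rng, n=3000, extent=6.0, slope=slope)
        # plant points well above the plane
        px = rng.uniform(1, 5, 400)
        py = rng.uniform(1, 5, 400)
        pz = slope[0] * px + slope[1] * py + rng.uniform(0.3, 0.8, 400)
        cloud = PointCloud(np.vstack([ground.xyz, np.stack([px, py, pz], axis=1)]))
        tile = tile_cloud(cloud, 20.0)[0]
        seeds = select_seeds(tile, seed_grid=1.0)
        labels = classify_ground_ptd(tile, seeds, max_dist=0.1, max_angle=30.0)
        assert (labels[:3000] == PointClass.GROUND).all()
        assert (labels[3000:] == PointClass.ABOVE_GROUND).all()

    def test_ground_accuracy_with_noise(self, rng):
        # roughness sigma = max_dist / 3 -> >= 99% accuracy required
        cloud = _plane_cloud(rng, n=5000, extent=6.0, slope=(0.02, 0.01), noise=0.1 / 3)
        tile = tile_cloud(cloud, 20.0)[0]
        seeds = select_seeds(tile, 1.0)
        labels = classify_ground_ptd(tile, seeds, max_dist=0.1, max_angle=30.0)
        assert (labels == PointClass.GROUND).mean() >= 0.99

    def test_collinear_seeds_raise(self):
        xyz = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        tile = tile_cloud(PointCloud(xyz), 20.0)[0]
        with pytest.raises(ValueError):
            classify_ground_ptd(tile, np.arange(10), 0.1, 30.0)


class TestTIN:
    def test_three_points_one_triangle(self):
        cloud = PointCloud(
            np.array([[0, 0, 0.0], [1, 0, 0.1], [0, 1, 0.2]]),
            labels=np.full(3, PointClass.GROUND),
        )
        tin = build_ground_tin(cloud)
        assert len(tin.triangles) == 1

    def test_square_two_triangles(self):
        cloud = PointCloud(
            np.array([[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0], [1, 1, 0.0]]),
            labels=np.full(4, PointClass.GROUND),
        )
        tin = build_ground_tin(cloud)
        assert len(tin.triangles) == 2

    def test_triangles_tile_the_hull(self, rng):
        pts = rng.uniform(0, 10, size=(100, 2))
        cloud = PointCloud(
            np.column_stack([pts, np.zeros(100)]), labels=np.full(100, PointClass.GROUND)
        )
        tin = build_ground_tin(cloud)
        from scipy.spatial import ConvexHull

        tri_area = 0.0
        for t in tin.triangles:
            a, b, c = tin.vertices[t][:, :2]
            tri_area += abs((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0]) / 2
        assert tri_area == pytest.approx(ConvexHull(pts).volume, rel=1e-9)

    def test_vertex_query_exact(self):
        cloud = PointCloud(
            np.array([[0, 0, 1.0], [2, 0, 2.0], [0, 2, 3.0], [2, 2, 4.0]]),
            labels=np.full(4, PointClass.GROUND),
        )
        tin = build_ground_tin(cloud)
        z, extr = ground_elevation(tin, 2.0, 2.0)
        assert z[0] == pytest.approx(4.0, abs=1e-12)
        assert not extr[0]

    def test_plane_interpolation_exact(self, rng):
        # barycentric interpolation is exact for affine surfaces
        pts = rng.uniform(0, 10, size=(60, 2))
        z = 0.1 * pts[:, 0] + 0.05 * pts[:, 1]
        cloud = PointCloud(np.column_stack([pts, z]), labels=np.full(60, PointClass.GROUND))
        tin = build_ground_tin(cloud)
        qx = rng.uniform(2, 8, 40)
        qy = rng.uniform(2, 8, 40)
        zi, extr = ground_elevation(tin, qx, qy)
        inside = ~extr
        assert inside.any()
        np.testing.assert_allclose(zi[inside], 0.1 * qx[inside] + 0.05 * qy[inside], atol=1e-9)

    def test_outside_hull_extrapolates_nearest_vertex(self):
        cloud = PointCloud(
            np.array([[0, 0, 1.0], [1, 0, 2.0], [0, 1, 3.0]]),
            labels=np.full(3, PointClass.GROUND),
        )
        tin = build_ground_tin(cloud)
        z, extr = ground_elevation(tin, 11.0, 0.0)
        assert extr[0]
        assert z[0] == pytest.approx(2.0)

    def test_too_few_ground_points_raise(self):
        cloud = PointCloud(np.zeros((5, 3)), labels=np.full(5, PointClass.ABOVE_GROUND))
        with pytest.raises(ValueError, match="3 ground"):
            build_ground_tin(cloud)


class TestNormalize:
    def test_tin_vertices_map_to_zero(self, rng):
        cloud = _plane_cloud(rng, n=50, extent=4.0, slope=(0.1, 0.0))
        cloud = cloud.with_labels(np.full(50, PointClass.GROUND))
        tin = build_ground_tin(cloud)
        norm = normalize_heights(cloud, tin)
        np.testing.assert_allclose(norm.z, 0.0, atol=1e-9)

    def test_plant_height_is_difference(self):
        ground = PointCloud(
            np.array([[0, 0, 0.25], [1, 0, 0.25], [0, 1, 0.25], [1, 1, 0.25]]),
            labels=np.full(4, PointClass.GROUND),
        )
        tin = build_ground_tin(ground)
        plant = PointCloud(np.array([[0.5, 0.5, 0.75]]), labels=np.array([PointClass.ABOVE_GROUND]))
        norm = normalize_heights(plant, tin)
        assert norm.z[0] == pytest.approx(0.50)

    def test_below_ground_clamped(self, caplog):
        ground = PointCloud(
            np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 1.0]]),
            labels=np.full(3, PointClass.GROUND),
        )
        tin = build_ground_tin(ground)
        noisy = PointCloud(np.array([[0.3, 0.3, 0.5]]))
        with caplog.at_level("INFO"):
            norm = normalize_heights(noisy, tin)
        assert norm.z[0] == 0.0


class TestRasterize:
    def test_single_point(self):
        cloud = PointCloud(np.array([[0.01, 0.01, 0.4], [0.9, 0.9, 0.0]]),
                           labels=np.array([PointClass.ABOVE_GROUND, PointClass.ABOVE_GROUND]))
        chm = rasterize_chm(cloud, resolution=0.5)
        assert chm.values[0, 0] == pytest.approx(0.4)

    def test_max_aggregation(self):
        cloud = PointCloud(
            np.array([[0.1, 0.1, 0.3], [0.2, 0.2, 0.6], [3.0, 3.0, 0.1]]),
            labels=np.full(3, PointClass.ABOVE_GROUND),
        )
        chm = rasterize_chm(cloud, resolution=1.0)
        assert chm.values[0, 0] == pytest.approx(0.6)

    def test_ground_only_cells_zero_and_empty_nodata(self):
        cloud = PointCloud(
            np.array([[0.5, 0.5, 0.0], [2.5, 0.5, 0.7], [2.5, 2.5, 0.2]]),
            labels=np.array([PointClass.GROUND, PointClass.ABOVE_GROUND, PointClass.ABOVE_GROUND]),
        )
        chm = rasterize_chm(cloud, resolution=1.0, extent=(0, 0, 3, 3))
        assert chm.values[0, 0] == 0.0
        assert chm.values[0, 2] == pytest.approx(0.7)
        assert chm.values[1, 1] == NODATA

    def test_matches_exhaustive_per_cell_max(self, rng):
        n = 5000
        xyz = np.column_stack(
            [rng.uniform(0, 4, n), rng.uniform(0, 4, n), rng.uniform(0, 1, n)]
        )
        cloud = PointCloud(xyz, labels=np.full(n, PointClass.ABOVE_GROUND))
        res = 0.05
        chm = rasterize_chm(cloud, resolution=res)
        xmin, ymin, xmax, ymax = cloud.bounds()
        for _ in range(200):
            i = rng.integers(0, chm.shape[0])
            j = rng.integers(0, chm.shape[1])
            mask = (
                (xyz[:, 0] >= xmin + j * res)
                & (xyz[:, 0] < xmin + (j + 1) * res)
                & (xyz[:, 1] >= ymin + i * res)
                & (xyz[:, 1] < ymin + (i + 1) * res)
            )
            if mask.any():
                assert chm.values[i, j] == pytest.approx(xyz[mask, 2].max())
            else:
                assert chm.values[i, j] == NODATA

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            rasterize_chm(PointCloud(np.empty((0, 3))), 0.1)


class TestFillGaps:
    def test_no_nodata_identity(self):
        chm = CHMRaster((0, 0), 1.0, np.ones((5, 5)))
        out = fill_chm_gaps(chm, 3)
        np.testing.assert_array_equal(out.values, chm.values)

    def test_isolated_gap_filled_with_median(self):
        vals = np.full((3, 3), 0.4)
        vals[1, 1] = NODATA
        out = fill_chm_gaps(CHMRaster((0, 0), 1.0, vals), 3)
        assert out.values[1, 1] == pytest.approx(0.4)

    def test_large_block_interior_stays_nodata(self):
        vals = np.full((9, 9), 0.2)
        vals[2:7, 2:7] = NODATA
        out = fill_chm_gaps(CHMRaster((0, 0), 1.0, vals), 3)
        # by-hand neighbour counting: the 5x5 block interior has no valid
        # neighbours, the block edge cells have >= 3 but corners of the
        # interior only 0
        assert (out.values[3:6, 3:6] == NODATA).all()
        assert out.values[2, 4] == NODATA  # edge-center: 3 valid < 4 required

    def test_geotiff_round_trip(self, tmp_path, rng):
        vals = rng.uniform(0, 1, size=(7, 5))
        vals[2, 2] = NODATA
        chm = CHMRaster((100.0, 200.0), 0.25, vals)
        path = tmp_path / "chm.tif"
        chm.to_geotiff(path)
        back = CHMRaster.from_geotiff(path)
        assert back.origin == pytest.approx(chm.origin)
        assert back.resolution == pytest.approx(0.25)
        np.testing.assert_allclose(back.values, chm.values, atol=1e-6)
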