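"""TALM/diffusion-map rendering, patch segmentation and Voronoi cluster tests."""

import numpy as np
import pytest

from granuletrack import maps, regions as rg
from granuletrack.maps import RasterMap
from granuletrack.tracking import Track

DT = 0.006742


def square(x0, y0, side):
    return np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])


class TestTalm:
    def test_count_conservation(self):
        xy = np.tile([[1.0, 1.0]], (5, 1))
        talm = maps.render_talm(xy, (40, 40))
        assert talm.grid.sum() == 5
        assert talm.grid.max() == 5

    def test_boundary_convention(self):
        b = 0.130 / 3
        talm = maps.render_talm(np.array([[2 * b, 3 * b]]), (40, 40))
        assert talm.grid[3, 2] == 1  # half-open bins: boundary belongs to upper bin

    def test_hotspot_is_brightest_bin(self):
        rng = np.random.default_rng(0)
        hotspot = np.array([2.0, 3.0])
        xy = np.vstack([
            hotspot + rng.normal(0, 0.01, (200, 2)),
            rng.uniform(0, 5, (500, 2)),
        ])
        talm = maps.render_talm(xy, (40, 40))
        i, j = np.unravel_index(np.argmax(talm.grid), talm.grid.shape)
        bi, bj = int(hotspot[1] / talm.bin_size), int(hotspot[0] / talm.bin_size)
        assert abs(i - bi) <= 1 and abs(j - bj) <= 1

    def test_conservation_random(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 40 * 0.13, (1234, 2))
        talm = maps.render_talm(xy, (40, 40))
        assert talm.grid.sum() == 1234


class TestDiffusionMap:
    def test_single_jump_arithmetic(self):
        """X = 0.054 µm² gives D = X/(4·Δt) ≈ 2.0 µm²/s at the start pixel."""
        xy = np.array([[1.0, 1.0], [1.0 + np.sqrt(0.054), 1.0]])
        dm = maps.render_diffusion_map([Track(0, [0, 1], xy)], (40, 40))
        vals = dm.grid[np.isfinite(dm.grid)]
        assert vals.size > 0
        assert np.unique(vals)[0] == pytest.approx(0.054 / (4 * DT), rel=1e-6)
        assert np.unique(vals)[0] == pytest.approx(2.0, rel=0.01)

    def test_zero_length_jumps(self):
        xy = np.tile([[1.0, 1.0]], (5, 1))
        dm = maps.render_diffusion_map([Track(0, np.arange(5), xy)], (40, 40))
        vals = dm.grid[np.isfinite(dm.grid)]
        assert (vals == 0).all()

    def test_gap_jumps_excluded(self):
        xy = np.array([[1.0, 1.0], [1.2, 1.0], [3.0, 3.0]])
        tr = Track(0, [0, 1, 3], xy)  # second link spans a gap
        dm = maps.render_diffusion_map([tr], (40, 40))
        # only one jump contributes
        from granuletrack.maps import _jump_entries

        starts, sq = _jump_entries([tr])
        assert len(sq) == 1

    def test_matches_bruteforce_per_pixel(self):
        """Window-averaged map equals a naive per-pixel recomputation."""
        rng = np.random.default_rng(2)
        tracks = []
        for i in range(30):
            n = rng.integers(2, 8)
            xy = rng.uniform(0.5, 4.5, (n, 2))
            tracks.append(Track(i, np.arange(n), xy))
        dm = maps.render_diffusion_map(tracks, (40, 40))
        b = dm.bin_size
        starts, sq = maps._jump_entries(tracks)
        jj = np.floor(starts[:, 0] / b).astype(int)
        ii = np.floor(starts[:, 1] / b).astype(int)
        ny, nx = dm.grid.shape
        for _ in range(200):
            i, j = rng.integers(0, ny), rng.integers(0, nx)
            sel = (np.abs(ii - i) <= 1) & (np.abs(jj - j) <= 1)
            # clip window at the map edge exactly like the convolution does
            if i == 0 or j == 0 or i == ny - 1 or j == nx - 1:
                continue
            if sel.any():
                expect = sq[sel].mean() / (4 * DT)
                assert dm.grid[i, j] == pytest.approx(expect, rel=1e-9)
            else:
                assert np.isnan(dm.grid[i, j])

    def test_two_zone_fixture(self):
        """Pixel-wise medians in slow/fast halves land within 25% of the truth."""
        rng = np.random.default_rng(3)
        tracks = []
        tid = 0
        for x0, d in ((1.25, 0.2), (3.75, 4.0)):
            for _ in range(400):
                n = 6
                steps = rng.normal(0, np.sqrt(2 * d * DT), (n - 1, 2))
                xy = np.vstack([[x0 + rng.uniform(-1, 1), rng.uniform(0.5, 4.5)], np.zeros((n - 1, 2))])
                xy[1:] = xy[0] + np.cumsum(steps, axis=0)
                tracks.append(Track(tid, np.arange(n), xy))
                tid += 1
        dm = maps.render_diffusion_map(tracks, (40, 40))
        b = dm.bin_size
        cols = np.arange(dm.grid.shape[1]) * b
        slow = dm.grid[:, cols < 2.3]
        fast = dm.grid[:, cols > 2.7]
        assert np.nanmedian(slow) == pytest.approx(0.2, rel=0.25)
        assert np.nanmedian(fast) == pytest.approx(4.0, rel=0.25)


def make_dmap(slow_mask, fast_value=5.0, slow_value=0.5, shape=(60, 60)):
    grid = np.full(shape, fast_value)
    grid[slow_mask] = slow_value
    return RasterMap("diffusion", grid, bin_size=0.130 / 3)


class TestPatches:
    def test_sixty_pixel_region_is_patch(self):
        m = np.zeros((60, 60), dtype=bool)
        m[10:16, 10:20] = True  # 60 px
        assert len(maps.segment_patches(make_dmap(m))) == 1

    def test_forty_pixel_region_is_not(self):
        m = np.zeros((60, 60), dtype=bool)
        m[10:14, 10:20] = True  # 40 px
        assert maps.segment_patches(make_dmap(m)) == []

    def test_enclosed_fast_pixels_filled(self):
        m = np.zeros((60, 60), dtype=bool)
        m[10:19, 10:19] = True  # 81 px block
        m[14:15, 13:18] = False  # 5 enclosed fast pixels -> ring of 76
        patches = maps.segment_patches(make_dmap(m))
        assert len(patches) == 1
        assert len(patches[0].pixels) == 81  # enclosed pixels assigned to the patch

    def test_idempotent_on_own_output(self):
        m = np.zeros((60, 60), dtype=bool)
        m[10:19, 10:19] = True
        m[30:40, 30:37] = True
        first = maps.segment_patches(make_dmap(m))
        mask1 = maps.patch_mask(first, (60, 60))
        second = maps.segment_patches(make_dmap(mask1))
        mask2 = maps.patch_mask(second, (60, 60))
        assert np.array_equal(mask1, mask2)

    def test_threshold_monotonicity_before_closing(self):
        rng = np.random.default_rng(4)
        grid = rng.uniform(0, 6, (60, 60))
        dm = RasterMap("diffusion", grid, bin_size=0.130 / 3)
        a1 = (np.isfinite(grid) & (grid < 1.0)).sum()
        a2 = (np.isfinite(grid) & (grid < 2.0)).sum()
        assert a2 >= a1

    def test_coverage_arithmetic(self):
        """One 4.7 µm² patch in 47 µm² granule-free cytoplasm covers 10%."""
        b = 0.130 / 3
        n_px = int(round(4.7 / (b * b)))
        side = int(np.sqrt(n_px))
        m = np.zeros((200, 200), dtype=bool)
        m[5 : 5 + side, 5 : 5 + side] = True
        extra = n_px - side * side
        m[5 + side, 5 : 5 + extra] = True
        dm = make_dmap(m, shape=(200, 200))
        patches = maps.segment_patches(dm)
        assert sum(len(p.pixels) for p in patches) == n_px
        # cell 48 µm², nucleus 1 µm² -> cytoplasm 47 µm²; no granules
        rs = rg.RegionSet(
            cell_polygon=square(0, 0, np.sqrt(48)),
            nucleus_polygon=square(5.5, 5.5, 1.0),  # far corner, clear of the patch
            granule_masks=np.zeros((1, 60, 60), dtype=bool),
            control_frames=[0],
            pixel_size=0.130,
        )
        out = maps.quantify_patches(patches, rs, dm)
        assert out["coverage_percent"] == pytest.approx(10.0, rel=0.02)

    def test_no_patches_zero_coverage(self):
        rs = rg.RegionSet(
            cell_polygon=square(0, 0, 7),
            nucleus_polygon=square(1, 1, 2),
            granule_masks=np.zeros((1, 60, 60), dtype=bool),
            control_frames=[0],
            pixel_size=0.130,
        )
        dm = make_dmap(np.zeros((60, 60), dtype=bool))
        out = maps.quantify_patches([], rs, dm)
        assert out["coverage_percent"] == 0.0


def brute_force_clusters(xy, area_quantile=0.25, min_cells=80):
    """Independent re-derivation via explicit tessellation + graph search."""
    from scipy.spatial import Voronoi

    vor = Voronoi(xy)
    n = len(xy)
    areas = np.full(n, np.nan)
    for i in range(n):
        reg = vor.regions[vor.point_region[i]]
        if reg and -1 not in reg:
            p = vor.vertices[reg]
            x, y = p[:, 0], p[:, 1]
            areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    finite = np.isfinite(areas)
    cut = np.quantile(areas[finite], area_quantile)
    kept = finite & (areas <= cut)
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(np.flatnonzero(kept))
    for a, b in vor.ridge_points:
        if kept[a] and kept[b]:
            g.add_edge(int(a), int(b))
    return [sorted(c) for c in nx.connected_components(g) if len(c) >= min_cells]


class TestVoronoiClusters:
    def test_uniform_points_no_clusters(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            xy = rng.uniform(0, 10, (1000, 2))
            assert maps.voronoi_clusters(xy) == []

    def test_blob_detected(self):
        rng = np.random.default_rng(3)
        blob = rng.normal([2, 2], 0.02, (120, 2))
        xy = np.vstack([blob, rng.uniform(0, 4, (300, 2))])
        clusters = maps.voronoi_clusters(xy)
        assert len(clusters) >= 1
        biggest = max(clusters, key=lambda c: c.n_detections)
        assert np.sum(biggest.point_indices < 120) >= 100

    def test_min_cells_threshold(self):
        rng = np.random.default_rng(3)
        blob = rng.normal([2, 2], 0.02, (120, 2))
        xy = np.vstack([blob, rng.uniform(0, 4, (300, 2))])
        found = maps.voronoi_clusters(xy)
        size = max(c.n_detections for c in found)
        assert maps.voronoi_clusters(xy, min_cells=size + 1) == []

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.vstack([
            rng.normal([1, 1], 0.01, (150, 2)),
            rng.normal([3, 3], 0.015, (120, 2)),
            rng.uniform(0, 4, (230, 2)),
        ])
        ours = sorted(sorted(c.point_indices.tolist()) for c in maps.voronoi_clusters(xy))
        ref = sorted(brute_force_clusters(xy))
        assert ours == ref

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            maps.voronoi_clusters(np.array([[0, 0], [1, 1]]))


class TestQuantifyClusters:
    def test_equivalent_diameter_worked_example(self):
        cl = maps.LocalizationCluster(np.arange(10), 10, 0.015, (0.0, 0.0))
        assert cl.equivalent_diameter_nm == pytest.approx(138.2, abs=0.1)

    def test_binding_events_worked_example(self):
        """350 detections at mean track length 10 frames = 35 binding events."""
        masks = np.zeros((1, 60, 60), dtype=bool)
        masks[0, 20:40, 20:40] = True
        rs = rg.RegionSet(
            cell_polygon=square(0, 0, 60 * 0.13),
            nucleus_polygon=square(0.1, 0.1, 0.5),
            granule_masks=masks,
            control_frames=[0],
            pixel_size=0.130,
        )
        center = (30 * 0.13, 30 * 0.13)  # inside the granule
        cls = [maps.LocalizationCluster(np.arange(350), 350, 0.015, center)]
        out = maps.quantify_clusters(cls, rs, mean_track_length=10.0)
        row = out[out.region == "granule"].iloc[0]
        assert row.detections_per_cluster == pytest.approx(350)
        assert row.binding_events_per_cluster == pytest.approx(35.0)
        assert row.equivalent_diameter_nm == pytest.approx(138.2, abs=0.1)

    def test_density_arithmetic(self):
        masks = np.zeros((1, 100, 100), dtype=bool)
        n_px = int(round(30.0 / 0.13**2))
        masks[0].flat[:n_px] = True  # ~30 µm² granule area
        rs = rg.RegionSet(
            cell_polygon=square(0, 0, 13.0),
            nucleus_polygon=square(11.0, 11.0, 1.0),
            granule_masks=masks,
            control_frames=[0],
            pixel_size=0.130,
        )
        area = float(rg.region_areas(rs).granule_um2.iloc[0])
        # 3 clusters whose centroids fall in the granule mask
        ys = [0.2, 0.5, 0.8]
        cls = [maps.LocalizationCluster(np.arange(5), 5, 0.01, (0.5, y)) for y in ys]
        out = maps.quantify_clusters(cls, rs)
        row = out[out.region == "granule"].iloc[0]
        assert row.n_clusters == 3
        assert row.density_per_um2 == pytest.approx(3 / area, rel=1e-6)
        assert row.density_per_um2 == pytest.approx(0.1, rel=0.01)
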