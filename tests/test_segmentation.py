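"""Flattening, DP boundary tracing, layer/lesion/STV/vessel segmentation."""

import warnings

import networkx as nx
import numpy as np
import pytest

from rsompy.datatypes import LesionRegions, ReconVolume
from rsompy.segmentation import (
    extract_stv_band,
    find_surface,
    flatten_surface,
    segment_layers,
    segment_lesion_boundary,
    segment_vessels,
    skeleton_network,
    trace_boundary_dp,
    unflatten_surface,
)


def _volume(arr, vz=5.0):
    return ReconVolume(intensity=np.asarray(arr, dtype=np.float32),
                       voxel_size_um=(12.0, 12.0, vz))


class TestFlatten:
    def _tilted_volume(self):
        nx_, ny, nz = 20, 10, 60
        arr = np.zeros((nx_, ny, nz), dtype=np.float32)
        for i in range(nx_):
            s = 5 + i  # surface voxel rises along x
            arr[i, :, s] = 2.0
            arr[i, :, s + 10] = 1.0
        return _volume(arr)

    def test_flat_surface_is_identity(self):
        arr = np.zeros((6, 6, 20), dtype=np.float32)
        arr[:, :, 0] = 1.0
        vol = _volume(arr)
        surf = np.zeros((6, 6))
        flat = flatten_surface(vol, surf)
        np.testing.assert_allclose(flat.intensity, vol.intensity)

    def test_tilted_plane_flattens_to_depth_zero(self):
        vol = self._tilted_volume()
        surf = find_surface(vol)
        flat = flatten_surface(vol, surf)
        new_surf = find_surface(flat)
        assert np.std(new_surf) <= vol.voxel_size_um[2]
        assert np.median(new_surf) <= vol.voxel_size_um[2]

    def test_flatten_round_trip(self):
        vol = self._tilted_volume()
        surf = find_surface(vol)
        flat = flatten_surface(vol, surf)
        back = unflatten_surface(flat)
        # interior voxels recovered within interpolation error
        core = (slice(None), slice(None), slice(5, 40))
        assert np.abs(back.intensity[core] - vol.intensity[core]).max() < 0.5

    def test_surface_outside_volume_rejected(self):
        vol = self._tilted_volume()
        with pytest.raises(ValueError, match="outside"):
            flatten_surface(vol, np.full((20, 10), 1e6))


class TestTraceBoundaryDP:
    def test_zero_cost_row_is_chosen(self):
        cost = np.ones((8, 10))
        cost[3, :] = 0.0
        assert np.all(trace_boundary_dp(cost) == 3)

    def test_matches_dijkstra_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            cost = rng.random((8, 8))
            path = trace_boundary_dp(cost, max_jump=2)
            assert np.all(np.abs(np.diff(path)) <= 2)
            dp_cost = cost[path, np.arange(8)].sum()

            G = nx.DiGraph()
            for r in range(8):
                G.add_edge("s", (r, 0), weight=cost[r, 0])
                G.add_edge((r, 7), "t", weight=0.0)
            for j in range(7):
                for r in range(8):
                    for rp in range(max(0, r - 2), min(8, r + 3)):
                        G.add_edge((r, j), (rp, j + 1), weight=cost[rp, j + 1])
            oracle = nx.shortest_path_length(G, "s", "t", weight="weight")
            assert dp_cost == pytest.approx(oracle, abs=1e-9)

    def test_uniform_zero_ties_break_topmost(self):
        path = trace_boundary_dp(np.zeros((6, 7)))
        assert np.all(path == 0)

    def test_all_infinite_column_rejected(self):
        cost = np.ones((4, 5))
        cost[:, 2] = np.inf
        with pytest.raises(ValueError, match="no finite cost|no path"):
            trace_boundary_dp(cost)


class TestSegmentLayers:
    def _melanin_volume(self, lo=100.0, hi=250.0, vz=5.0, nz=100):
        arr = np.zeros((40, 24, nz), dtype=np.float32)
        z = np.arange(nz) * vz
        arr[:, :, (z >= lo) & (z < hi)] = 3.0
        return _volume(arr, vz)

    def test_band_bottom_found(self):
        vol = self._melanin_volume(100.0, 250.0)
        lb = segment_layers(vol)
        assert np.median(lb.ep_bottom_um) == pytest.approx(250.0, abs=12.0)

    def test_thicker_band_gives_deeper_boundary(self):
        thin = segment_layers(self._melanin_volume(100.0, 200.0))
        thick = segment_layers(self._melanin_volume(100.0, 300.0))
        assert np.median(thick.ep_bottom_um) > np.median(thin.ep_bottom_um)

    def test_no_melanin_band_errors_with_override_hint(self):
        rng = np.random.default_rng(0)
        arr = np.zeros((40, 24, 100), dtype=np.float32)
        arr[rng.integers(0, 40, 60), rng.integers(0, 24, 60),
            rng.integers(60, 95, 60)] = 1.0
        with pytest.raises(ValueError, match="fixed_ep_thickness_um"):
            segment_layers(_volume(arr))

    def test_fixed_thickness_override(self):
        vol = self._melanin_volume()
        lb = segment_layers(vol, fixed_ep_thickness_um=180.0)
        assert np.all(lb.ep_bottom_um == 180.0)


class TestLesionBoundary:
    def _disk_image(self, radius=60, size=200, bg=0.1, fg=1.0):
        yy, xx = np.mgrid[:size, :size]
        img = np.full((size, size), bg)
        img[(yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2] = fg
        return img

    def test_disk_boundary_radial_error_below_2px(self):
        img = self._disk_image()
        regions = segment_lesion_boundary(img)
        r = np.linalg.norm(regions.boundary_path - 100.0, axis=1)
        assert np.abs(r - 60.0).mean() <= 2.0

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="no lesion contrast"):
            segment_lesion_boundary(np.ones((64, 64)))

    def test_larger_of_two_disks_kept(self):
        img = np.full((200, 200), 0.1)
        yy, xx = np.mgrid[:200, :200]
        img[(yy - 60) ** 2 + (xx - 60) ** 2 <= 40**2] = 1.0
        img[(yy - 150) ** 2 + (xx - 150) ** 2 <= 15**2] = 1.0
        regions = segment_lesion_boundary(img)
        area = regions.lesion_mask.sum()
        assert area == pytest.approx(np.pi * 40**2, rel=0.1)
        assert regions.lesion_mask[60, 60] and not regions.lesion_mask[150, 150]


class TestStvBand:
    def test_straight_boundary_band_width_in_columns(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[:, :50] = True
        regions = LesionRegions(lesion_mask=mask, boundary_path=np.empty((0, 2)))
        regions = extract_stv_band(regions, band_width_um=500.0, pixel_size_um=12.0)
        cols = np.nonzero(regions.stv_mask.any(axis=0))[0]
        assert len(cols) == int(np.ceil(500 / 12))  # 42 columns
        assert cols[0] == 50

    def test_annulus_area_matches_analytic(self):
        # large image so the 500 um band is not clipped
        size, r_px = 260, 50  # 600 um lesion radius at 12 um pixels
        yy, xx = np.mgrid[:size, :size]
        mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r_px**2
        regions = LesionRegions(lesion_mask=mask, boundary_path=np.empty((0, 2)))
        regions = extract_stv_band(regions, band_width_um=500.0, pixel_size_um=12.0)
        band_px = int(np.ceil(500 / 12))
        expected = np.pi * ((r_px + band_px) ** 2 - r_px**2)
        assert regions.stv_mask.sum() == pytest.approx(expected, rel=0.05)

    def test_empty_mask_rejected(self):
        regions = LesionRegions(lesion_mask=np.zeros((10, 10), dtype=bool),
                                boundary_path=np.empty((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            extract_stv_band(regions)

    def test_band_area_linear_in_width_for_straight_boundary(self):
        mask = np.zeros((40, 400), dtype=bool)
        mask[:, :50] = True
        areas = []
        for width in (120.0, 240.0, 360.0):
            regions = LesionRegions(lesion_mask=mask.copy(),
                                    boundary_path=np.empty((0, 2)))
            regions = extract_stv_band(regions, band_width_um=width,
                                       pixel_size_um=12.0)
            areas.append(regions.stv_mask.sum())
        assert areas[1] == 2 * areas[0]
        assert areas[2] == 3 * areas[0]


def _tube_image(size=100, half_width=1):
    img = np.zeros((size, size))
    img[size // 2 - half_width: size // 2 + half_width + 1, 10:90] = 1.0
    return img


class TestSegmentVessels:
    def test_single_tube_one_segment_no_branches(self):
        net = segment_vessels(_tube_image(), threshold="otsu",
                              background_sigma_px=0)
        assert len(net.segments) == 1
        assert net.n_branch_points == 0
        # skeleton within 1 px of the centerline
        rows = np.argwhere(net.skeleton)[:, 0]
        assert np.abs(rows - 50).mean() <= 1.0

    def test_crossing_tubes_have_branch_point(self):
        img = _tube_image()
        img[10:90, 49:52] = 1.0
        net = segment_vessels(img, threshold="otsu", background_sigma_px=0)
        assert net.n_branch_points >= 1

    def test_all_zero_roi_yields_empty_network(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = segment_vessels(np.zeros((50, 50)))
        assert len(net.segments) == 0 and not net.mask.any()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            segment_vessels(np.ones((10, 10)),
                            roi_mask=np.zeros((10, 10), dtype=bool))

    def test_segment_arc_at_least_chord(self):
        rng = np.random.default_rng(5)
        img = np.zeros((120, 120))
        for _ in range(4):
            r0, c0 = rng.integers(10, 110, 2)
            r1, c1 = rng.integers(10, 110, 2)
            n = 200
            rr = np.linspace(r0, r1, n).astype(int)
            cc = np.linspace(c0, c1, n).astype(int)
            img[rr, cc] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = segment_vessels(img, threshold="otsu", background_sigma_px=0,
                                  closing_radius_px=1)
        for seg in net.segments:
            assert seg.arc_length_um >= seg.chord_length_um - 1e-9

    @pytest.mark.parametrize("amplitude", [0.0, 40.0])
    def test_phantom_segment_count_and_length_recovered(self, amplitude):
        from rsompy.phantom import generate_sinusoid_phantom

        ph = generate_sinusoid_phantom(
            grid_shape=(96, 96, 40), voxel_size_um=(12.0, 12.0, 12.0),
            n_vessels=4, amplitude_um=amplitude, wavelength_um=500.0,
            radius_um=20.0, depth_range_um=(120.0, 360.0), seed=3,
        )
        proj = ph.vessel_mask.any(axis=2).astype(float)
        net = segment_vessels(proj, threshold="otsu", background_sigma_px=0,
                              pixel_size_um=12.0)
        true_len = sum(
            np.linalg.norm(np.diff(s["points"][:, :2], axis=0), axis=1).sum()
            for s in ph.vessel_segments
        )
        n_true = len(ph.vessel_segments)
        assert abs(len(net.segments) - n_true) <= 0.2 * n_true
        assert net.total_skeleton_length_um == pytest.approx(true_len, rel=0.15)


class TestSkeletonNetwork:
    def test_anisotropic_lengths(self):
        mask = np.zeros((30, 5, 5), dtype=bool)
        mask[5:25, 2, 2] = True
        net = skeleton_network(mask, pixel_size_um=(10.0, 10.0, 4.0),
                               min_spur_px=0)
        assert len(net.segments) == 1
        assert net.segments[0].arc_length_um == pytest.approx(190.0, abs=1e-6)
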