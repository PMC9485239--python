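"""HMM bound/free segmentation, turning-angle anisotropy and shuttling tests."""

import numpy as np
import pytest

from granuletrack import kinetics as kin, regions as rg
from granuletrack.synthetic import simulate_free_tracks, simulate_two_state_tracks
from granuletrack.tracking import Track

DT = 0.006742


def to_tracks(arrays, mark_free=False):
    tracks = []
    for i, xy in enumerate(arrays):
        tr = Track(i, np.arange(len(xy)), xy)
        if mark_free:
            tr.state_labels = np.array(["free"] * (len(xy) - 1), dtype=object)
        tracks.append(tr)
    return tracks


def square(x0, y0, side):
    return np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])


class TestHmm:
    def test_well_separated_states_decoded(self):
        xy, labels = simulate_two_state_tracks(300, 30, 0.01, 2.0, stay_prob=0.95, seed=1)
        tracks = to_tracks(xy)
        seg = kin.segment_states(tracks)
        correct = total = 0
        for tr, lab in zip(tracks, labels):
            got = tr.state_labels == "free"
            correct += int(np.sum(got == (lab == 1)))
            total += len(lab)
        assert correct / total >= 0.90
        assert seg.sigma[0] < seg.sigma[1]
        assert np.allclose(seg.transition.sum(axis=1), 1.0)

    def test_accuracy_degrades_as_states_merge(self):
        accs = []
        for d_bound in (0.01, 0.5, 1.5):
            xy, labels = simulate_two_state_tracks(150, 25, d_bound, 2.0, stay_prob=0.95, seed=2)
            tracks = to_tracks(xy)
            kin.segment_states(tracks)
            correct = total = 0
            for tr, lab in zip(tracks, labels):
                got = tr.state_labels == "free"
                correct += int(np.sum(got == (lab == 1)))
                total += len(lab)
            accs.append(correct / total)
        assert accs[0] > accs[1] > accs[2] - 0.05  # monotone within tolerance
        assert accs[0] >= 0.9

    def test_identical_displacements_single_state_free(self):
        xy = [np.column_stack([np.arange(10) * 0.5, np.zeros(10)]) for _ in range(5)]
        tracks = to_tracks(xy)
        kin.segment_states(tracks)
        for tr in tracks:
            assert (tr.state_labels == "free").all()

    def test_bound_is_smaller_scale_by_construction(self):
        xy, _ = simulate_two_state_tracks(100, 20, 0.01, 2.0, seed=3)
        seg = kin.segment_states(to_tracks(xy))
        assert seg.sigma[0] == min(seg.sigma)


class TestAngles:
    def test_collinear_forward_is_zero(self):
        xy = np.array([[0, 0], [0.2, 0], [0.4, 0]])
        tr = to_tracks([xy], mark_free=True)[0]
        df = kin.compute_angles([tr])
        assert df.angle_deg.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_reversal_is_180(self):
        xy = np.array([[0, 0], [0.2, 0], [0.0, 0]])
        tr = to_tracks([xy], mark_free=True)[0]
        df = kin.compute_angles([tr])
        assert df.angle_deg.iloc[0] == pytest.approx(180.0)

    def test_short_jump_pair_excluded(self):
        xy = np.array([[0, 0], [0.2, 0], [0.3, 0]])  # second jump 0.10 µm
        tr = to_tracks([xy], mark_free=True)[0]
        assert len(kin.compute_angles([tr])) == 0

    def test_gap_pairs_excluded(self):
        xy = np.array([[0, 0], [0.2, 0], [0.4, 0]])
        tr = Track(0, [0, 1, 3], xy)
        tr.state_labels = np.array(["free", "free"], dtype=object)
        assert len(kin.compute_angles([tr])) == 0

    def test_bound_links_excluded(self):
        xy = np.array([[0, 0], [0.2, 0], [0.4, 0], [0.6, 0]])
        tr = Track(0, np.arange(4), xy)
        tr.state_labels = np.array(["free", "bound", "free"], dtype=object)
        assert len(kin.compute_angles([tr])) == 0  # no two consecutive free links


class TestFoldAnisotropy:
    def test_equal_windows_give_one(self):
        angles = np.concatenate([np.full(50, 180.0), np.full(50, 0.0)])
        res = kin.fold_anisotropy(angles, seed=1)
        assert res.f_180_0 == pytest.approx(1.0)

    def test_brownian_is_isotropic(self):
        """Noise-free Brownian turning angles are uniform: f = 1 within 3σ binomial."""
        tracks = to_tracks(simulate_free_tracks(2000, 20, 2.0, seed=4), mark_free=True)
        df = kin.compute_angles(tracks, 0.13)
        res = kin.fold_anisotropy(df.angle_deg.to_numpy(), seed=5)
        n_win = np.sum((df.angle_deg >= 150) & (df.angle_deg <= 210)) + np.sum(
            (df.angle_deg >= 330) | (df.angle_deg <= 30)
        )
        sigma = 2.0 / np.sqrt(n_win / 2)  # binomial error propagated to the ratio
        assert abs(res.f_180_0 - 1.0) <= 3 * sigma

    def test_confined_motion_is_anisotropic(self):
        """Diffusion confined to 0.15-µm disks turns back on itself: f > 1.3."""
        rng = np.random.default_rng(6)
        tracks = []
        R = 0.15
        for i in range(400):
            xy = np.zeros((12, 2))
            for t in range(1, 12):
                step = rng.normal(0, np.sqrt(2 * 2.0 * DT), 2)
                p = xy[t - 1] + step
                r = np.hypot(*p)
                if r > R:  # radial reflection at the confinement boundary
                    p *= max(2 * R - r, 0.0) / r
                xy[t] = p
            tracks.append(xy)
        trs = to_tracks(tracks, mark_free=True)
        df = kin.compute_angles(trs, 0.13)
        res = kin.fold_anisotropy(df.angle_deg.to_numpy(), seed=7)
        assert res.f_180_0 > 1.3

    def test_zero_denominator_gives_nan(self):
        res = kin.fold_anisotropy(np.full(20, 180.0), seed=1)
        assert np.isnan(res.f_180_0)

    def test_resample_std_scales_with_sample_size(self):
        rng = np.random.default_rng(8)
        small = rng.uniform(0, 360, 500)
        large = rng.uniform(0, 360, 8000)
        s_small = kin.fold_anisotropy(small, seed=9).resample_std
        s_large = kin.fold_anisotropy(large, seed=9).resample_std
        ratio = s_small / s_large
        expect = np.sqrt(8000 / 500)
        assert 0.4 * expect < ratio < 2.5 * expect


@pytest.fixture()
def granule_scene():
    """Static square granule in a 20 µm cell at 1 µm pixels."""
    masks = np.zeros((1, 20, 20), dtype=bool)
    masks[0, 8:12, 8:12] = True
    return rg.RegionSet(
        cell_polygon=square(0, 0, 20),
        nucleus_polygon=square(1, 1, 2),
        granule_masks=masks,
        control_frames=[0],
        pixel_size=1.0,
    )


class TestShuttling:
    def make_track(self, tid, start, end, n=4):
        xy = np.linspace(start, end, n)
        tr = Track(tid, np.arange(n), xy)
        tr.state_labels = np.array(["free"] * (n - 1), dtype=object)
        return tr

    def test_enter_event(self, granule_scene):
        tr = self.make_track(0, np.array([5.0, 10.0]), np.array([10.0, 10.0]))
        ev = kin.classify_shuttling([tr], granule_scene)
        assert len(ev) == 1 and ev[0].direction == "enter"

    def test_leave_event(self, granule_scene):
        tr = self.make_track(0, np.array([10.0, 10.0]), np.array([16.0, 10.0]))
        ev = kin.classify_shuttling([tr], granule_scene)
        assert len(ev) == 1 and ev[0].direction == "leave"

    def test_no_event_if_both_inside(self, granule_scene):
        tr = self.make_track(0, np.array([9.0, 9.0]), np.array([10.5, 10.5]))
        assert kin.classify_shuttling([tr], granule_scene) == []

    def test_no_event_if_both_outside(self, granule_scene):
        tr = self.make_track(0, np.array([2.0, 2.0]), np.array([5.0, 5.0]))
        assert kin.classify_shuttling([tr], granule_scene) == []

    def test_stats_arithmetic(self, granule_scene):
        events = [kin.ShuttlingEvent(i, "enter", 1, 0, 3) for i in range(6)]
        events += [kin.ShuttlingEvent(i + 6, "leave", 1, 0, 3) for i in range(4)]
        out = kin.shuttling_stats(events, granule_scene)
        assert out["n_total"] == 10
        assert out["fraction_entering"] == pytest.approx(0.6)
        assert out["events_per_um2"] == pytest.approx(10 / 16)  # 16 µm² granule

    def test_steady_state_balance(self, granule_scene):
        """Stationary diffusion across a static boundary enters and leaves equally often."""
        rng = np.random.default_rng(10)
        tracks = []
        for i in range(3000):
            xy = np.empty((6, 2))
            xy[0] = rng.uniform(4, 16, 2)
            for t in range(1, 6):
                xy[t] = np.clip(xy[t - 1] + rng.normal(0, 1.2, 2), 0.01, 19.99)
            tr = Track(i, np.arange(6), xy)
            tr.state_labels = np.array(["free"] * 5, dtype=object)
            tracks.append(tr)
        events = kin.classify_shuttling(tracks, granule_scene, use_free_segments=False)
        out = kin.shuttling_stats(events, granule_scene)
        n = out["n_total"]
        assert n > 100
        assert abs(out["fraction_entering"] - 0.5) <= 3 * 0.5 / np.sqrt(n)
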