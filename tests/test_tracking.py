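import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from mechanoscape.synthetic import TrackSimSpec, gen_tracks
from mechanoscape.tracking import (
    CellTrack,
    depth_filter,
    duration_filter,
    load_tracks_csv,
    motility_summary,
    region_density,
    split_on_gaps,
    tracks_to_frame,
)


def make_track(xyz, dt=30.0, track_id="t"):
    xyz = np.asarray(xyz, dtype=float)
    t = np.arange(xyz.shape[0]) * dt
    return CellTrack(track_id, t, xyz, dt)


def line_track(n, z=20.0, step=1.0):
    return make_track([[i * step, 0.0, z] for i in range(n)])


class TestDepthFilter:
    def test_superficial_track_dropped(self):
        assert depth_filter([line_track(5, z=10.0)]) == []

    def test_deep_track_unchanged(self):
        out = depth_filter([line_track(5, z=20.0)])
        assert len(out) == 1 and out[0].t_s.size == 5

    def test_mixed_depth_matches_per_sample_oracle(self):
        rng = np.random.default_rng(6)
        tracks = []
        for k in range(30):
            n = rng.integers(3, 20)
            xyz = np.column_stack(
                [rng.uniform(0, 100, n), rng.uniform(0, 100, n), rng.uniform(0, 40, n)]
            )
            tracks.append(make_track(xyz, track_id=f"t{k}"))
        kept = depth_filter(tracks, 15.0)
        expected = 0
        for tr in tracks:
            n_deep = sum(1 for z in tr.xyz_um[:, 2] if z >= 15.0)
            if n_deep >= 2:
                expected += n_deep
        assert sum(tr.t_s.size for tr in kept) == expected


class TestDurationFilter:
    def test_short_track_excluded(self):
        assert duration_filter([line_track(3)], recording_s=1200.0) == []  # 1 min of 20

    def test_long_track_included(self):
        assert len(duration_filter([line_track(7)], recording_s=1200.0)) == 1  # 3 min

    def test_exact_boundary_excluded(self):
        exact = line_track(5)  # 120 s span = exactly 10% of 20 min
        assert duration_filter([exact], recording_s=1200.0) == []
        over = line_track(6)  # one more frame
        assert len(duration_filter([over], recording_s=1200.0)) == 1


class TestMotilitySummary:
    def test_constant_velocity_track(self):
        m = motility_summary(make_track([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        assert m.speed_um_per_min == pytest.approx(2.0)
        assert m.displacement_um == pytest.approx(2.0)
        assert m.straightness == 1.0

    def test_closed_loop(self):
        m = motility_summary(
            make_track([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]])
        )
        assert m.displacement_um == 0.0
        assert m.straightness == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        xyz = np.cumsum(rng.normal(0, 2, (41, 3)), axis=0)
        tr = make_track(xyz)
        m = motility_summary(tr)
        path = sum(
            float(np.sqrt(((b - a) ** 2).sum())) for a, b in zip(xyz[:-1], xyz[1:])
        )
        disp = float(np.sqrt(((xyz[-1] - xyz[0]) ** 2).sum()))
        assert m.path_length_um == pytest.approx(path, rel=1e-12)
        assert m.displacement_um == pytest.approx(disp, rel=1e-12)
        assert m.speed_um_per_min == pytest.approx(path / (40 * 30) * 60, rel=1e-12)
        assert m.straightness == pytest.approx(disp / path, rel=1e-12)

    @given(st.integers(min_value=0, max_value=500))
    def test_straightness_bounds_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        xyz = np.cumsum(rng.normal(0, 1, (10, 3)), axis=0)
        m = motility_summary(make_track(xyz))
        assert 0.0 <= m.straightness <= 1.0 + 1e-12
        assert m.displacement_um <= m.path_length_um + 1e-9

    @given(st.integers(min_value=0, max_value=200), st.floats(0, 2 * np.pi))
    def test_rigid_motion_invariance(self, seed, angle):
        rng = np.random.default_rng(seed)
        xyz = np.cumsum(rng.normal(0, 1, (12, 3)), axis=0)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        moved = xyz @ rot.T + [5.0, -3.0, 7.0]
        m0, m1 = motility_summary(make_track(xyz)), motility_summary(make_track(moved))
        assert m1.speed_um_per_min == pytest.approx(m0.speed_um_per_min, rel=1e-9)
        assert m1.displacement_um == pytest.approx(m0.displacement_um, rel=1e-9)

    def test_2d_mode_projects_z(self):
        tr = make_track([[0, 0, 0], [0, 0, 5], [0, 0, 10]])
        assert motility_summary(tr, mode="2d").path_length_um == 0.0
        assert motility_summary(tr, mode="3d").path_length_um == 10.0


class TestTrackValidation:
    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            CellTrack("x", [0.0, 0.0, 30.0], np.zeros((3, 3)), 30.0)

    def test_gap_splitting(self):
        t = np.array([0, 30, 60, 300, 330.0])  # 8-frame gap after index 2
        tr = CellTrack("g", t, np.zeros((5, 3)), 30.0)
        pieces = split_on_gaps(tr, max_gap_frames=3)
        assert [p.t_s.size for p in pieces] == [3, 2]


class TestParameterRecovery:
    def test_speed_recovered_within_five_percent(self):
        tracks, truth = gen_tracks(TrackSimSpec(n_tracks=200, speed_um_per_min=3.0, seed=2))
        speeds = [motility_summary(t).speed_um_per_min for t in tracks]
        assert abs(np.mean(speeds) - 3.0) / 3.0 < 0.05

    def test_straightness_decreases_with_turning_dispersion(self):
        levels = [0.0, 20.0, 60.0, 120.0, 180.0]
        level_idx, straightness = [], []
        for li, sd in enumerate(levels):
            tracks, _ = gen_tracks(TrackSimSpec(n_tracks=60, turning_sd_deg=sd, seed=3))
            for tr in tracks:
                level_idx.append(li)
                straightness.append(motility_summary(tr).straightness)
        rho, p = spearmanr(level_idx, straightness)
        assert rho < 0 and p < 0.01


class TestRegionDensity:
    def test_counts_over_area(self):
        mask = np.zeros((10, 10), int)
        mask[:, :5] = 1  # stroma: 50 px
        mask[:, 5:] = 2
        ps = np.sqrt(0.05 / 50)  # stroma area 0.05 mm^2
        pts = np.array([[0.02, 0.05], [0.01, 0.03], [0.015, 0.08], [0.001, 0.001], [0.02, 0.02]])
        densities = {d.region_label: d for d in region_density(pts, mask, ps)}
        assert densities["stroma"].n_cells == 5
        assert densities["stroma"].cells_per_mm2 == pytest.approx(100.0)
        assert densities["tumor_islet"].n_cells == 0
        assert densities["tumor_islet"].cells_per_mm2 == 0.0

    def test_scatter_matches_point_in_label_oracle(self):
        rng = np.random.default_rng(7)
        mask = rng.integers(0, 3, (20, 20))
        mask[0, 0], mask[0, 1] = 1, 2  # both regions present
        ps = 0.05
        pts = rng.uniform(0, 20 * ps, (200, 2))
        densities = {d.region_label: d.n_cells for d in region_density(pts, mask, ps)}
        counts = {1: 0, 2: 0}
        for x, y in pts:
            r, c = int(y // ps), int(x // ps)
            if 0 <= r < 20 and 0 <= c < 20 and mask[r, c] in counts:
                counts[mask[r, c]] += 1
        assert densities["stroma"] == counts[1]
        assert densities["tumor_islet"] == counts[2]

    def test_zero_area_region_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            region_density(np.zeros((0, 2)), np.zeros((5, 5), int), 0.1)


class TestTrackIO:
    def test_csv_round_trip(self, tmp_path):
        tracks, _ = gen_tracks(TrackSimSpec(n_tracks=3, seed=9))
        path = tmp_path / "tracks.csv"
        tracks_to_frame(tracks).to_csv(path, index=False)
        loaded = load_tracks_csv(path)
        assert len(loaded) == 3
        for a, b in zip(tracks, loaded):
            assert np.allclose(a.xyz_um, b.xyz_um)
            assert np.allclose(a.t_s, b.t_s)
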