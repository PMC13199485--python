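"""Track filtering, ML displacement, smoothing, onset, persistence and speeds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cet.kinetics import (TrackTable, convergence_onset, filter_tracks,
                          ml_displacement_curve, smooth_curve, summarize_kinetics,
                          track_persistence, track_speeds)


def table_from(dfs, midline_x=0.0):
    return TrackTable(pd.concat(dfs, ignore_index=True), midline_x=midline_x)


class TestFilterTracks:
    def test_two_frame_track_removed(self, track_df):
        t = table_from([track_df([[200, 0], [201, 0]], track_id=0),
                        track_df([[200, 0], [201, 0], [202, 0]], track_id=1)])
        out, rep = filter_tracks(t)
        assert set(out.data["track_id"]) == {1}
        assert rep.n_tracks_too_short == 1

    def test_midline_band_removed(self, track_df):
        t = table_from([track_df([[50, 0], [52, 0], [51, 0], [50, 0]], track_id=0)])
        out, rep = filter_tracks(t, exclusion_radius_um=100.0)
        assert out.data.empty
        assert rep.n_obs_midline_removed == 4

    def test_empty_input_empty_output(self):
        t = TrackTable(pd.DataFrame(columns=["track_id", "frame", "t_hpf", "x", "y"]))
        out, rep = filter_tracks(t)
        assert out.data.empty and rep.n_tracks_out == 0

    def test_per_observation_splits_track_crossing_band(self, track_df):
        # track dips into the exclusion band mid-way: both flanks long enough survive
        xs = [[200, 0]] * 4 + [[50, 0]] * 2 + [[200, 0]] * 4
        t = table_from([track_df(xs, track_id=0)])
        out, _ = filter_tracks(t)
        assert len(out.data) == 8
        assert out.data["track_id"].nunique() == 2  # two consecutive runs

    def test_per_track_mode_drops_whole_track(self, track_df):
        xs = [[200, 0]] * 4 + [[50, 0]] * 2 + [[200, 0]] * 4
        t = table_from([track_df(xs, track_id=0)])
        out, _ = filter_tracks(t, midline_mode="per_track")
        assert out.data.empty

    def test_no_tracks_survive_warns_not_raises(self, track_df):
        t = table_from([track_df([[10, 0], [11, 0], [12, 0]])])
        with pytest.warns(UserWarning, match="no tracks"):
            out, _ = filter_tracks(t)
        assert out.data.empty


class TestMlDisplacement:
    def test_symmetric_convergence_positive(self, track_df):
        left = track_df([[-200 + i, 0] for i in range(5)], track_id=0)
        right = track_df([[200 - i, 0] for i in range(5)], track_id=1)
        curve = ml_displacement_curve(table_from([left, right]))
        np.testing.assert_allclose(curve["mean"], 1.0)
        assert (curve["n"] == 2).all()

    def test_stationary_zero(self, track_df):
        curve = ml_displacement_curve(table_from([track_df([[150, 0]] * 6)]))
        np.testing.assert_allclose(curve["mean"], 0.0)

    def test_divergence_negative(self, track_df):
        t = table_from([track_df([[200 + 2 * i, 0] for i in range(4)])])
        curve = ml_displacement_curve(t)
        np.testing.assert_allclose(curve["mean"], -2.0)

    def test_reflection_about_midline_invariant(self, track_df):
        rng = np.random.default_rng(3)
        pts = np.column_stack([200 + rng.normal(0, 5, 10), rng.normal(0, 5, 10)])
        a = ml_displacement_curve(table_from([track_df(pts)]))
        refl = pts.copy()
        refl[:, 0] = -refl[:, 0]
        b = ml_displacement_curve(table_from([track_df(refl)]))
        np.testing.assert_allclose(a["mean"], b["mean"])

    def test_translation_with_midline_invariant(self, track_df):
        rng = np.random.default_rng(4)
        pts = np.column_stack([300 + rng.normal(0, 5, 8), rng.normal(0, 5, 8)])
        a = ml_displacement_curve(table_from([track_df(pts)], midline_x=0.0))
        shifted = pts.copy()
        shifted[:, 0] += 123.0
        b = ml_displacement_curve(table_from([track_df(shifted)], midline_x=123.0))
        np.testing.assert_allclose(a["mean"], b["mean"])


class TestSmoothing:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_curve(np.full(10, 3.0)), 3.0)

    def test_trailing_hand_example(self):
        out = smooth_curve(np.array([0.0, 0.0, 0.0, 4.0]), window=4)
        assert out[-1] == pytest.approx(1.0)

    def test_window_one_identity(self):
        v = np.array([1.0, np.nan, 3.0])
        out = smooth_curve(v, window=1)
        np.testing.assert_array_equal(out[[0, 2]], v[[0, 2]])
        assert np.isnan(out[1])

    def test_nan_omitted_within_window(self):
        out = smooth_curve(np.array([2.0, np.nan, 4.0, 6.0]), window=4)
        assert out[-1] == pytest.approx(4.0)


class TestOnset:
    def grid(self, n=48, t0=6.5):
        return t0 + np.arange(n) / 12.0  # 5-min frames

    def test_noiseless_hinge_exact(self):
        t = self.grid()
        y = np.maximum(t - 8.0, 0.0) * 0.2
        res = convergence_onset(y, t)
        assert res.detected
        assert res.onset_hpf == pytest.approx(8.0, abs=1 / 12 + 1e-9)

    def test_strictly_linear_rising_none(self):
        t = self.grid()
        res = convergence_onset(0.3 * (t - t[0]), t)
        assert res.onset_hpf is None

    def test_flat_null_controls_false_positives(self):
        rng = np.random.default_rng(0)
        t = self.grid()
        fp = sum(convergence_onset(rng.normal(0, 1, t.size), t).detected
                 for _ in range(400))
        assert fp / 400 <= 0.07

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            convergence_onset(np.full(12, np.nan), self.grid(12))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            convergence_onset(np.zeros(5), self.grid(5))


class TestTrackStats:
    def test_straight_track_persistence_one(self, track_df):
        t = track_df([[i, 0] for i in range(5)])
        assert track_persistence(t) == pytest.approx(1.0)

    def test_out_and_back_zero(self, track_df):
        t = track_df([[0, 0], [5, 0], [0, 0]])
        assert track_persistence(t) == pytest.approx(0.0)

    def test_l_shape_hand_value(self, track_df):
        t = track_df([[0, 0], [1, 0], [1, 1]])
        assert track_persistence(t) == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        straight, inst = track_speeds(t, frame_interval_min=5.0)
        assert straight == pytest.approx(np.sqrt(2) / 10, abs=1e-12)
        np.testing.assert_allclose(inst, [0.2, 0.2])

    def test_two_um_step_point_four(self, track_df):
        t = track_df([[0, 0], [2, 0]])
        _, inst = track_speeds(t, frame_interval_min=5.0)
        assert inst[0] == pytest.approx(0.4, abs=1e-12)

    def test_stationary_zero_with_flag(self, track_df):
        t = track_df([[3, 3]] * 4)
        assert track_persistence(t) == 0.0
        straight, inst = track_speeds(t)
        assert straight == 0.0 and (inst == 0).all()

    def test_single_observation_errors(self, track_df):
        with pytest.raises(ValueError):
            track_speeds(track_df([[0, 0]]))

    @staticmethod
    def _df(pts):
        pts = np.asarray(pts, float)
        return pd.DataFrame({"track_id": 0, "frame": np.arange(len(pts)),
                             "t_hpf": 7.0 + np.arange(len(pts)) / 12.0,
                             "x": pts[:, 0], "y": pts[:, 1]})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=12))
    def test_persistence_bounds_and_triangle_inequality(self, pts):
        t = self._df(pts)
        xy = np.asarray(pts, float)
        if np.linalg.norm(np.diff(xy, axis=0), axis=1).sum() == 0:
            assert track_persistence(t) == 0.0
            return
        p = track_persistence(t)
        assert 0.0 <= p <= 1.0 + 1e-12
        straight, inst = track_speeds(t)
        assert inst.mean() >= straight - 1e-12  # triangle inequality

    def test_persistence_one_iff_monotone_collinear(self, track_df):
        mono = track_df([[0, 0], [1, 1], [2.5, 2.5], [4, 4]])
        assert track_persistence(mono) == pytest.approx(1.0, abs=1e-12)
        bent = track_df([[0, 0], [1, 1], [2, 1.01]])
        assert track_persistence(bent) < 1.0


class TestPipelineSummary:
    def test_recovers_planted_onset(self):
        from cet.synthdata import SimTrackSpec, gen_tracks

        spec = SimTrackSpec(n_cells=150, diffusion_sd=1.0, convergence_speed=1.0,
                            onset_hpf=8.0, seed=12)
        summary = summarize_kinetics(gen_tracks(spec))
        assert summary.onset.detected
        assert summary.onset.onset_hpf == pytest.approx(8.0, abs=5 / 60 + 1e-9)
        assert (summary.per_track["persistence"] <= 1).all()
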