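from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pairschool.forcemap import (
    DEFAULT_D_EDGES,
    DEFAULT_VF_EDGES,
    DEFAULT_VP_EDGES,
    Forcemap,
    bin_forcemap,
    distance_profile,
    estimate_chance_fraction,
    filter_quasi_1d,
    peak_force,
    project_both,
    project_to_focal_frame,
    quadrant_analysis,
    shuffle_correction,
)
from pairschool.kinematics import TrajectoryPair
from pairschool.synthio import make_independent_walkers

from conftest import make_linear_pair


def _samples(rows):
    df = pd.DataFrame(rows)
    for col in ("frame", "focal", "d_perp", "heading_diff"):
        if col not in df:
            df[col] = 0.0
    return df


class TestProjection:
    def test_partner_directly_ahead(self):
        traj = make_linear_pair(n=6, v1=(5, 0), v2=(5, 0), offset=(5.0, 0.0))
        s = project_to_focal_frame(traj, focal=0)
        np.testing.assert_allclose(s["d_par"], 5.0)
        np.testing.assert_allclose(s["d_perp"], 0.0, atol=1e-12)
        np.testing.assert_allclose(s["heading_diff"], 0.0, atol=1e-9)
        np.testing.assert_allclose(s["v_p_proj"], s["v_f"])

    def test_partner_moving_perpendicular(self):
        traj = make_linear_pair(n=6, v1=(5, 0), v2=(0, 5), offset=(0.0, 3.0))
        s = project_to_focal_frame(traj, focal=0)
        np.testing.assert_allclose(s["v_p_proj"], 0.0, atol=1e-9)
        np.testing.assert_allclose(s["heading_diff"], 90.0, atol=1e-9)

    def test_parallel_perp_decomposition_preserves_distance(self, short_sim):
        s = project_both(short_sim.trajectory)
        traj = short_sim.trajectory
        for _, row in s.sample(50, random_state=0).iterrows():
            i, focal = int(row["frame"]), int(row["focal"])
            rel = traj.positions[i, 1 - focal] - traj.positions[i, focal]
            assert row["d_par"] ** 2 + row["d_perp"] ** 2 == pytest.approx(
                float(rel @ rel), rel=1e-9
            )

    def test_zero_speed_frames_skipped(self):
        pos = np.zeros((6, 2, 2))
        pos[:, 1, 0] = np.arange(6.0)  # fish 2 moves, fish 1 frozen
        traj = TrajectoryPair(np.arange(6) / 30.0, pos, 30.0)
        assert len(project_to_focal_frame(traj, focal=0)) == 0
        assert len(project_to_focal_frame(traj, focal=1)) > 0


class TestFilter:
    def test_threshold_edges(self):
        s = _samples(
            [
                {"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 0.0,
                 "heading_diff": 50.0},
                {"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 0.0,
                 "heading_diff": 10.0, "d_perp": 7.5},
                {"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 0.0,
                 "heading_diff": 10.0, "d_perp": 6.9},
                {"d_par": 25.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 0.0,
                 "heading_diff": 10.0},
            ]
        )
        out = filter_quasi_1d(s)
        assert len(out) == 1
        assert out["d_perp"].iloc[0] == 6.9
        assert out.attrs["retained_fraction"] == 0.25

    def test_simulator_output_fully_parallel(self, short_sim):
        s = project_both(short_sim.trajectory)
        out = filter_quasi_1d(s)
        # quasi-1-D by construction: only the |d_par| < 20 cut can bite
        assert out.attrs["retained_fraction"] > 0.9


class TestBinning:
    def test_single_sample(self):
        fmap = bin_forcemap(_samples(
            [{"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 7.0}]
        ))
        assert fmap.total_occupancy == 1
        assert fmap.mean_force.compressed().tolist() == [7.0]

    def test_cancellation(self):
        fmap = bin_forcemap(_samples(
            [
                {"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 10.0},
                {"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": -10.0},
            ]
        ))
        assert fmap.mean_force.compressed().tolist() == [0.0]

    def test_occupancy_conservation_and_exclusion_count(self, short_sim):
        samples = filter_quasi_1d(project_both(short_sim.trajectory))
        fmap = bin_forcemap(samples)
        assert fmap.total_occupancy + fmap.n_excluded == len(samples)

    def test_pooling_identity(self, short_sim):
        # one map from pooled samples == occupancy-weighted merge of per-fish maps
        t = short_sim.trajectory
        s0 = filter_quasi_1d(project_to_focal_frame(t, 0))
        s1 = filter_quasi_1d(project_to_focal_frame(t, 1))
        pooled = bin_forcemap(pd.concat([s0, s1], ignore_index=True))
        m0, m1 = bin_forcemap(s0), bin_forcemap(s1)
        np.testing.assert_array_equal(pooled.occupancy, m0.occupancy + m1.occupancy)
        np.testing.assert_allclose(pooled.force_sum, m0.force_sum + m1.force_sum)
        occ = pooled.occupancy
        merged = np.where(
            occ > 0,
            (m0.force_sum + m1.force_sum) / np.maximum(occ, 1),
            np.nan,
        )
        np.testing.assert_allclose(
            pooled.mean_force.filled(np.nan), merged, equal_nan=True
        )

    def test_half_open_bins(self):
        fmap = bin_forcemap(_samples(
            [{"d_par": -20.0, "v_p_proj": 0.0, "v_f": 0.0, "a_par": 1.0},
             {"d_par": 20.0, "v_p_proj": 0.0, "v_f": 0.0, "a_par": 1.0}]
        ))
        assert fmap.total_occupancy == 1  # upper edge excluded
        assert fmap.n_excluded == 1

    def test_negative_partner_speed_excluded_but_counted(self):
        fmap = bin_forcemap(_samples(
            [{"d_par": 1.0, "v_p_proj": -2.0, "v_f": 5.0, "a_par": 1.0}]
        ))
        assert fmap.total_occupancy == 0
        assert fmap.n_excluded == 1


class TestShuffleCorrection:
    def _tiny_map(self, k=0.0):
        shape = (3, 10, 6)
        occ = np.zeros(shape, dtype=np.int64)
        fsum = np.zeros(shape)
        occ[0, 5, 0], fsum[0, 5, 0] = 4, 8.0
        return Forcemap(DEFAULT_D_EDGES, DEFAULT_VP_EDGES, DEFAULT_VF_EDGES,
                        occ, fsum, np.zeros(shape), k=k)

    def test_zero_k_leaves_map_unchanged(self):
        assert self._tiny_map(k=0.0).mean_force[0, 5, 0] == 2.0

    def test_printed_scaling_rule(self):
        # k = 0.2 scales all forces by 1/(1-0.2) = 1.25
        assert self._tiny_map(k=0.2).mean_force[0, 5, 0] == pytest.approx(2.5)

    def test_correction_touches_values_not_occupancies(self, short_sim):
        t = short_sim.trajectory
        samples = filter_quasi_1d(project_both(t))
        fmap = bin_forcemap(samples)
        corrected = shuffle_correction(fmap, t, n_shuffles=3,
                                       rng=np.random.default_rng(0),
                                       wrap_length=short_sim.config.track_length)
        np.testing.assert_array_equal(corrected.occupancy, fmap.occupancy)
        assert 0.0 < corrected.k < 1.0
        ratio = corrected.mean_force / fmap.mean_force
        np.testing.assert_allclose(ratio.compressed(), 1.0 / (1.0 - corrected.k))

    def test_independent_walkers_have_chance_level_k(self):
        # decoupling two already-independent fish changes nothing, so the
        # shuffled occupancy matches the observed one and k sits near 1
        traj, _ = make_independent_walkers(n=9000, seed=4)
        samples = filter_quasi_1d(project_both(traj))
        fmap = bin_forcemap(samples)
        k = estimate_chance_fraction(fmap, traj, n_shuffles=5,
                                     rng=np.random.default_rng(1))
        assert 0.7 < k < 1.3

    def test_social_pair_k_below_chance_threshold(self, short_sim):
        t = short_sim.trajectory
        fmap = bin_forcemap(filter_quasi_1d(project_both(t)))
        k = estimate_chance_fraction(fmap, t, n_shuffles=5,
                                     rng=np.random.default_rng(2),
                                     wrap_length=short_sim.config.track_length)
        assert 0.05 < k < 0.8

    def test_k_at_or_above_one_rejected(self, short_sim):
        t = short_sim.trajectory
        fmap = bin_forcemap(filter_quasi_1d(project_both(t)))
        with pytest.raises(ValueError):
            replace(fmap, k=1.0)


class TestProfilesAndQuadrants:
    def test_simulated_distance_profile_signs(self, short_sim):
        fmap = bin_forcemap(filter_quasi_1d(project_both(short_sim.trajectory)))
        prof = distance_profile(fmap)
        good = prof[prof["occupancy"] >= 50]
        ahead = good[good["d_center"] > 0]["mean_force"]
        behind = good[good["d_center"] < 0]["mean_force"]
        assert (ahead > 0).all()
        assert (behind < 0).all()

    def test_odd_symmetric_fixture(self):
        rows = []
        for d in (-15.0, -5.0, 5.0, 15.0):
            for _ in range(10):
                rows.append({"d_par": d, "v_p_proj": 5.0, "v_f": 5.0,
                             "a_par": np.sign(d) * 3.0})
        prof = distance_profile(bin_forcemap(_samples(rows)))
        filled = prof.dropna(subset=["mean_force"])
        np.testing.assert_allclose(
            filled["mean_force"].to_numpy(),
            3.0 * np.sign(filled["d_center"].to_numpy()),
        )

    def test_empty_bins_masked_not_zero(self):
        prof = distance_profile(bin_forcemap(_samples(
            [{"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 2.0}]
        )))
        assert prof["mean_force"].isna().sum() == 9

    def test_uniform_force_gives_uniform_quadrants(self):
        rows = [
            {"d_par": d, "v_p_proj": vp, "v_f": vf, "a_par": 4.2}
            for d in (-10.0, 10.0)
            for vp in (5.0, 25.0)
            for vf in (5.0, 15.0, 25.0)
        ]
        q = quadrant_analysis(bin_forcemap(_samples(rows)))
        np.testing.assert_allclose(q["mean_force"], 4.2)

    def test_empty_quadrant_masked(self):
        q = quadrant_analysis(bin_forcemap(_samples(
            [{"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 1.0}]
        )))
        assert q["mean_force"].isna().sum() == 11


class TestPeakForce:
    def test_zero_map(self):
        fmap = bin_forcemap(_samples(
            [{"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 0.0}]
        ))
        assert peak_force(fmap, min_occupancy=1) == 0.0

    def test_singleton_outlier_excluded(self):
        rows = [{"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 2.0}
                for _ in range(25)]
        rows.append({"d_par": 15.0, "v_p_proj": 25.0, "v_f": 25.0, "a_par": 500.0})
        fmap = bin_forcemap(_samples(rows))
        assert peak_force(fmap, min_occupancy=20) == pytest.approx(2.0)

    def test_no_qualifying_bin_is_an_error(self):
        fmap = bin_forcemap(_samples(
            [{"d_par": 1.0, "v_p_proj": 5.0, "v_f": 5.0, "a_par": 1.0}]
        ))
        with pytest.raises(ValueError):
            peak_force(fmap, min_occupancy=20)
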