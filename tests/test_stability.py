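"""Stable-point census, crossing statistics and the derived analyses."""

import numpy as np
import pytest

from reinworld import (ModelConfig, Trajectory, basin_map,
                       count_stable_points_1d, detect_plateaus,
                       expected_stable_points, find_fixed_points_nd,
                       find_stable_points_1d, hysteresis_sweep,
                       rein_pair_probability, relax, rice_downcrossings,
                       sample_field, survival_probability, threshold_K,
                       transition_intervals)


class TestCensus1D:
    def test_linear_restoring_force(self):
        pts = find_stable_points_1d(lambda x: -(x - 50.0), 100.0)
        assert len(pts) == 1
        assert pts[0].classification == "stable"
        assert pts[0].location[0] == pytest.approx(50.0, abs=1e-4)

    def test_constant_force_has_no_crossings(self):
        assert find_stable_points_1d(lambda x: 1.0, 100.0) == []

    def test_sinusoid_census_matches_closed_form(self):
        pts = find_stable_points_1d(lambda x: np.sin(2 * np.pi * x / 25.0),
                                    100.0, h=0.5)
        stable = [p for p in pts if p.classification == "stable"]
        assert len(stable) == 4
        np.testing.assert_allclose(sorted(p.location[0] for p in stable),
                                   [12.5, 37.5, 62.5, 87.5], atol=1e-4)

    def test_alternation_on_gp_fields(self, gauss_kernel):
        rng = np.random.default_rng(17)
        for _ in range(10):
            fld = sample_field(gauss_kernel, R=100.0, n_env=1, rng=rng)
            pts = find_stable_points_1d(fld, 100.0)
            kinds = [p.classification for p in pts]
            for a, b in zip(kinds[:-1], kinds[1:]):
                assert a != b  # stable and unstable strictly alternate

    def test_fast_count_agrees_with_census(self, gauss_kernel):
        rng = np.random.default_rng(29)
        for _ in range(10):
            fld = sample_field(gauss_kernel, R=100.0, n_env=1, rng=rng)
            pts = find_stable_points_1d(fld, 100.0)
            n_stable = sum(p.classification == "stable" for p in pts)
            assert count_stable_points_1d(fld, 100.0) == n_stable


class TestCensusND:
    def test_separable_linear_field_single_point(self):
        pts = find_fixed_points_nd(lambda E: -(E - 50.0), 100.0, h=5.0, n_env=3)
        assert len(pts) == 1
        assert pts[0].classification == "stable"
        np.testing.assert_allclose(pts[0].location, [50.0, 50.0, 50.0],
                                   atol=1e-6)

    def test_product_field_full_combinatorial_census(self):
        """The census of a separable field is the product of the 1-D
        censuses, class by class (stable x stable -> stable, mixed ->
        saddle, unstable x unstable -> unstable)."""
        f1 = lambda x: np.sin(2 * np.pi * x / 25.0)   # 4 down-, 3 up-crossings inside
        f2 = lambda y: (y - 30.0) * (y - 70.0) / 100.0  # up at 30, down at 70
        pts1 = find_stable_points_1d(f1, 100.0, h=0.5)
        pts2 = find_stable_points_1d(f2, 100.0, h=0.5)
        n1 = {c: sum(p.classification == c for p in pts1)
              for c in ("stable", "unstable")}
        n2 = {c: sum(p.classification == c for p in pts2)
              for c in ("stable", "unstable")}
        pts = find_fixed_points_nd(lambda E: np.array([f1(E[0]), f2(E[1])]),
                                   100.0, h=2.0, n_env=2)
        got = {c: sum(p.classification == c for p in pts)
               for c in ("stable", "unstable", "saddle")}
        assert got["stable"] == n1["stable"] * n2["stable"]
        assert got["unstable"] == n1["unstable"] * n2["unstable"]
        assert got["saddle"] == (n1["stable"] * n2["unstable"]
                                 + n1["unstable"] * n2["stable"])
        assert len(pts) == len(pts1) * len(pts2)

    def test_gp_field_census_resolution_stable(self, gauss_kernel):
        """Halving the grid spacing must not change the censused stable
        points of one realisation by more than the merge tolerance."""
        rng = np.random.default_rng(31)
        fld = sample_field(gauss_kernel, R=60.0, n_env=2, rng=rng)
        pts = [p.location for p in find_fixed_points_nd(fld, 60.0)
               if p.classification == "stable"]
        # resample the same surface on a finer grid by interpolation
        fine_axis = np.linspace(0.0, 60.0, 2 * (fld.axis.size - 1) + 1)
        mesh = np.stack(np.meshgrid(fine_axis, fine_axis, indexing="ij"),
                        axis=-1)
        from reinworld import GPForceField
        fine = GPForceField(axis=fine_axis,
                            samples=np.moveaxis(
                                fld.force(mesh.reshape(-1, 2)).reshape(
                                    mesh.shape[0], mesh.shape[1], 2), -1, 0),
                            kernel=fld.kernel)
        pts_fine = [p.location for p in find_fixed_points_nd(fine, 60.0)
                    if p.classification == "stable"]
        assert len(pts) == len(pts_fine)
        for p in pts:
            assert min(np.linalg.norm(p - q) for q in pts_fine) < 0.1


class TestClosedForms:
    def test_expected_count_matches_rice_oracle(self, gauss_kernel):
        # the 1-D closed form equals the stationary-GP down-crossing rate
        # computed from the kernel curvature by finite differences
        assert expected_stable_points(1, 100.0, 5.0) == pytest.approx(
            rice_downcrossings(gauss_kernel, 100.0, numeric=True), rel=1e-5)

    def test_expected_count_limits_and_monotonicity(self):
        widths = np.array([5.0, 10.0, 20.0, 50.0, 90.0])
        vals = [expected_stable_points(1, 100.0, w) for w in widths]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))
        assert vals[-1] < 1.0  # a near-range-wide niche leaves O(1) states
        # ratio invariance: only R/width matters
        assert expected_stable_points(1, 100.0, 5.0) == pytest.approx(
            expected_stable_points(1, 200.0, 10.0))
        with pytest.raises(ValueError):
            expected_stable_points(1, 5.0, 5.0)

    def test_threshold_directions(self):
        assert threshold_K(100.0, 10.0) < threshold_K(100.0, 5.0)
        assert threshold_K(200.0, 5.0) > threshold_K(100.0, 5.0)
        assert threshold_K(100.0, 5.0, n_env=2) > threshold_K(100.0, 5.0)

    def test_saturation_knee_near_threshold(self):
        """The K at which the measured count first reaches 95% of its
        large-K plateau lies within a factor of two of the closed-form
        diversity threshold."""
        from reinworld import saturation_sweep

        cfg = ModelConfig(K=100, n_env=1, seed=1)
        K_grid = [10, 20, 30, 40, 50, 80, 1000]
        df = saturation_sweep(K_grid, cfg, n_populations=400,
                              rng=np.random.default_rng(61))
        plateau = df[df["K"] == 1000]["mean"].iloc[0]
        knee = next(int(k) for k, m in zip(df["K"], df["mean"])
                    if m >= 0.95 * plateau)
        kt = threshold_K(cfg.essential_range, cfg.niche_width)
        assert kt / 2 <= knee <= 2 * kt


class TestReinPair:
    def test_analytic_value(self):
        assert rein_pair_probability("analytic") == 0.25

    def test_monte_carlo_brackets_analytic(self):
        p = rein_pair_probability("monte_carlo", n_trials=100_000,
                                  rng=np.random.default_rng(2))
        assert abs(p - 0.25) < 0.005

    def test_degenerate_all_positive_effects(self):
        assert rein_pair_probability("analytic", positive_prob=1.0) == 0.0
        assert rein_pair_probability("monte_carlo", n_trials=1000,
                                     rng=np.random.default_rng(3),
                                     positive_prob=1.0) == 0.0


class TestSurvival:
    def test_global_attractor_always_survives(self, std_config):
        est = survival_probability(
            1, std_config, n_trials=20, rng=np.random.default_rng(5),
            field_factory=lambda r: (lambda E: -(E - 50.0)))
        assert est.estimate == 1.0 and est.n_escaped == 0

    def test_uniform_outward_force_never_survives(self, std_config):
        est = survival_probability(
            1, std_config, n_trials=20, rng=np.random.default_rng(6),
            field_factory=lambda r: (lambda E: np.ones_like(E)))
        assert est.estimate == 0.0 and est.n_escaped == 20

    def test_ci_brackets_estimate(self, std_config):
        est = survival_probability(1, std_config, n_trials=30,
                                   rng=np.random.default_rng(7))
        assert 0.0 <= est.ci_low <= est.estimate <= est.ci_high <= 1.0
        assert est.n_survived + est.n_escaped + est.n_unsettled == 30


class TestBasinsAndShocks:
    def test_basin_map_single_attractor(self, std_config):
        bm = basin_map(lambda E: -(E - 50.0), std_config, resolution=7)
        assert (bm.labels == 0).all()
        assert len(bm.stable_points) == 1

    def test_census_consistency_of_settled_endpoints(self, gauss_kernel,
                                                     std_config):
        """Every settled endpoint lies at a censused stable point, never at
        an unstable one (1-D GP realisations, P = 0)."""
        rng = np.random.default_rng(41)
        for _ in range(3):
            fld = sample_field(gauss_kernel, R=100.0, n_env=1, rng=rng)
            pts = find_stable_points_1d(fld, 100.0)
            stable = np.array([p.location[0] for p in pts
                               if p.classification == "stable"])
            unstable = np.array([p.location[0] for p in pts
                                 if p.classification == "unstable"])
            for E0 in rng.uniform(0.0, 100.0, size=5):
                res = relax(fld, np.array([E0]), std_config, t_max=600.0)
                if res.settled:
                    assert np.min(np.abs(stable - res.E[0])) < 0.1
                    if unstable.size:
                        assert np.min(np.abs(unstable - res.E[0])) > 0.5

    def test_shock_inside_and_outside_basin(self, gauss_kernel, std_config):
        """A sub-basin shock relaxes back to the same state; a large shock
        lands the system on a different censused stable point."""
        fld = sample_field(gauss_kernel, R=100.0, n_env=1,
                           rng=np.random.default_rng(47))
        pts = find_stable_points_1d(fld, 100.0)
        stable = sorted(p.location[0] for p in pts
                        if p.classification == "stable")
        unstable = sorted(p.location[0] for p in pts
                          if p.classification == "unstable")
        assert len(stable) >= 2
        # pick an interior stable point and its basin edges
        e0 = stable[1]
        edges = ([u for u in unstable if u < e0] or [0.0],
                 [u for u in unstable if u > e0] or [100.0])
        small = 0.5 * min(e0 - edges[0][-1], edges[1][0] - e0)
        res_in = relax(fld, np.array([e0 + small]), std_config, t_max=600.0)
        assert res_in.settled
        assert res_in.E[0] == pytest.approx(e0, abs=0.1)
        big = (edges[1][0] - e0) + 5.0
        res_out = relax(fld, np.array([e0 + big]), std_config, t_max=600.0)
        if res_out.settled:
            assert abs(res_out.E[0] - e0) > 1.0
            assert min(abs(s - res_out.E[0]) for s in stable) < 0.1


class TestHysteresis:
    CFG = ModelConfig(K=1, n_env=1, dt=0.05)

    def test_single_crossing_no_loop(self):
        loop = hysteresis_sweep(lambda x: -(x - 50.0) * 0.1, self.CFG,
                                p_lo=-1.0, p_hi=1.0, n_steps=41)
        assert loop.up_transitions == [] and loop.down_transitions == []
        np.testing.assert_allclose(loop.e_up, loop.e_down[::-1], atol=1e-3)

    def test_cubic_fold_points_located(self):
        a, c = 0.08, 300.0
        F = lambda x: -((x - 50.0) ** 3) / c + a * (x - 50.0)
        ef = np.sqrt(a * c / 3.0)
        p_fold = F(50.0 + ef)  # forcing at which the lower branch folds
        loop = hysteresis_sweep(F, self.CFG, p_lo=-1.0, p_hi=1.0, n_steps=101)
        assert len(loop.up_transitions) == 1
        assert len(loop.down_transitions) == 1
        step = loop.p_up[1] - loop.p_up[0]
        assert loop.up_transitions[0][0] == pytest.approx(p_fold, abs=1.5 * step)
        assert loop.down_transitions[0][0] == pytest.approx(-p_fold,
                                                            abs=1.5 * step)
        assert loop.is_hysteretic


class TestPlateaus:
    def test_detector_on_synthetic_staircase(self):
        cfg = ModelConfig(K=1, n_env=1, tau_env=1.0)
        t = np.arange(0.0, 300.0, 0.5)
        E = np.where(t < 140, 20.0, 40.0) + 0.05 * np.sin(t)
        # sharpen: linear 10-unit transition at t in [140, 150]
        ramp = np.clip((t - 140.0) / 10.0, 0.0, 1.0)
        E = 20.0 + 20.0 * ramp + 0.05 * np.sin(t)
        P = 0.01 * t
        traj = Trajectory(times=t, env=E[:, None], force=-P[:, None],
                          perturbation=P[:, None])
        plats = detect_plateaus(traj, cfg)
        assert len(plats) == 2
        gaps = transition_intervals(plats)
        assert len(gaps) == 1
        assert gaps[0][0] < 150.0 < gaps[0][1] or gaps[0][0] > 130.0
        for p in plats:
            assert p.comp_max_interior <= p.comp_max
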