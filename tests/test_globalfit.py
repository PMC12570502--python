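"""Hybrid GA+NLLS global fitting: objective, optimizer, scheme fits, CIs."""

import numpy as np
import pytest

from rnapkin import (
    ExperimentDesign,
    NoiseModel,
    OptimizerConfig,
    TimeCourse,
    Trajectory,
    build_scheme1,
    chi_square,
    fit_scheme2,
    generate_multi_nt,
    generate_single_nt,
    global_fit_scheme1,
    grid_search_ci,
    hybrid_optimize,
    simulate,
)
from rnapkin.globalfit import (
    GridMismatchError,
    InsufficientConditionsError,
    MissingSpeciesError,
)

FAST = OptimizerConfig(population=24, generations=20, n_starts=2, seed=0)


class TestChiSquare:
    def _traj_and_tc(self):
        t = np.geomspace(5e-3, 1.0, 5)
        y = np.linspace(0.1, 0.5, 5)
        traj = Trajectory(t, {"EC11": y, "rest": 1 - y}, ligand_conc_uM=10.0, temperature="25C")
        tc = TimeCourse(t, {"EC11": y.copy()}, conc_uM=10.0, temperature="25C")
        return traj, tc

    def test_perfect_model_gives_zero(self):
        traj, tc = self._traj_and_tc()
        assert chi_square([traj], [tc]) == 0.0

    def test_constant_offset_closed_form(self):
        traj, tc = self._traj_and_tc()
        tc.fractions["EC11"] = tc.fractions["EC11"] + 0.05
        assert chi_square([traj], [tc]) == pytest.approx(5 * 0.05**2)

    def test_weights_scale_residuals_exactly(self):
        traj, tc = self._traj_and_tc()
        tc.fractions["EC11"] = tc.fractions["EC11"] + 0.1
        w = np.array([1.0, 2.0, 3.0, 0.5, 1.0])
        expected = float(np.sum((0.1 * w) ** 2))
        assert chi_square([traj], [tc], weights={"EC11": w}) == pytest.approx(expected)

    def test_grid_mismatch_rejected(self):
        traj, tc = self._traj_and_tc()
        other = TimeCourse(tc.times * 2, dict(tc.fractions), conc_uM=10.0, temperature="25C")
        with pytest.raises(GridMismatchError):
            chi_square([traj], [other])


class TestHybridOptimizer:
    def test_convex_quadratic_reaches_analytic_minimum(self):
        x, f, _ = hybrid_optimize(
            lambda v: (v[0] - 1.2) ** 2 + 3 * (v[1] + 0.4) ** 2,
            [(-5, 5), (-5, 5)],
            FAST,
        )
        assert np.allclose(x, [1.2, -0.4], atol=1e-6)
        assert f < 1e-10

    def test_bimodal_toy_finds_global_basin(self):
        """Two quadratic wells; the deeper one (at +2) must win nearly always."""

        def obj(v):
            return min(
                0.5 + (v[0] + 2) ** 2 + (v[1] + 2) ** 2,
                0.0 + (v[0] - 2) ** 2 + (v[1] - 2) ** 2,
            )

        hits = 0
        for seed in range(25):
            cfg = OptimizerConfig(population=24, generations=15, n_starts=2, seed=seed)
            x, f, _ = hybrid_optimize(obj, [(-6, 6), (-6, 6)], cfg)
            hits += f < 0.25
        assert hits >= 24

    def test_trace_is_monotone_nonincreasing(self):
        _, _, trace = hybrid_optimize(
            lambda v: np.sin(5 * v[0]) + v[0] ** 2, [(-3, 3)], FAST
        )
        assert np.all(np.diff(trace) <= 0)

    def test_determinism_under_fixed_seed(self):
        obj = lambda v: (v[0] - 0.5) ** 4 + abs(v[1])
        r1 = hybrid_optimize(obj, [(-2, 2), (-2, 2)], FAST)
        r2 = hybrid_optimize(obj, [(-2, 2), (-2, 2)], FAST)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]


class TestScheme1GlobalFit:
    def test_noise_free_recovery_within_one_percent(self, table1_params, quiet_noise):
        design = ExperimentDesign(
            time_grid=np.geomspace(5e-3, 10, 20), concentrations_uM=(10.0, 250.0)
        )
        tcs = generate_single_nt(design, table1_params, quiet_noise)
        fit = global_fit_scheme1(tcs, FAST)
        assert fit.estimates["Kd"] == pytest.approx(table1_params.Kd, rel=0.01)
        assert fit.estimates["k3"] == pytest.approx(table1_params.k3, rel=0.01)
        assert fit.chi_square < 1e-8
        assert fit.fixed["k1"] == 1.0e8

    def test_noisy_recovery_within_ten_percent(self, table1_params):
        design = ExperimentDesign()
        tcs = generate_single_nt(design, table1_params, NoiseModel(seed=7))
        fit = global_fit_scheme1(tcs, OptimizerConfig(population=24, generations=20, n_starts=2, seed=7))
        assert fit.estimates["k3"] == pytest.approx(table1_params.k3, rel=0.10)

    def test_single_concentration_rejected(self, table1_params, quiet_noise):
        design = ExperimentDesign(
            time_grid=np.geomspace(5e-3, 10, 15), concentrations_uM=(250.0,)
        )
        tcs = generate_single_nt(design, table1_params, quiet_noise)
        with pytest.raises(InsufficientConditionsError):
            global_fit_scheme1(tcs, FAST)

    def test_determinism_of_full_result(self, table1_params, small_design):
        tcs = generate_single_nt(small_design, table1_params, NoiseModel(seed=2))
        f1 = global_fit_scheme1(tcs, FAST)
        f2 = global_fit_scheme1(tcs, FAST)
        assert f1.estimates == f2.estimates and f1.chi_square == f2.chi_square


class TestScheme2Fit:
    def test_noise_free_recovery_within_five_percent(self, chain_params_65c_1000, quiet_noise):
        design = ExperimentDesign(concentrations_uM=(1000.0,), temperature="65C")
        tcs = generate_multi_nt(design, chain_params_65c_1000, quiet_noise)
        cfg = OptimizerConfig(population=32, generations=40, n_starts=3, seed=5)
        fit = fit_scheme2(tcs, reversible=True, config=cfg)
        for i, truth in chain_params_65c_1000.kobs.items():
            assert fit.estimates[f"kobs{i}"] == pytest.approx(truth, rel=0.05)
        assert fit.chi_square < 1e-8

    def test_irreversible_fit_worse_on_reversible_truth(self, chain_params_25c_1000):
        design = ExperimentDesign(concentrations_uM=(1000.0,))
        tcs = generate_multi_nt(design, chain_params_25c_1000, NoiseModel(seed=3))
        cfg = OptimizerConfig(population=32, generations=30, n_starts=2, seed=3)
        rev = fit_scheme2(tcs, reversible=True, config=cfg)
        irr = fit_scheme2(tcs, reversible=False, config=cfg)
        assert irr.chi_square > rev.chi_square
        assert len(irr.estimates) == 3 and len(rev.estimates) == 6

    def test_missing_species_rejected(self, chain_params_25c_1000, quiet_noise):
        design = ExperimentDesign(concentrations_uM=(1000.0,))
        tcs = generate_multi_nt(design, chain_params_25c_1000, quiet_noise)
        for tc in tcs:
            del tc.fractions["M12"]
        with pytest.raises(MissingSpeciesError):
            fit_scheme2(tcs, reversible=True, config=FAST)


class TestGridSearchCI:
    def test_gaussian_case_matches_analytic_width(self, table1_params, quiet_noise):
        """On near-noiseless data with a quadratic basin, the profiled 68%
        interval must bracket the estimate tightly and symmetrically."""
        design = ExperimentDesign(
            time_grid=np.geomspace(5e-3, 10, 20), concentrations_uM=(10.0, 250.0)
        )
        tcs = generate_single_nt(design, table1_params, NoiseModel(fraction_sd=0.01, seed=9))
        fit = global_fit_scheme1(tcs, FAST)
        lo, hi = grid_search_ci(fit, tcs, "k3")
        assert lo < fit.estimates["k3"] < hi
        est = fit.estimates["k3"]
        assert (hi - lo) / est < 0.1
        # crude symmetry of a near-quadratic basin
        assert 0.3 < (est - lo) / (hi - est) < 3.0

    def test_bounds_recorded_on_result(self, table1_params, quiet_noise, small_design):
        tcs = generate_single_nt(small_design, table1_params, NoiseModel(fraction_sd=0.02, seed=4))
        fit = global_fit_scheme1(tcs, FAST)
        grid_search_ci(fit, tcs, "Kd")
        lo, hi = fit.bounds68["Kd"]
        assert lo <= fit.estimates["Kd"] <= hi

    def test_unidentifiable_parameter_truncates_with_warning(self, table1_params):
        """With only saturating concentrations the lower edge of Kd is
        unidentifiable: the profile never crosses and the interval is
        truncated at the search-box edge, flagged on the result."""
        design = ExperimentDesign(
            time_grid=np.geomspace(5e-3, 10, 15), concentrations_uM=(250.0, 1000.0)
        )
        tcs = generate_single_nt(design, table1_params, NoiseModel(seed=6))
        fit = global_fit_scheme1(tcs, FAST)
        lo, hi = grid_search_ci(fit, tcs, "Kd")
        assert lo <= fit.estimates["Kd"] <= hi
        assert any("truncated" in w for w in fit.warnings)

    def test_unfloated_parameter_rejected(self, table1_params, quiet_noise, small_design):
        tcs = generate_single_nt(small_design, table1_params, quiet_noise)
        fit = global_fit_scheme1(tcs, FAST)
        with pytest.raises(ValueError):
            grid_search_ci(fit, tcs, "k1")
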