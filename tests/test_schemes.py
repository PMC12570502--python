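"""Kinetic-scheme construction, ODE integration, and derived quantities.

The independent oracle for the linear systems is the matrix exponential
computed per time point with scipy.linalg.expm, assembled here from the
scheme's rate matrix.
"""

import numpy as np
import pytest
import scipy.linalg

from rnapkin import (
    RateParameters,
    build_scheme1,
    build_scheme2,
    intermediate_half_life,
    pseudo_first_order_kobs,
    simulate,
)
from rnapkin.schemes import KineticScheme, NoPeakError, SchemeError, Transition, rate_matrix
from rnapkin.tables import chain_params


def expm_oracle(scheme, params, conc, times):
    K = rate_matrix(scheme, params, conc)
    y0 = np.zeros(len(scheme.species))
    y0[0] = 1.0
    return np.column_stack([scipy.linalg.expm(K * t) @ y0 for t in times])


class TestSchemeConstruction:
    def test_scheme1_shape_and_reverse_rate(self, table1_params):
        s = build_scheme1()
        assert len(s.species) == 3
        assert table1_params.k_minus1 == pytest.approx(298.5)

    def test_scheme2_reversible_has_six_rates(self):
        assert len(build_scheme2(True).rate_symbols) == 6
        assert len(build_scheme2(False).rate_symbols) == 3

    def test_scheme2_is_a_simple_path(self):
        s = build_scheme2(True)
        pairs = {(t.source, t.target) for t in s.transitions}
        chain = list(zip(s.species[:-1], s.species[1:]))
        assert pairs == set(chain) | {(b, a) for a, b in chain}

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(SchemeError):
            RateParameters(Kd=-1.0, k3=1.0)
        with pytest.raises(SchemeError):
            RateParameters(Kd=0.0, k3=1.0)

    def test_undeclared_species_rejected(self):
        with pytest.raises(SchemeError):
            KineticScheme("bad", ("A",), (Transition("A", "B", "k"),))


class TestSimulate:
    @pytest.mark.parametrize("conc", [10.0, 1000.0])
    def test_matches_matrix_exponential_oracle(self, table1_params, conc):
        times = np.geomspace(1e-4, 10.0, 50)
        s = build_scheme1()
        traj = simulate(s, table1_params, conc, times)
        oracle = expm_oracle(s, table1_params, conc, times)
        sim = np.vstack([traj.species(name) for name in s.species])
        assert np.max(np.abs(sim - oracle)) < 1e-6

    def test_scheme2_matches_oracle(self, chain_params_65c_1000):
        times = np.geomspace(1e-4, 10.0, 50)
        s = build_scheme2(True)
        traj = simulate(s, chain_params_65c_1000, 1000.0, times)
        oracle = expm_oracle(s, chain_params_65c_1000, 1000.0, times)
        sim = np.vstack([traj.species(name) for name in s.species])
        assert np.max(np.abs(sim - oracle)) < 1e-6

    def test_irreversible_sink_absorbs_everything(self, table1_params):
        traj = simulate(build_scheme1(), table1_params, 1000.0, np.array([50.0, 100.0]))
        assert traj.species("EC11")[-1] == pytest.approx(1.0, abs=1e-6)

    def test_fractions_sum_to_one(self, chain_params_25c_1000):
        times = np.geomspace(5e-3, 10.0, 40)
        traj = simulate(build_scheme2(True), chain_params_25c_1000, 1000.0, times)
        total = sum(traj.species(n) for n in traj.fractions)
        assert np.allclose(total, 1.0, atol=1e-6)

    def test_zero_reverse_rates_reproduce_irreversible_chain(self):
        fwd = {1: 0.5, 3: 0.3, 5: 0.2}
        params_rev = RateParameters(kobs={**fwd, 2: 0.0, 4: 0.0, 6: 0.0})
        params_irr = RateParameters(kobs=fwd)
        times = np.geomspace(5e-3, 10.0, 30)
        t_rev = simulate(build_scheme2(True), params_rev, 0.0, times)
        t_irr = simulate(build_scheme2(False), params_irr, 0.0, times)
        for name in t_rev.fractions:
            assert np.allclose(t_rev.species(name), t_irr.species(name), atol=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(SchemeError):
            RateParameters(kobs={1: -0.1})


class TestDerivedQuantities:
    def test_half_saturation_and_saturation_limits(self):
        assert pseudo_first_order_kobs(3.0, 2.0, 3.0) == pytest.approx(1.0)
        assert pseudo_first_order_kobs(3.0, 2.0, 1e9) == pytest.approx(2.0, rel=1e-6)

    def test_published_operating_point(self):
        assert pseudo_first_order_kobs(2.985, 1.001, 250.0) == pytest.approx(0.989, abs=5e-4)

    def test_rapid_equilibrium_matches_dominant_relaxation(self, table1_params):
        # binding equilibrates ~1e4 faster than catalysis at 100 uM
        K = rate_matrix(build_scheme1(), table1_params, 100.0)
        slow = sorted(abs(np.linalg.eigvals(K)))[1]  # smallest nonzero magnitude
        kobs = pseudo_first_order_kobs(table1_params.Kd, table1_params.k3, 100.0)
        assert slow == pytest.approx(kobs, rel=2e-2)

    def test_two_state_half_life_is_ln2_over_k(self):
        k = 3.0
        params = RateParameters(kobs={1: k, 3: 0.0, 5: 0.0})
        times = np.geomspace(1e-4, 5.0, 200)
        traj = simulate(build_scheme2(False), params, 0.0, times)
        assert intermediate_half_life(traj, "M10") == pytest.approx(np.log(2) / k, rel=1e-3)

    def test_terminal_accumulator_has_no_peak(self, chain_params_65c_1000):
        times = np.geomspace(5e-3, 10.0, 60)
        traj = simulate(build_scheme2(True), chain_params_65c_1000, 1000.0, times)
        with pytest.raises(NoPeakError):
            intermediate_half_life(traj, "M13plus")

    def test_transient_intermediate_half_life_against_dense_oracle(self):
        params = chain_params(10.0, temperature="65C")
        times = np.geomspace(1e-5, 1.0, 400)
        traj = simulate(build_scheme2(True), params, 10.0, times)
        t_half = intermediate_half_life(traj, "M11")
        # brute-force dense-grid oracle on the matrix-exponential solution:
        # time from the peak to halfway between peak and end-of-window level
        s = build_scheme2(True)
        tt = np.linspace(1e-6, 1.0, 100_000)
        y = expm_oracle(s, params, 10.0, tt)[s.index("M11")]
        ipk = int(np.argmax(y))
        half = y[-1] + (y[ipk] - y[-1]) / 2
        below = np.nonzero(y[ipk:] <= half)[0]
        oracle = tt[ipk + below[0]] - tt[ipk]
        assert t_half == pytest.approx(oracle, rel=0.02)
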