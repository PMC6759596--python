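"""Membrane flux laws against independent oracles and exact limits."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy.linalg import null_space

from rootflux.constants import FARADAY, GAS_CONSTANT
from rootflux.kinetics import (
    CarrierCycleParams,
    KineticsValidationError,
    antiporter_flux,
    boltzmann_open_probability,
    carrier_charge_flux,
    carrier_cycle_flux,
    ghk_flux,
    king_altman_flux,
    kor_gating_midpoint,
    nscc_permeability,
    water_flux_plasma_membrane,
    water_flux_tonoplast,
)

T = 298.0
RT_F = GAS_CONSTANT * T / FARADAY


class TestGHK:
    def test_zero_at_nernst_potential(self):
        for z, c_in, c_out in [(1, 10.0, 100.0), (1, 50.0, 5.0), (-1, 3.0, 30.0)]:
            V = (RT_F / z) * np.log(c_out / c_in)
            assert ghk_flux(1e-9, z, V, c_in, c_out, T) == pytest.approx(0.0, abs=1e-22)

    def test_small_voltage_limit_is_ficks_law(self):
        J = ghk_flux(1e-9, 1, 1e-12, 10.0, 100.0, T)
        assert J == pytest.approx(1e-9 * (10.0 - 100.0), rel=1e-6)

    def test_matches_high_precision_evaluation(self):
        # independent oracle: 50-digit symbolic evaluation of the closed form
        P, z, V, c_in, c_out = 1e-9, 1, -0.1, 10.0, 100.0
        u = sympy.Rational(z) * sympy.Float(FARADAY, 50) * sympy.Float(V, 50) / (
            sympy.Float(GAS_CONSTANT, 50) * sympy.Float(T, 50)
        )
        expected = sympy.Float(P, 50) * u * (
            sympy.Float(c_in, 50) - sympy.Float(c_out, 50) * sympy.exp(-u)
        ) / (1 - sympy.exp(-u))
        got = ghk_flux(P, z, V, c_in, c_out, T)
        assert got == pytest.approx(float(sympy.N(expected, 50)), rel=1e-10)

    @settings(deadline=None, max_examples=60)
    @given(
        V=st.floats(-0.25, 0.25),
        c_in=st.floats(0.01, 500.0),
        c_out=st.floats(0.01, 500.0),
    )
    def test_reversal_antisymmetry(self, V, c_in, c_out):
        # J(V; c_in, c_out) = -J(-V; c_out, c_in) for fixed z
        a = ghk_flux(2e-9, 1, V, c_in, c_out, T)
        b = ghk_flux(2e-9, 1, -V, c_out, c_in, T)
        assert a == pytest.approx(-b, rel=1e-9, abs=1e-25)

    def test_continuous_across_voltage_regimes(self):
        # the small/exact/asymptotic branches must join smoothly
        V = np.array([-2.0, -1.5, -0.5, -1e-6, -1e-9, 0.0, 1e-9, 1e-6, 0.5, 2.0])
        J = ghk_flux(1e-9, 1, V, 10.0, 100.0, T)
        assert np.all(np.isfinite(J))
        # positive chord conductance: flux is monotone increasing in V
        assert np.all(np.diff(J) > 0)


class TestGating:
    def test_midpoint_half_open(self):
        assert boltzmann_open_probability(-0.05, -0.05, 0.01, "inward") == 0.5
        assert boltzmann_open_probability(-0.05, -0.05, 0.01, "outward") == 0.5

    def test_saturation_limits(self):
        assert boltzmann_open_probability(-10.0, -0.05, 0.01, "inward") == pytest.approx(1.0)
        assert boltzmann_open_probability(10.0, -0.05, 0.01, "inward") == pytest.approx(0.0)
        assert boltzmann_open_probability(10.0, -0.05, 0.01, "outward") == pytest.approx(1.0)

    def test_grid_matches_direct_transcendental_evaluation(self):
        V = np.linspace(-0.2, 0.1, 31)
        p = boltzmann_open_probability(V, -0.05, 0.01, "outward")
        direct = 1.0 / (1.0 + np.exp(-(V + 0.05) / 0.01))
        np.testing.assert_allclose(p, direct, rtol=1e-12)
        assert np.all(np.diff(p) > 0)

    def test_zero_slope_rejected(self):
        with pytest.raises(KineticsValidationError):
            boltzmann_open_probability(0.0, 0.0, 0.0, "inward")

    def test_kor_midpoint_tracks_nernst_slope(self):
        v1 = kor_gating_midpoint(5.0, 100.0, 0.0, T)
        v10 = kor_gating_midpoint(50.0, 100.0, 0.0, T)
        assert v10 - v1 == pytest.approx(RT_F * np.log(10.0), rel=1e-12)

    def test_kor_midpoint_offset_at_reference(self):
        assert kor_gating_midpoint(100.0, 100.0, 0.017, T) == pytest.approx(0.017)

    def test_kor_midpoint_monotone(self):
        vals = [kor_gating_midpoint(k, 100.0, 0.0, T) for k in (0.5, 5.0, 50.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_kor_rejects_nonpositive_k(self):
        with pytest.raises(KineticsValidationError):
            kor_gating_midpoint(0.0, 100.0)


class TestNSCCBlock:
    def test_no_calcium_no_block(self):
        assert nscc_permeability(2e-9, 0.0, 0.3) == 2e-9

    def test_half_block_at_k(self):
        assert nscc_permeability(2e-9, 0.3, 0.3) == pytest.approx(1e-9)

    def test_ratio_matches_direct_evaluation(self):
        lo = nscc_permeability(1e-9, 0.5, 0.3)
        hi = nscc_permeability(1e-9, 2.0, 0.3)
        assert lo / hi == pytest.approx((0.3 / 0.8) / (0.3 / 2.3), rel=1e-12)
        assert lo > hi  # monotone decreasing in Ca


class TestAntiporter:
    def test_equilibrium_ratio_gives_zero_flux(self):
        # Na_in/Na_out == H_in/H_out -> no net exchange
        assert antiporter_flux(1e-7, 10.0, 50.0, 2e-4, 1e-3) == pytest.approx(0.0)

    def test_knockout(self):
        assert antiporter_flux(0.0, 123.0, 1.0, 1e-3, 1e-5) == 0.0

    def test_physiological_sign_and_magnitude(self):
        # acidic apoplast (pH 5.3) vs cytosol (pH 7.2) drives Na+ efflux
        H_out = 1e3 * 10 ** (-5.3)
        H_in = 1e3 * 10 ** (-7.2)
        J = antiporter_flux(1e-7, 10.0, 50.0, H_in, H_out)
        assert J == pytest.approx(1e-7 * (10.0 * H_out - 50.0 * H_in), rel=1e-12)
        assert J > 0

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.1, 200.0), st.floats(0.1, 200.0), st.floats(1e-6, 1e-2))
    def test_charge_neutrality_by_stoichiometry(self, na_in, na_out, h):
        # 1 Na+ out against 1 H+ in: net charge flux is identically zero
        J_na = antiporter_flux(1e-7, na_in, na_out, h, 2 * h)
        J_h = -J_na
        assert J_na + J_h == 0.0


def _random_rates(rng):
    return {k: float(10 ** rng.uniform(-1, 4)) for k in
            ("k12", "k21", "k23", "k32", "k34", "k43", "k41", "k14")}


def _master_equation_flux(rates, N=1.0):
    """Independent oracle: stationary distribution of the 4-state master
    equation via null space, then the net 1->2 edge flux."""
    k = rates
    A = np.array([
        [-(k["k12"] + k["k14"]), k["k21"], 0.0, k["k41"]],
        [k["k12"], -(k["k21"] + k["k23"]), k["k32"], 0.0],
        [0.0, k["k23"], -(k["k32"] + k["k34"]), k["k43"]],
        [k["k14"], 0.0, k["k34"], -(k["k43"] + k["k41"])],
    ])
    ns = null_space(A)
    p = ns[:, 0] / ns[:, 0].sum()
    return N * (p[0] * k["k12"] - p[1] * k["k21"])


class TestCarrierCycle:
    def test_detailed_balance_gives_zero_flux(self):
        k = dict(k12=2.0, k21=3.0, k23=5.0, k32=7.0, k34=11.0, k43=13.0,
                 k41=7.0 * 3 * 13 / (2 * 5 * 11), k14=1.0)
        J = king_altman_flux(**k, N=1e-8)
        assert J == pytest.approx(0.0, abs=1e-22)

    def test_matches_master_equation_oracle_on_random_rates(self, rng):
        # >= 100 random rate sets at tight relative tolerance
        for _ in range(120):
            rates = _random_rates(rng)
            ours = king_altman_flux(**rates, N=1.0)
            oracle = _master_equation_flux(rates)
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-18)

    def test_linear_in_carrier_density(self, rng):
        rates = _random_rates(rng)
        assert king_altman_flux(**rates, N=2e-8) == pytest.approx(
            2.0 * king_altman_flux(**rates, N=1e-8), rel=1e-12
        )

    def test_all_rates_zero_is_zero_not_error(self):
        zero = {k: 0.0 for k in ("k12", "k21", "k23", "k32", "k34", "k43", "k41", "k14")}
        assert king_altman_flux(**zero, N=1e-8) == 0.0

    def test_voltage_factors_applied_symmetrically(self):
        params = CarrierCycleParams(
            rates=dict(k12=10.0, k21=1.0, k23=5.0, k32=2.0, k34=20.0, k43=3.0,
                       k41=4.0, k14=6.0),
            N=1.0, z_t=1.0,
        )
        conc = {}
        V = -0.1
        from rootflux.kinetics import carrier_cycle_rates

        eff = carrier_cycle_rates(params, V, conc, T)
        f = np.exp(FARADAY * V / (2 * GAS_CONSTANT * T))
        assert eff["k23"] == pytest.approx(5.0 * f)
        assert eff["k32"] == pytest.approx(2.0 / f)
        # the voltage factor must not leak into other steps
        assert eff["k12"] == 10.0 and eff["k41"] == 4.0

    def test_binding_concentrations_enter_pseudo_first_order(self):
        params = CarrierCycleParams(
            rates=dict(k12=1e6, k21=1.0, k23=5.0, k32=2.0, k34=20.0, k43=1e6,
                       k41=4.0, k14=6.0),
            N=1e-8, z_t=0.0,
            binding={"k12": [("H", "in")], "k43": [("H", "out")]},
            cargo={"H": 1.0},
        )
        conc = {"H": {"in": 1e-4, "out": 5e-3}}
        J = carrier_cycle_flux(params, 0.0, conc, T)
        manual = king_altman_flux(1e6 * 1e-4, 1.0, 5.0, 2.0, 20.0, 1e6 * 5e-3,
                                  4.0, 6.0, N=1e-8)
        assert J == pytest.approx(manual, rel=1e-12)

    def test_charge_flux_reporting(self):
        params = CarrierCycleParams(
            rates=dict(k12=10.0, k21=1.0, k23=5.0, k32=2.0, k34=20.0, k43=3.0,
                       k41=4.0, k14=6.0),
            N=1e-8, z_t=2.0,
        )
        J = carrier_cycle_flux(params, -0.05, {}, T)
        assert carrier_charge_flux(params, J) == pytest.approx(2.0 * J)


class TestWaterFluxes:
    def test_balanced_pressures_no_flow(self):
        assert water_flux_plasma_membrane(1e-13, 0.9, 1e5, 1e5, 2e5, 2e5) == 0.0

    def test_osmotic_balance_at_sigma_one(self):
        # sigma = 1 and dP == dpi -> no flow
        assert water_flux_plasma_membrane(1e-13, 1.0, 3e5, 1e5, 5e5, 3e5) == pytest.approx(0.0)

    def test_plasma_membrane_direct_evaluation(self):
        Jv = water_flux_plasma_membrane(1e-13, 0.9, 0.2e6, 0.0, 0.1e6, 0.0)
        assert Jv == pytest.approx(1e-13 * (0.2e6 - 0.9 * 0.1e6), rel=1e-12)

    def test_tonoplast_ignores_hydraulic_pressure(self):
        # identical osmotic state, wildly different P: still zero
        assert water_flux_tonoplast(1e-12, 1.0, 4e5, 4e5) == 0.0

    def test_tonoplast_sign_opposes_osmotic_gradient(self):
        # water moves toward the osmotically stronger side
        assert water_flux_tonoplast(1e-12, 1.0, 2e5, 5e5) > 0  # into vacuole
        assert water_flux_tonoplast(1e-12, 1.0, 5e5, 2e5) < 0

    def test_tonoplast_sweep_matches_direct_evaluation(self):
        dpi = np.linspace(-3e5, 3e5, 13)
        Jv = water_flux_tonoplast(2e-12, 0.98, 1e5 + dpi, 1e5)
        np.testing.assert_allclose(Jv, -2e-12 * 0.98 * dpi, rtol=1e-12)
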