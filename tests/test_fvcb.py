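"""Core FvCB forward model and thermal-response forms against direct-formula oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from photoacclim.fvcb import (
    InvalidArgumentError,
    KineticsSet,
    LightParams,
    NoOptimumError,
    PeakedArrheniusParams,
    QuadraticParams,
    T0_C,
    arrhenius_adjust,
    available_kinetics,
    electron_transport,
    fvcb_ac,
    fvcb_aj,
    fvcb_anet,
    load_kinetics,
    peaked_arrhenius,
    quadratic_agrowth,
    topt_from_quadratic,
)

R = 8.314


class TestArrhenius:
    def test_reference_temperature_identity(self):
        assert arrhenius_adjust(404.9, 79430, 25.0) == pytest.approx(404.9, abs=1e-12)

    def test_zero_activation_energy(self):
        assert arrhenius_adjust(100.0, 0.0, 40.0) == 100.0

    def test_formula_oracle_at_35(self):
        # independent single-line transcription of the exponential form
        tk = 35.0 + 273.15
        expected = 404.9 * math.exp(79430 * (tk - 298.15) / (298.15 * R * tk))
        assert arrhenius_adjust(404.9, 79430, 35.0) == pytest.approx(
            expected, rel=1e-14
        )

    def test_strictly_increasing_and_input_validation(self):
        temps = np.linspace(-5, 45, 30)
        vals = arrhenius_adjust(100.0, 50_000.0, temps)
        assert np.all(np.diff(vals) > 0)
        with pytest.raises(InvalidArgumentError):
            arrhenius_adjust(float("nan"), 50_000.0, 25.0)
        with pytest.raises(InvalidArgumentError):
            arrhenius_adjust(-1.0, 50_000.0, 25.0)


class TestPeakedArrhenius:
    P = PeakedArrheniusParams(kopt=100.0, topt=313.15, ea=60_000.0)

    def test_maximum_identity(self):
        assert peaked_arrhenius(self.P, 313.15) == pytest.approx(100.0, abs=1e-12)

    def test_formula_oracle_at_20C(self):
        tl = 293.15
        x = (tl - 313.15) / (tl * R * 313.15)
        expected = 100.0 * 2e5 * math.exp(60_000 * x) / (
            2e5 - 60_000 * (1 - math.exp(2e5 * x))
        )
        assert peaked_arrhenius(self.P, tl) == pytest.approx(expected, rel=1e-14)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(min_value=263.15, max_value=330.0))
    def test_unimodality(self, tl):
        value = peaked_arrhenius(self.P, tl)
        if abs(tl - self.P.topt) > 1e-6:
            assert value < self.P.kopt
        assert value > 0

    def test_ea_ge_hd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PeakedArrheniusParams(kopt=100, topt=313.15, ea=2.1e5, hd=2e5)

    def test_simple_arrhenius_limit(self):
        # with hd -> 1e7 and a distant topt, ratios match plain Arrhenius < 1e-6
        p = PeakedArrheniusParams(kopt=100.0, topt=353.15, ea=65_000.0, hd=1e7)
        temps = np.array([275.15, 285.15, 295.15, 305.15])
        ratio_peaked = peaked_arrhenius(p, temps) / peaked_arrhenius(p, 298.15)
        ratio_simple = arrhenius_adjust(1.0, 65_000.0, temps - T0_C)
        np.testing.assert_allclose(ratio_peaked, ratio_simple, rtol=1e-6)


class TestElectronTransport:
    def test_zero_light_root(self):
        assert electron_transport(LightParams(q=0.0), 100.0) == pytest.approx(0.0)

    def test_rectangular_hyperbola_degenerate_case(self):
        lp = LightParams(theta=0.0)
        aq = lp.alpha * lp.q
        assert electron_transport(lp, 100.0) == pytest.approx(
            aq * 100.0 / (aq + 100.0), rel=1e-12
        )

    def test_lower_root_oracle(self):
        lp = LightParams()
        aq = lp.alpha * lp.q
        roots = np.roots([lp.theta, -(aq + 100.0), aq * 100.0])
        assert electron_transport(lp, 100.0) == pytest.approx(
            min(roots.real), rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=1.0, max_value=500.0),
        st.floats(min_value=0.0, max_value=3000.0),
    )
    def test_bounds_property(self, jmax, q):
        lp = LightParams(q=q)
        j = electron_transport(lp, jmax)
        assert -1e-9 <= j <= min(lp.alpha * q, jmax) + 1e-9


class TestAssimilation:
    def test_compensation_point_identity(self, tobacco):
        kt = tobacco.at_leaf_temperature(25.0)
        assert fvcb_ac(50.0, kt.gammastar, 210_000, kt, 1.0) == pytest.approx(-1.0)
        assert fvcb_aj(80.0, kt.gammastar, kt.gammastar, 1.0) == pytest.approx(-1.0)

    def test_saturation_limits(self, tobacco):
        kt = tobacco.at_leaf_temperature(25.0)
        assert fvcb_ac(50.0, 1e9, 210_000, kt, 1.0) == pytest.approx(49.0, rel=1e-3)
        assert fvcb_aj(80.0, 1e12, 42.75, 1.0) == pytest.approx(19.0, rel=1e-3)

    def test_formula_oracles(self, tobacco):
        kt = tobacco.at_leaf_temperature(25.0)
        km = kt.kc * (1 + 210_000 / kt.ko)
        assert fvcb_ac(50.0, 300.0, 210_000, kt, 1.0) == pytest.approx(
            50 * (300 - kt.gammastar) / (300 + km) - 1, rel=1e-14
        )
        assert fvcb_aj(80.0, 300.0, 42.75, 1.0) == pytest.approx(
            (80 / 4) * (300 - 42.75) / (300 + 2 * 42.75) - 1, rel=1e-14
        )

    def test_negative_vcmax_rejected(self, tobacco):
        kt = tobacco.at_leaf_temperature(25.0)
        with pytest.raises(InvalidArgumentError):
            fvcb_ac(-5.0, 300.0, 210_000, kt, 1.0)

    def test_anet_limiting_extremes(self, tobacco, light):
        kt = tobacco.at_leaf_temperature(25.0)
        ci = np.array([100.0, 300.0, 800.0, 1500.0])
        a_huge_v, lim_v = fvcb_anet(1e6, 100.0, ci, 210_000, kt, 1.0, light)
        assert set(lim_v) == {"Aj"}
        j = electron_transport(light, 100.0)
        np.testing.assert_allclose(a_huge_v, fvcb_aj(j, ci, kt.gammastar, 1.0))
        a_huge_j, lim_j = fvcb_anet(50.0, 1e6, ci, 210_000, kt, 1.0, light)
        assert set(lim_j) == {"Ac"}
        np.testing.assert_allclose(a_huge_j, fvcb_ac(50.0, ci, 210_000, kt, 1.0))

    def test_crossover_bisection_matches_grid_scan(self, tobacco, light):
        kt = tobacco.at_leaf_temperature(25.0)
        j = electron_transport(light, 100.0)

        def gap(ci):
            return fvcb_ac(50.0, ci, 210_000, kt, 1.0) - fvcb_aj(
                j, ci, kt.gammastar, 1.0
            )

        ci_cross = brentq(gap, 50.0, 2000.0)
        grid = np.arange(50.0, 2000.0, 0.1)
        _, labels = fvcb_anet(50.0, 100.0, grid, 210_000, kt, 1.0, light)
        switch = grid[np.argmax(labels == "Aj")]
        assert abs(ci_cross - switch) <= 0.1 + 1e-9

    def test_monotone_nondecreasing_in_ci(self, tobacco, light):
        kt = tobacco.at_leaf_temperature(25.0)
        grid = np.linspace(kt.gammastar, 2000.0, 500)
        anet, _ = fvcb_anet(80.0, 140.0, grid, 210_000, kt, 1.0, light)
        assert np.all(np.diff(anet) >= -1e-12)


class TestQuadratic:
    def test_closed_form_optimum(self):
        topt, aopt = topt_from_quadratic(QuadraticParams(-0.02, 1.0, 2.0))
        assert topt == pytest.approx(25.0)
        assert aopt == pytest.approx(14.5)

    def test_no_optimum_error(self):
        with pytest.raises(NoOptimumError):
            topt_from_quadratic(QuadraticParams(0.01, 1.0, 0.0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=-0.5, max_value=-0.001),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-10, max_value=30),
    )
    def test_maximum_property(self, a, b, c):
        qp = QuadraticParams(a, b, c)
        topt, aopt = topt_from_quadratic(qp)
        for delta in (-0.1, 0.1):
            assert quadratic_agrowth(qp, topt + delta) < aopt


class TestKineticsPresets:
    def test_presets_load_and_validate(self):
        assert set(available_kinetics()) == {"tobacco", "rice", "potato"}
        for name in available_kinetics():
            kin = load_kinetics(name)
            assert kin.kc25 > 0 and kin.ko25 > kin.kc25 and kin.gammastar25 > 0

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="tobacco"):
            load_kinetics("wheat")

    def test_invalid_constants_rejected(self):
        with pytest.raises(InvalidArgumentError):
            KineticsSet(
                name="bad", kc25=-1, ko25=1, gammastar25=1, rl25=None,
                ea_kc=0, ea_ko=0, ea_gammastar=0, ea_rl=0,
            )
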