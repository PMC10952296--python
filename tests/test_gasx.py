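import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spac.gasx import (
    GasExchangeParams,
    calibrate_fl,
    farquhar_anpot,
    fl_factor,
    fs_factor,
    gs_leuning,
    gs_tuzet,
    leaf_kinetics,
    solve_ci,
    transp_flux,
)


class TestStressFactors:
    def test_fs_unstressed_and_example(self):
        assert fs_factor(0.0, 2.0, 1.0) == 1.0
        assert fs_factor(-1.0, 1.0, 1.0) == pytest.approx(math.exp(-1.0))

    def test_fs_monotone(self):
        for p, q in [(1.0, 1.0), (2.0, 0.5), (3.0, 2.0)]:
            assert fs_factor(-2.0, p, q) < fs_factor(-1.0, p, q)

    def test_fl_no_drop(self):
        assert fl_factor(-0.4, -0.4, 0.7, 1.2) == 1.0

    def test_fl_default_calibration_anchors(self, gp):
        # shipped defaults: 1.0 MPa drop halves gs, 0.2 MPa drop cuts 10%
        assert fl_factor(0.0, -1.0, gp.al, gp.gl) == pytest.approx(0.5, abs=1e-12)
        assert fl_factor(0.0, -0.2, gp.al, gp.gl) == pytest.approx(0.9, abs=1e-12)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_factors_in_unit_interval(self, drop, q):
        assert 0.0 < fl_factor(0.0, -drop, q, 1.3) <= 1.0
        assert 0.0 < fs_factor(-drop, 2.0, q) <= 1.0


class TestCalibrateFl:
    def test_closed_form(self):
        al, gl = calibrate_fl((1.0, 0.5), (0.2, 0.1))
        assert al == pytest.approx(math.log(2.0), rel=1e-12)
        gl_expected = math.log(math.log(0.9) / math.log(0.5)) / math.log(0.2)
        assert gl == pytest.approx(gl_expected, rel=1e-12)

    def test_round_trip_at_anchors(self):
        anchors = [(0.7, 0.35), (0.15, 0.06)]
        al, gl = calibrate_fl(*anchors)
        for d, r in anchors:
            assert 1.0 - fl_factor(0.0, -d, al, gl) == pytest.approx(r, rel=1e-10)

    def test_anchor_order_symmetric(self):
        assert calibrate_fl((1.0, 0.5), (0.2, 0.1)) == pytest.approx(
            calibrate_fl((0.2, 0.1), (1.0, 0.5))
        )

    def test_inconsistent_anchors_rejected(self):
        with pytest.raises(ValueError, match="monotone|inconsistent"):
            calibrate_fl((1.0, 0.1), (0.2, 0.5))
        with pytest.raises(ValueError):
            calibrate_fl((1.0, 0.5), (1.0, 0.1))


class TestFarquhar:
    def test_dark_respiration(self, gp):
        # at 25 degC every temperature response is at its base value
        assert farquhar_anpot(25.0, 0.0, 280.0, gp) == pytest.approx(-gp.Rd25, rel=1e-9)

    def test_compensation_point(self, gp):
        kin = leaf_kinetics(25.0, 2000.0, gp)
        assert farquhar_anpot(25.0, 2000.0, kin.gamma, gp) == pytest.approx(-kin.rd, abs=1e-9)

    def test_direct_evaluation_oracle(self, gp):
        # Vcmax25=60, ci=280, Ta=25, saturating light: single-equation evaluation
        ci = 280.0
        kc, ko, gamma = 404.9, 278.4, gp.Gamma25
        ac = 60.0 * (ci - gamma) / (ci + kc * (1.0 + 210.0 / ko))
        i2 = 0.28 * 2000.0
        b = i2 + gp.Jmax25
        j = (b - math.sqrt(b * b - 4 * 0.9 * i2 * gp.Jmax25)) / (2 * 0.9)
        aj = 0.25 * j * (ci - gamma) / (ci + 2 * gamma)
        expected = min(ac, aj) - gp.Rd25
        assert farquhar_anpot(25.0, 2000.0, ci, gp) == pytest.approx(expected, rel=1e-9)

    def test_invalid_ci(self, gp):
        with pytest.raises(ValueError):
            farquhar_anpot(25.0, 500.0, -1.0, gp)


class TestStomatalModels:
    def test_leuning_floor_at_zero_assimilation(self, gp):
        assert gs_leuning(0.0, 1.0, 300.0, 42.75, 1000.0, gp) == gp.g0
        assert gs_leuning(-1.0, 1.0, 300.0, 42.75, 1000.0, gp) == gp.g0

    def test_leuning_vpd_term_halves(self, gp):
        g_at_0 = gs_leuning(10.0, 1.0, 300.0, 42.75, 0.0, gp) - gp.g0
        g_at_d0 = gs_leuning(10.0, 1.0, 300.0, 42.75, gp.D0, gp) - gp.g0
        assert g_at_d0 == pytest.approx(0.5 * g_at_0, rel=1e-12)

    def test_leuning_linear_in_fs(self, gp):
        full = gs_leuning(10.0, 1.0, 300.0, 42.75, 500.0, gp) - gp.g0
        half = gs_leuning(10.0, 0.5, 300.0, 42.75, 500.0, gp) - gp.g0
        assert half == pytest.approx(0.5 * full, rel=1e-12)

    def test_tuzet_closed_when_fl_zero(self, gp):
        assert gs_tuzet(10.0, 1.0, 0.0, 300.0, 42.75, gp, "tuzet") == gp.g0

    def test_tuzet_matches_leuning_at_zero_vpd(self, gp):
        # same a1: full Tuzet with fl=1 equals Leuning with D=0 structurally
        a = gs_tuzet(10.0, 0.8, 1.0, 300.0, 42.75, gp, "tuzet")
        b = gs_leuning(10.0, 0.8, 300.0, 42.75, 0.0, gp)
        assert a == pytest.approx(b, rel=1e-12)

    def test_tuzet_halved_by_anchor_drop(self, gp):
        fl = fl_factor(0.0, -1.0, gp.al, gp.gl)
        full = gs_tuzet(10.0, 1.0, 1.0, 300.0, 42.75, gp, "tuzet") - gp.g0
        damped = gs_tuzet(10.0, 1.0, fl, 300.0, 42.75, gp, "tuzet") - gp.g0
        assert damped == pytest.approx(0.5 * full, rel=1e-12)

    def test_unknown_mode_rejected(self, gp):
        with pytest.raises(ValueError, match="unknown stomatal mode"):
            gs_tuzet(10.0, 1.0, 1.0, 300.0, 42.75, gp, "medlyn")

    @given(st.floats(0.0, 4.0), st.floats(0.0, 3.9))
    @settings(max_examples=50, deadline=None)
    def test_gs_non_increasing_in_potential_drop(self, drop_hi, frac):
        gp = GasExchangeParams()
        drop_lo = frac * drop_hi / 4.0
        fl_hi = fl_factor(0.0, -drop_hi, gp.al, gp.gl)
        fl_lo = fl_factor(0.0, -drop_lo, gp.al, gp.gl)
        hi = gs_tuzet(10.0, 1.0, fl_hi, 300.0, 42.75, gp, "tuzet")
        lo = gs_tuzet(10.0, 1.0, fl_lo, 300.0, 42.75, gp, "tuzet")
        assert hi <= lo + 1e-15

    @given(st.floats(0.0, 5000.0), st.floats(0.0, 5000.0))
    @settings(max_examples=50, deadline=None)
    def test_leuning_non_increasing_in_vpd(self, d1, d2):
        gp = GasExchangeParams()
        lo, hi = sorted((d1, d2))
        assert gs_leuning(10.0, 1.0, 300.0, 42.75, hi, gp) <= gs_leuning(
            10.0, 1.0, 300.0, 42.75, lo, gp
        ) + 1e-15


class TestCiCoupling:
    def test_large_supply_pushes_ci_to_ca(self):
        gp = GasExchangeParams(a1=1e6)
        sol = solve_ci(25.0, 1500.0, 1000.0, 400.0, gp, model="leuning")
        assert sol.ci > 0.995 * 400.0

    def test_tiny_supply_pulls_ci_toward_gamma(self):
        gp = GasExchangeParams(a1=0.0, g0=1e-5)
        sol = solve_ci(25.0, 1500.0, 1000.0, 400.0, gp, model="leuning")
        kin = leaf_kinetics(25.0, 1500.0, gp)
        assert sol.ci < kin.gamma + 25.0

    def test_dark_ci_exceeds_ca(self, gp):
        sol = solve_ci(20.0, 0.0, 500.0, 400.0, gp, model="tuzet")
        assert sol.ci >= 400.0
        assert sol.an < 0.0

    def test_residual_small_and_matches_grid_search(self, gp):
        sol = solve_ci(28.0, 1200.0, 2000.0, 400.0, gp, model="leuning", fs=0.8)
        # brute-force grid at 1e-4 resolution around the root
        ci_grid = np.arange(50.0, 400.0, 1e-4)
        best, best_r = None, np.inf
        for ci in ci_grid[:: len(ci_grid) // 4000]:  # coarse pass
            an = farquhar_anpot(28.0, 1200.0, ci, gp)
            from spac.gasx import gs_leuning as gl

            kin = leaf_kinetics(28.0, 1200.0, gp)
            gs = gl(an, 0.8, ci, kin.gamma, 2000.0, gp)
            r = abs(gs * (400.0 - ci) - 0.8 * an)
            if r < best_r:
                best, best_r = ci, r
        fine = np.arange(best - 0.1, best + 0.1, 1e-4)
        kin = leaf_kinetics(28.0, 1200.0, gp)
        for ci in fine:
            an = farquhar_anpot(28.0, 1200.0, ci, gp)
            gs = gs_leuning(an, 0.8, ci, kin.gamma, 2000.0, gp)
            r = abs(gs * (400.0 - ci) - 0.8 * an)
            if r < best_r:
                best, best_r = ci, r
        assert sol.ci == pytest.approx(best, abs=2e-4)

    def test_realized_equals_fs_times_potential(self, gp):
        sol = solve_ci(25.0, 900.0, 1500.0, 400.0, gp, model="tuzet", fs=0.6, fl=0.7)
        assert sol.an == pytest.approx(0.6 * sol.anpot, rel=1e-12)


class TestTranspiration:
    def test_zero_vpd(self):
        assert transp_flux(0.2, 0.0, 101325.0, 3.0) == 0.0

    def test_unit_conversion_oracle(self):
        expected = 1.6 * 0.2 * (1000.0 / 101325.0) * 0.018 / 1000.0
        got = transp_flux(0.2, 1000.0, 101325.0, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(5.7e-8, rel=0.01)

    def test_linear_in_lai(self):
        assert transp_flux(0.2, 800.0, 101325.0, 6.0) == pytest.approx(
            2 * transp_flux(0.2, 800.0, 101325.0, 3.0)
        )
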