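import math

import numpy as np
import pytest
from scipy.optimize import brentq

import haksym as hx
from haksym.exceptions import InvalidInputError

PH45 = 10.0 ** -4.5


def _current_vs_K(params, V, H_out, K, K_in=0.0, H_in=0.0):
    cond = hx.Conditions(V_mV=V, K_out_M=K, H_out_M=H_out,
                         K_in_M=K_in, H_in_M=H_in)
    return hx.steady_state_current(params, cond).I


def _current_vs_H(params, V, K_out, H, K_in=0.0, H_in=0.0):
    cond = hx.Conditions(V_mV=V, K_out_M=K_out, H_out_M=H,
                         K_in_M=K_in, H_in_M=H_in)
    return hx.steady_state_current(params, cond).I


class TestClosedFormReductions:
    def test_kk_matches_numeric_half_saturation(self, params):
        """K_K equals the numerically located half-saturation of |I|([K+]o)
        from the full closed form, pure influx regime."""
        red = hx.km_imax_potassium(params, -120.0, PH45, K_in_M=0.0, H_in_M=0.0)
        I_sat = abs(_current_vs_K(params, -120.0, PH45, 1e6 * red.K_m_M))
        half = brentq(
            lambda K: abs(_current_vs_K(params, -120.0, PH45, K)) - I_sat / 2,
            1e-12, 1.0, rtol=1e-14)
        assert half == pytest.approx(red.K_m_M, rel=1e-3)

    def test_kh_matches_numeric_half_saturation(self, params):
        red = hx.km_proton(params, -120.0, 200e-6, K_in_M=0.0, H_in_M=0.0)
        I_sat = abs(_current_vs_H(params, -120.0, 200e-6, 1e6 * red.K_m_M))
        half = brentq(
            lambda H: abs(_current_vs_H(params, -120.0, 200e-6, H)) - I_sat / 2,
            1e-15, 1.0, rtol=1e-14)
        assert half == pytest.approx(red.K_m_M, rel=1e-3)

    def test_saturating_current_limit(self, params):
        """|I|([K+]o) approaches I_Kmax; at 1e4 K_K it is within 0.1 %."""
        red = hx.km_imax_potassium(params, -120.0, PH45, K_in_M=0.0, H_in_M=0.0)
        I = _current_vs_K(params, -120.0, PH45, 1e4 * red.K_m_M)
        assert I == pytest.approx(red.I_max_A, rel=1e-3)
        assert red.I_max_A < 0  # inward branch

    def test_full_curve_is_exactly_michaelis_menten(self, params):
        """With internal products zero, a noiseless 50-point scan of the full
        model refits to the closed-form (I_Kmax, K_K) to 1e-6 relative."""
        red = hx.km_imax_potassium(params, -120.0, PH45, K_in_M=0.0, H_in_M=0.0)
        K = np.geomspace(red.K_m_M / 100, red.K_m_M * 100, 50)
        resp = np.abs([_current_vs_K(params, -120.0, PH45, k) for k in K])
        fit = hx.fit_michaelis_menten(hx.DoseResponseDataset(K, resp))
        assert fit.K_m == pytest.approx(red.K_m_M, rel=1e-6)
        assert fit.I_max == pytest.approx(abs(red.I_max_A), rel=1e-6)

    def test_kk_scales_exactly_with_binding_constant(self, params):
        """K_K(k23_0 / f) = f * K_K exactly in the pure influx regime, and
        within 1 % at default internal concentrations."""
        f = 1000.0
        scaled = hx.apply_mutant_scaling(params, f, "k23_down")
        kk0 = hx.km_imax_potassium(params, -120.0, PH45, 0.0, 0.0).K_m_M
        kk1 = hx.km_imax_potassium(scaled, -120.0, PH45, 0.0, 0.0).K_m_M
        assert kk1 == pytest.approx(f * kk0, rel=1e-12)
        kk0d = hx.km_imax_potassium(params, -120.0, PH45).K_m_M
        kk1d = hx.km_imax_potassium(scaled, -120.0, PH45).K_m_M
        assert kk1d == pytest.approx(f * kk0d, rel=1e-2)

    @pytest.mark.parametrize("f", [3.0, 10.0, 250.0])
    def test_kk_homogeneity_in_k23(self, params, f):
        scaled = hx.apply_mutant_scaling(params, f, "k23_down")
        kk0 = hx.km_imax_potassium(params, -120.0, PH45, 0.0, 0.0).K_m_M
        kk1 = hx.km_imax_potassium(scaled, -120.0, PH45, 0.0, 0.0).K_m_M
        assert kk1 == pytest.approx(f * kk0, rel=1e-12)

    def test_invalid_cosubstrate_rejected(self, params):
        with pytest.raises(InvalidInputError):
            hx.km_imax_potassium(params, -120.0, 0.0)
        with pytest.raises(InvalidInputError):
            hx.km_proton(params, -120.0, 0.0)


class TestVoltageDependence:
    def test_proton_affinity_shifts_with_hyperpolarisation(self, params):
        """K_H falls monotonically from -60 to -150 mV (by more than 5x)
        while K_K stays within a factor 2 over -60..-140 mV."""
        grid = np.arange(-150.0, -57.5, 2.5)
        df = hx.voltage_scan(params, grid, H_out_M=PH45, K_out_M=200e-6)
        kh = df["K_H_M"].to_numpy()
        assert (np.diff(kh) > 0).all()  # decreasing toward negative V
        assert kh[-1] / kh[0] > 5.0
        kk = df[(df.V_mV >= -140) & (df.V_mV <= -60)]["K_K_M"]
        assert kk.max() / kk.min() < 2.0

    def test_maximal_current_grows_with_hyperpolarisation(self, params):
        df = hx.voltage_scan(params, np.arange(-140.0, -35.0, 5.0),
                             H_out_M=PH45, K_out_M=200e-6)
        mags = df["I_Kmax_A"].abs().to_numpy()
        assert (np.diff(mags) < 0).all()  # grows toward negative V
        # depolarisation to -40 mV nearly abolishes the current
        assert mags[-1] < 0.05 * mags[0]

    def test_scan_single_voltage_matches_direct_calls(self, params):
        df = hx.voltage_scan(params, [-120.0], H_out_M=PH45, K_out_M=200e-6)
        k = hx.km_imax_potassium(params, -120.0, PH45)
        h = hx.km_proton(params, -120.0, 200e-6)
        assert df.loc[0, "K_K_M"] == k.K_m_M
        assert df.loc[0, "I_Kmax_A"] == k.I_max_A
        assert df.loc[0, "K_H_M"] == h.K_m_M
        assert list(df.columns) == ["V_mV", "K_K_M", "I_Kmax_A", "K_H_M"]

    def test_empty_grid_rejected(self, params):
        with pytest.raises(InvalidInputError):
            hx.voltage_scan(params, [], H_out_M=PH45, K_out_M=200e-6)


class TestMutantScaling:
    def test_factor_one_is_identity(self, params):
        assert hx.apply_mutant_scaling(params, 1.0, "k23_down") == params
        assert hx.apply_mutant_scaling(params, 1.0, "k32_up") == params

    def test_detailed_balance_preserved(self, params):
        m = hx.apply_mutant_scaling(params, 1000.0, "k23_down")
        assert m.cycle_product_forward == pytest.approx(
            m.cycle_product_reverse, rel=1e-10)

    def test_weak_potassium_site_raises_proton_affinity(self, params):
        """Dividing k23_0 by 1000 lowers K_H (the coupled-affinity shift)."""
        m = hx.apply_mutant_scaling(params, 1000.0, "k23_down")
        kh_wt = hx.km_proton(params, -120.0, 200e-6).K_m_M
        kh_mut = hx.km_proton(m, -120.0, 200e-6).K_m_M
        assert kh_mut < kh_wt

    def test_binding_down_equivalent_to_debinding_up(self, params):
        """k23_0/1000 and k32*1000 produce current-[K+]o curves at -120 mV
        agreeing within 5 % of the curve maximum."""
        a = hx.apply_mutant_scaling(params, 1000.0, "k23_down")
        b = hx.apply_mutant_scaling(params, 1000.0, "k32_up")
        K = np.geomspace(1e-6, 1.0, 60)
        Ia = np.array([hx.steady_state_current(
            a, hx.Conditions(V_mV=-120, K_out_M=k, H_out_M=PH45)).I for k in K])
        Ib = np.array([hx.steady_state_current(
            b, hx.Conditions(V_mV=-120, K_out_M=k, H_out_M=PH45)).I for k in K])
        assert np.max(np.abs(Ia - Ib)) < 0.05 * np.max(np.abs(Ia))

    def test_invalid_scaling_rejected(self, params):
        with pytest.raises(InvalidInputError):
            hx.apply_mutant_scaling(params, -2.0)
        with pytest.raises(InvalidInputError):
            hx.apply_mutant_scaling(params, 10.0, mode="bogus")


class TestCalibration:
    def test_round_trip_hits_published_affinities(self, params):
        kk = hx.km_imax_potassium(params, -120.0, PH45).K_m_M
        kh = hx.km_proton(params, -120.0, 200e-6).K_m_M
        assert kk == pytest.approx(23.56e-6, rel=0.05)
        assert kh == pytest.approx(4.81e-6, rel=0.05)
        imax = abs(hx.km_imax_potassium(params, -140.0, PH45).I_max_A)
        assert imax == pytest.approx(417e-9, rel=0.05)

    def test_calibration_is_deterministic(self, params):
        again, report = hx.calibrate_default_params(seed=0)
        assert again == params
        assert max(abs(r) for r in report["log_residuals"]) < 1e-6

    def test_missing_core_target_rejected(self):
        only_kk = (hx.CalibrationTarget("K_K", 23.56e-6, -120.0,
                                        H_out_M=PH45),)
        with pytest.raises(InvalidInputError):
            hx.calibrate_default_params(targets=only_kk)
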