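import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haksym as hx
from haksym.exceptions import (FeatureExtractionError, InsufficientDataError,
                               InvalidInputError, UndefinedMetricError)

#: the eight test concentrations of the K+ dose-response protocol (M)
K_CONCS = np.array([10, 20, 50, 100, 200, 500, 1000, 2000]) * 1e-6
#: proton concentrations of the pH 8.5 .. 4.0 protocol (M)
H_CONCS = 10.0 ** -np.array([8.5, 7.5, 6.5, 6.0, 5.5, 5.0, 4.5, 4.0])


class TestMichaelisMentenFit:
    def test_noiseless_round_trip(self):
        truth = dict(I_max=1.01e-6, K_m=23.56e-6)
        resp = hx.michaelis_menten(K_CONCS, **truth)
        fit = hx.fit_michaelis_menten(hx.DoseResponseDataset(K_CONCS, resp))
        assert fit.K_m == pytest.approx(truth["K_m"], rel=1e-6)
        assert fit.I_max == pytest.approx(truth["I_max"], rel=1e-6)
        # half-saturation property of the fitted curve
        assert hx.michaelis_menten(fit.K_m, fit.I_max, fit.K_m) == \
            pytest.approx(fit.I_max / 2, rel=1e-12)
        assert fit.converged and fit.n_points == 8

    def test_noisy_replicates_recover_km(self):
        ds = hx.generate_dose_response((1.01e-6, 23.56e-6), K_CONCS,
                                       hx.NoiseModel(seed=42, cv=0.05),
                                       n_replicates=5)
        fit = hx.fit_michaelis_menten(ds)
        assert fit.K_m == pytest.approx(23.56e-6, rel=0.10)
        assert fit.stderr["K_m"] > 0

    def test_insufficient_points_or_span(self):
        with pytest.raises(InsufficientDataError):
            hx.fit_michaelis_menten(hx.DoseResponseDataset(
                np.array([1e-5, 2e-5]), np.array([1.0, 2.0])))
        narrow = np.array([1e-5, 2e-5, 5e-5])
        with pytest.raises(InsufficientDataError):
            hx.fit_michaelis_menten(hx.DoseResponseDataset(
                narrow, hx.michaelis_menten(narrow, 1.0, 2e-5)))


class TestHillFit:
    @pytest.mark.parametrize("h, K_m", [(1.67, 4.81e-6), (2.17, 0.36e-6)])
    def test_noiseless_round_trip(self, h, K_m):
        resp = hx.hill(H_CONCS, 1.0, K_m, h)
        fit = hx.fit_hill(hx.DoseResponseDataset(H_CONCS, resp))
        assert fit.h == pytest.approx(h, rel=1e-4)
        assert fit.K_m == pytest.approx(K_m, rel=1e-4)

    def test_reduces_to_michaelis_menten_when_h_is_one(self):
        resp = hx.michaelis_menten(K_CONCS, 1.0, 23.56e-6)
        ds = hx.DoseResponseDataset(K_CONCS, resp)
        mm = hx.fit_michaelis_menten(ds)
        hill = hx.fit_hill(ds)
        assert hill.h == pytest.approx(1.0, rel=1e-6)
        assert hill.K_m == pytest.approx(mm.K_m, rel=1e-6)

    def test_needs_four_points(self):
        c = np.array([1e-6, 1e-5, 1e-4])
        with pytest.raises(InsufficientDataError):
            hx.fit_hill(hx.DoseResponseDataset(c, hx.hill(c, 1.0, 1e-5, 1.5)))


class TestSteadyStateBellFit:
    def test_noiseless_round_trip(self):
        truth = dict(I_max=1.01e-6, K_m=28.3e-6, I_s=124e-9)
        resp = hx.steady_state_bell(K_CONCS, **truth)
        fit = hx.fit_steady_state_bell(hx.DoseResponseDataset(K_CONCS, resp),
                                       K_m_fixed=28.3e-6)
        assert fit.I_max == pytest.approx(truth["I_max"], rel=1e-6)
        assert fit.I_s == pytest.approx(truth["I_s"], rel=1e-6)
        assert fit.K_m_fixed == 28.3e-6

    def test_curve_limits_equal_offset(self):
        lo = hx.steady_state_bell(1e-15, 1.01e-6, 28.3e-6, 124e-9)
        hi = hx.steady_state_bell(1e6, 1.01e-6, 28.3e-6, 124e-9)
        assert lo == pytest.approx(124e-9, rel=1e-6)
        assert hi == pytest.approx(124e-9, rel=1e-6)

    def test_fitted_curve_peaks_at_fixed_km(self):
        resp = hx.steady_state_bell(K_CONCS, 1.01e-6, 28.3e-6, 124e-9)
        fit = hx.fit_steady_state_bell(hx.DoseResponseDataset(K_CONCS, resp),
                                       K_m_fixed=28.3e-6)
        grid = np.geomspace(1e-7, 1e-1, 10001)
        curve = hx.steady_state_bell(grid, fit.I_max, fit.K_m_fixed, fit.I_s)
        assert grid[np.argmax(curve)] == pytest.approx(28.3e-6, rel=2e-3)


class TestBellArgmax:
    @pytest.mark.parametrize("K_m", [28.3e-6, 12.92e-3, 1.0])
    def test_argmax_equals_km_by_grid_oracle(self, K_m):
        grid = np.geomspace(K_m * 1e-3, K_m * 1e3, 10000)
        curve = hx.steady_state_bell(grid, 1.0, K_m, 0.2)
        oracle = grid[np.argmax(curve)]
        assert hx.bell_argmax(K_m) == K_m
        assert oracle == pytest.approx(K_m, rel=2e-3)

    def test_argmax_invariant_to_scale_and_offset(self):
        grid = np.geomspace(1e-8, 1e-2, 20001)
        for I_max, I_s in [(1.0, 0.0), (5.0, 2.0), (0.1, -0.05)]:
            curve = hx.steady_state_bell(grid, I_max, 28.3e-6, I_s)
            assert grid[np.argmax(curve)] == pytest.approx(28.3e-6, rel=1e-3)

    def test_invalid_km(self):
        with pytest.raises(InvalidInputError):
            hx.bell_argmax(0.0)


class TestPercentInactivation:
    def test_boundary_values(self):
        assert hx.percent_inactivation(1.0, 1.0) == 0.0
        assert hx.percent_inactivation(1.0, 0.0) == 100.0

    def test_undefined_for_nonpositive_peak(self):
        with pytest.raises(UndefinedMetricError):
            hx.percent_inactivation(0.0, 0.0)
        with pytest.raises(UndefinedMetricError):
            hx.percent_inactivation(1.0, -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(peak=st.floats(1e-12, 1e-3), frac=st.floats(0.0, 1.0),
           scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, peak, frac, scale):
        ss = frac * peak
        a = hx.percent_inactivation(peak, ss)
        b = hx.percent_inactivation(scale * peak, scale * ss)
        assert a == pytest.approx(b, abs=1e-9)
        assert 0.0 <= a <= 100.0


class TestTraceFeatures:
    def test_flat_zero_trace(self):
        protocol = hx.step_protocol(2e-3, baseline_s=5.0, step_s=20.0,
                                    washout_s=0.0)
        t = np.arange(0, 25.0, 0.1)
        trace = hx.TEVCTrace(time_s=t, current_A=np.zeros_like(t),
                             protocol=protocol)
        ft = hx.extract_trace_features(trace, protocol)
        assert ft.dI_peak_A == 0.0
        assert ft.dI_ss_A == 0.0
        assert math.isnan(ft.pct_inactivation)

    def test_round_trip_against_generator_truth(self):
        protocol = hx.step_protocol(200e-6)
        trace = hx.simulate_tevc_trace(hx.WT_PRESET, protocol,
                                       hx.NoiseModel(seed=5))
        ft = hx.extract_trace_features(trace, protocol)
        truth = trace.truth["segments"][1]
        assert ft.dI_peak_A == pytest.approx(truth["dI_peak_achieved_A"],
                                             rel=0.01)
        assert ft.dI_ss_A == pytest.approx(truth["dI_ss_achieved_A"],
                                           rel=0.01)

    def test_low_potassium_does_not_inactivate(self):
        protocol = hx.step_protocol(10e-6)
        trace = hx.simulate_tevc_trace(hx.WT_PRESET, protocol,
                                       hx.NoiseModel(seed=6))
        ft = hx.extract_trace_features(trace, protocol)
        assert ft.pct_inactivation < 5.0

    def test_high_potassium_inactivates(self):
        protocol = hx.step_protocol(2e-3)
        trace = hx.simulate_tevc_trace(hx.WT_PRESET, protocol,
                                       hx.NoiseModel(seed=6))
        ft = hx.extract_trace_features(trace, protocol)
        assert ft.pct_inactivation > 90.0
        assert 1.0 < ft.t_peak_s < 4.0  # peak after about 2 s

    def test_missing_baseline_rejected(self):
        protocol = hx.step_protocol(2e-3, baseline_s=5.0)
        t = np.arange(6.0, 30.0, 0.1)  # starts after the baseline window
        trace = hx.TEVCTrace(time_s=t, current_A=np.zeros_like(t),
                             protocol=protocol)
        with pytest.raises(FeatureExtractionError):
            hx.extract_trace_features(trace, protocol)
        with pytest.raises(FeatureExtractionError):
            hx.extract_trace_features(trace, protocol, step_index=0)


class TestDatasetInvariants:
    def test_rejects_unsorted_or_negative(self):
        with pytest.raises(InvalidInputError):
            hx.DoseResponseDataset(np.array([2e-5, 1e-5, 3e-5]),
                                   np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InvalidInputError):
            hx.DoseResponseDataset(np.array([1e-5, 2e-5]),
                                   np.array([1.0, -2.0]))
        with pytest.raises(InvalidInputError):
            hx.DoseResponseDataset(np.array([1e-5, 1e-5]),
                                   np.array([1.0, 2.0]))

    def test_replicates_may_repeat_concentrations(self):
        ds = hx.DoseResponseDataset(np.array([1e-5, 2e-5, 1e-5, 2e-5]),
                                    np.array([1.0, 2.0, 1.1, 2.1]),
                                    replicate=np.array([0, 0, 1, 1]))
        assert ds.n_replicates == 2
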