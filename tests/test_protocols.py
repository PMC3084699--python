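"""Clamp engine, trace-analysis operations and scenario presets."""

import numpy as np
import pytest

from usmcsim.io import FixtureSpec, make_fixture
from usmcsim.model import StimulusProtocol
from usmcsim.protocols import (FitError, NoThreshold, VoltageClampProtocol,
                               ap_metrics, classify_ap, count_spikes,
                               fit_exponential_decay, peak_iv,
                               run_voltage_clamp, threshold_search,
                               time_to_peak)


class TestClampEngine:
    def test_step_to_reversal_gives_zero_steady_current(self, params):
        from usmcsim import _kernels as K
        e_k = float(K.derived_from_params(params.vector)[K.D_E_K])
        proto = VoltageClampProtocol(holding=-80.0, steps=(e_k,),
                                     step_duration=400.0, hold_duration=200.0,
                                     isolate=("ik2",), clamp_ca=True)
        res = run_voltage_clamp(proto, params)
        t, i = res.component_trace(0)
        assert np.abs(i[t >= res.step_start]).max() < 1e-10

    def test_pre_equilibration_continuity(self, params):
        # after the settling period the pre-step current must be flat
        proto = VoltageClampProtocol(holding=-80.0, steps=(-20.0,),
                                     step_duration=100.0,
                                     hold_duration=500.0,
                                     isolate=("ical",), clamp_ca=True)
        res = run_voltage_clamp(proto, params)
        t, i = res.component_trace(0)
        pre = i[(t > 400.0) & (t < proto.hold_duration)]
        assert np.abs(np.diff(pre)).max() < 1e-9

    def test_unknown_component_rejected(self):
        with pytest.raises(KeyError):
            proto = VoltageClampProtocol(steps=(0.0,), isolate=("nope",))
            run_voltage_clamp(proto)

    def test_ina_clamp_peaks_decays_and_iv_shape(self, params):
        steps = tuple(np.arange(-50.0, 41.0, 10.0))
        proto = VoltageClampProtocol(holding=-80.0, steps=steps,
                                     step_duration=100.0, hold_duration=300.0,
                                     isolate=("ina",), clamp_ca=True)
        res = run_voltage_clamp(proto, params)
        # each trace peaks inward then decays toward zero within the step
        t, i = res.component_trace(3)        # -20 mV
        win = (t >= res.step_start) & (t < res.step_end)
        seg = i[win]
        assert seg.min() < -0.01
        assert abs(seg[-1]) < 0.1 * abs(seg.min())
        # normalized peak I-V has a single inward minimum between
        # activation threshold and reversal
        curve = peak_iv(res, mode="peak")
        k = int(np.argmin(curve.values))
        assert 0 < k < len(steps) - 1
        assert curve.values[k] < 0
        left = curve.values[:k + 1]
        right = curve.values[k:]
        assert np.all(np.diff(left) <= 1e-12)
        assert np.all(np.diff(right) >= -1e-12)

    def test_ik1_availability_depends_on_holding(self, params):
        peaks = {}
        for hold in (-80.0, -40.0):
            proto = VoltageClampProtocol(holding=hold, steps=(0.0,),
                                         step_duration=2000.0,
                                         hold_duration=400.0,
                                         isolate=("ik1",), clamp_ca=True,
                                         dt=0.05)
            peaks[hold] = peak_iv(run_voltage_clamp(proto, params)).values[0]
        assert peaks[-40.0] < 0.2 * peaks[-80.0]

    def test_iclca_two_step_tail_currents(self, params):
        # conditioning depolarization loads Ca via the L-type current;
        # hyperpolarized test steps then show inward Cl tail current
        proto = VoltageClampProtocol(
            holding=-50.0, conditioning=(10.0, 1000.0),
            steps=(-100.0, -80.0, 0.0), step_duration=1500.0,
            hold_duration=300.0, isolate=("ical", "iclca"))
        res = run_voltage_clamp(proto, params)
        curve = peak_iv(res, mode="peak", component="iclca")
        assert curve.values[0] < 0          # inward tail at -100 mV
        assert curve.values[0] < curve.values[2]


class TestIVExtraction:
    def _fixture_result(self):
        """Constructed clamp-like traces with known extrema."""
        t = np.arange(0.0, 200.0, 0.5)
        steps = np.array([-40.0, -20.0, 0.0])
        peaks = np.array([-1.0, -3.0, -2.0])

        class FakeResult:
            step_start, step_end = 50.0, 150.0
            def __init__(self):
                self.steps = steps
            def component_trace(self, k, component=None):
                i = np.zeros_like(t)
                win = (t >= 50.0) & (t < 150.0)
                tt = t[win] - 50.0
                i[win] = peaks[k] * (tt / 5.0) * np.exp(1 - tt / 5.0)
                i[t >= 150.0] = 0.5 * peaks[k] * np.exp(
                    -(t[t >= 150.0] - 150.0) / 10.0)
                return t, i
        return FakeResult(), peaks

    def test_peak_extraction_exact(self):
        res, peaks = self._fixture_result()
        curve = peak_iv(res, mode="peak")
        assert np.allclose(curve.values, peaks, rtol=1e-12)

    def test_normalization_reference_equals_one(self):
        res, peaks = self._fixture_result()
        curve = peak_iv(res, mode="peak", normalization_ref=-20.0)
        assert abs(curve.values[1]) == pytest.approx(1.0)

    def test_end_mode_near_zero_for_inactivating(self):
        res, _ = self._fixture_result()
        curve = peak_iv(res, mode="end")
        assert np.all(np.abs(curve.values) < 1e-6)

    def test_tail_mode(self):
        res, peaks = self._fixture_result()
        curve = peak_iv(res, mode="tail")
        assert np.allclose(curve.values, 0.5 * peaks, rtol=1e-6)


class TestExponentialFit:
    def test_monoexponential_within_one_percent(self):
        t, y = make_fixture(FixtureSpec("monoexp", (2.0, 40.0), t_end=400.0))
        amps, taus = fit_exponential_decay(t, y, 1)
        assert taus[0] == pytest.approx(40.0, rel=0.01)
        assert amps[0] == pytest.approx(2.0, rel=0.01)

    def test_biexponential_within_five_percent(self):
        t, y = make_fixture(
            FixtureSpec("biexp", (3.0, 30.0, 1.0, 300.0), t_end=2000.0))
        amps, taus = fit_exponential_decay(t, y, 2)
        assert taus[0] == pytest.approx(30.0, rel=0.05)
        assert taus[1] == pytest.approx(300.0, rel=0.05)

    def test_negative_going_trace(self):
        t, y = make_fixture(FixtureSpec("monoexp", (2.0, 25.0), t_end=250.0))
        amps, taus = fit_exponential_decay(t, -y, 1)
        assert taus[0] == pytest.approx(25.0, rel=0.01)
        assert amps[0] == pytest.approx(-2.0, rel=0.01)

    def test_constant_trace_fails(self):
        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(FitError):
            fit_exponential_decay(t, np.ones_like(t), 1)


class TestTimeToPeak:
    def test_alpha_function_peak_exact(self):
        t, y = make_fixture(FixtureSpec("alpha", (1.0, 30.0), t_end=300.0))
        tp, has = time_to_peak(t, y)
        assert has
        assert tp == pytest.approx(30.0, abs=0.5)

    def test_monotone_trace_flagged(self):
        t = np.arange(0.0, 100.0, 1.0)
        tp, has = time_to_peak(t, t ** 2)
        assert not has
        assert tp == t[-1]

    def test_invariant_under_amplitude_scaling(self):
        t, y = make_fixture(FixtureSpec("alpha", (1.0, 12.0), t_end=150.0))
        assert time_to_peak(t, y)[0] == time_to_peak(t, 50 * y)[0]


class TestAPMetrics:
    def test_flat_trace(self):
        t = np.arange(0.0, 500.0, 0.5)
        m = ap_metrics(t, np.full_like(t, -55.0))
        assert m.rmp == pytest.approx(-55.0)
        assert m.n_spikes == 0
        assert not m.has_ap

    def test_triangular_ap_max_dvdt(self):
        t, v = make_fixture(
            FixtureSpec("triangle_ap", (-60.0, 20.0, 100.0, 20.0, 80.0),
                        t_end=500.0, dt=0.5))
        stim = StimulusProtocol.single_pulse(100.0, 1.0, 1.0)
        m = ap_metrics(t, v, stim)
        assert m.max_dvdt == pytest.approx(80.0 / 20.0, rel=1e-6)
        assert m.peak == pytest.approx(20.0)
        assert m.rmp == pytest.approx(-60.0)

    def test_square_ap_duration_at_any_level(self):
        t, v = make_fixture(
            FixtureSpec("square_ap", (-60.0, 10.0, 100.0, 120.0),
                        t_end=500.0, dt=0.5))
        stim = StimulusProtocol.single_pulse(100.0, 1.0, 1.0)
        for frac in (0.2, 0.5, 0.8):
            m = ap_metrics(t, v, stim, apd_fraction=frac)
            assert m.apd == pytest.approx(120.0, abs=1.0)

    def test_spike_counting(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = -60 + 80 * (np.sin(2 * np.pi * t / 20.0) > 0.9)
        assert count_spikes(t, v, 0.0) == 5


class TestThresholdSearch:
    def test_bisection_resolution_and_all_or_none(self, params, equilibrium):
        v_th, i_th = threshold_search(params, pulse_width=2.0,
                                      y0=equilibrium, resolution=0.05)
        assert -55.0 < v_th < -20.0
        assert 0.0 < i_th < 40.0
        # all-or-none: slightly below stays sub, slightly above fires
        from usmcsim.model import integrate
        for amp, fires in ((i_th * 0.95, False), (i_th * 1.05, True)):
            stim = StimulusProtocol.single_pulse(50.0, 2.0, amp)
            traj = integrate(equilibrium, 600.0, params=params, stimulus=stim)
            assert (traj.v.max() >= 0.0) == fires

    def test_no_threshold_without_inward_currents(self, params, equilibrium):
        p = params.update({"g_cal": 0.0, "g_cat": 0.0, "g_na": 0.0})
        with pytest.raises(NoThreshold):
            threshold_search(p, pulse_width=2.0, y0=equilibrium,
                             amp_max=30.0)

    def test_wider_pulse_threshold_not_larger(self, params, equilibrium):
        _, i2 = threshold_search(params, 2.0, y0=equilibrium, resolution=0.1)
        _, i5 = threshold_search(params, 5.0, y0=equilibrium, resolution=0.1)
        assert i5 <= i2 + 0.1


class TestClassification:
    def test_classify_square_plateau(self):
        t, v = make_fixture(
            FixtureSpec("square_ap", (-60.0, -20.0, 100.0, 3000.0),
                        t_end=4000.0, dt=1.0))
        assert classify_ap(t, v, rmp=-60.0) == "plateau"

    def test_classify_single_spike(self):
        t, v = make_fixture(
            FixtureSpec("triangle_ap", (-60.0, 20.0, 100.0, 20.0, 60.0),
                        t_end=2000.0, dt=0.5))
        assert classify_ap(t, v, rmp=-60.0) == "spike"
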