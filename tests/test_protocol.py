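import numpy as np
import pytest
from scipy.optimize import brentq

from fpaperf.errors import AcquisitionWindowError, NoTriggerError
from fpaperf.protocol import (
    ProtocolAcquisition,
    ProtocolConfig,
    detect_trigger,
    dispersion_sweep,
    peak_offset,
    run_protocol,
    select_v1_v2,
)
from fpaperf.synthetic import (
    AorticCurve,
    build_curve_model,
    make_acquisition_spec,
    sample_curve,
)


@pytest.fixture
def config():
    return ProtocolConfig()


def make_monitored(spec, model, interval=None, rng=None):
    duration = model.t_peak + 8.0
    times = spec.gate_times(duration) if interval is None else np.arange(
        0.0, duration, interval
    )
    return sample_curve(model, times, rng)


class TestDetectTrigger:
    def test_first_crossing_gate(self, config):
        times = np.arange(10.0)
        y = np.array([40.0, 40, 45, 100, 170, 200, 400, 500, 450, 300])
        curve = AorticCurve(times=times, enhancement=y, baseline=40.0)
        # threshold 180 crossed between samples 4 and 5 -> sample 5's time
        assert detect_trigger(curve, config) == 5.0

    def test_threshold_above_max(self, config):
        times = np.arange(10.0)
        curve = AorticCurve(times=times, enhancement=np.full(10, 50.0), baseline=40.0)
        with pytest.raises(NoTriggerError):
            detect_trigger(curve, config)

    def test_against_analytic_root(self, spec45, noiseless_model, config):
        curve = make_monitored(spec45, noiseless_model)
        m = noiseless_model
        threshold = m.C + config.trigger_delta
        root = brentq(lambda t: m(t) - threshold, m.t0 + 1e-9, m.t_peak)
        expected = curve.times[np.searchsorted(curve.times, root)]
        assert detect_trigger(curve, config) == pytest.approx(expected)

    def test_baseline_estimated_from_prearrival(self, spec45, noiseless_model, config):
        curve = make_monitored(spec45, noiseless_model)
        anonymous = AorticCurve(times=curve.times, enhancement=curve.enhancement)
        assert detect_trigger(anonymous, config) == detect_trigger(curve, config)


class TestSelectV1V2:
    def test_hand_computed_gate_grid(self, config):
        # HR 60: gates at 0.75, 1.75, ..., trigger 10.2 -> v1 = 10.75;
        # T_i = 9, d = 1 -> v2 = first gate >= 16.25 = 16.75 (6 gates later)
        spec = make_acquisition_spec(45.0, heart_rate=60.0)
        gates = spec.gate_times(30.0)
        v1, v2 = select_v1_v2(10.2, spec, config, gates, d=1.0)
        assert v1 == pytest.approx(10.75)
        assert v2 == pytest.approx(16.75)

    def test_exact_multiple_lands_on_gate(self, config):
        # d = 0 and T_i/2 = 5 s an exact multiple of the 1-s R-R
        spec = make_acquisition_spec(50.0, heart_rate=60.0)
        gates = spec.gate_times(30.0)
        v1, v2 = select_v1_v2(10.2, spec, config, gates, d=0.0)
        assert v1 == pytest.approx(10.75)
        assert v2 == pytest.approx(15.75)

    def test_trigger_after_last_gate(self, config):
        spec = make_acquisition_spec(45.0, heart_rate=60.0)
        gates = spec.gate_times(20.0)
        with pytest.raises(AcquisitionWindowError):
            select_v1_v2(25.0, spec, config, gates)

    def test_window_too_short_for_v2(self, config):
        spec = make_acquisition_spec(95.0, heart_rate=60.0)  # T_i/2 = 9.5
        gates = spec.gate_times(15.0)
        with pytest.raises(AcquisitionWindowError):
            select_v1_v2(10.0, spec, config, gates, d=4.0)


class TestPeakOffset:
    def test_on_peak_gate(self):
        gates = np.arange(1.0, 20.0)
        assert peak_offset(14.0, 14.2, gates) == 0

    def test_two_gates_late(self):
        gates = np.arange(1.0, 20.0)
        assert peak_offset(16.0, 14.2, gates) == 2

    def test_enumeration_oracle_hr75(self):
        spec = make_acquisition_spec(45.0, heart_rate=75.0)
        gates = spec.gate_times(30.0)
        # explicit enumeration of nearest gates
        i_v2 = min(range(gates.size), key=lambda i: abs(gates[i] - 13.0))
        i_pk = min(range(gates.size), key=lambda i: abs(gates[i] - 14.3))
        assert peak_offset(13.0, 14.3, gates) == i_v2 - i_pk

    def test_continuous_mode(self):
        gates = np.arange(0.0, 20.0, 0.8)
        off = peak_offset(13.0, 14.6, gates, continuous=True)
        assert off == pytest.approx(-2.0)


def build_cohort_for_sweep(n=20, b=16.0, seed=0, dispersion=2.3):
    cohort = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        spec = make_acquisition_spec(
            weight=rng.uniform(28, 96),
            condition="rest" if i % 2 == 0 else "stress",
            heart_rate=rng.uniform(73, 105),
            seed=i,
        )
        model = build_curve_model(
            spec, b=b, t0=rng.uniform(4, 10),
            dispersion_delay=dispersion, noise_sd=10.0,
        )
        gates = spec.gate_times(model.t_peak + 10.0)
        monitoring = make_monitored(spec, model, interval=0.35, rng=rng)
        cohort.append(
            ProtocolAcquisition(
                spec=spec, gate_times=gates, curve=monitoring,
                ideal_peak_time=model.t_peak,
            )
        )
    return cohort


class TestDispersionSweep:
    def test_perfect_cohort_zero_offset(self, config):
        # every V2 lands exactly on the peak gate for d matching the truth
        spec = make_acquisition_spec(50.0, heart_rate=60.0)
        gates = spec.gate_times(40.0)
        y = np.where(gates < 10.0, 40.0, 400.0)
        curve = AorticCurve(times=gates, enhancement=y, baseline=40.0)
        trigger = detect_trigger(curve, config)
        v1, v2 = select_v1_v2(trigger, spec, config, gates, d=0.0)
        acq = ProtocolAcquisition(
            spec=spec, gate_times=gates, curve=curve, ideal_peak_time=v2
        )
        summary = dispersion_sweep([acq, acq], ProtocolConfig(d_grid=(0.0,)))
        entry = summary.entry(0.0)
        assert entry.mean == 0.0
        assert entry.rmse == 0.0
        assert entry.p_value == 1.0

    def test_best_d_beats_largest_d(self, config):
        cohort = build_cohort_for_sweep()
        summary = dispersion_sweep(cohort, config)
        best = min(e.mean_abs for e in summary.entries)
        assert best < summary.entry(4.0).mean_abs

    def test_v2_monotone_in_d(self, config):
        cohort = build_cohort_for_sweep(n=5)
        for acq in cohort:
            v2s = [run_protocol(acq, config, d=d).v2_time for d in config.d_grid]
            assert np.all(np.diff(v2s) >= 0)

    def test_mean_offset_monotone_in_d(self, config):
        cohort = build_cohort_for_sweep()
        summary = dispersion_sweep(cohort, config)
        means = [e.mean for e in summary.entries]
        assert np.all(np.diff(means) >= 0)

    def test_failed_acquisitions_skipped(self, config):
        cohort = build_cohort_for_sweep(n=6)
        flat = AorticCurve(
            times=cohort[0].curve.times,
            enhancement=np.full(cohort[0].curve.times.size, 40.0),
            baseline=40.0,
        )
        broken = ProtocolAcquisition(
            spec=cohort[0].spec, gate_times=cohort[0].gate_times,
            curve=flat, ideal_peak_time=cohort[0].ideal_peak_time,
        )
        summary = dispersion_sweep(cohort + [broken], config)
        assert summary.n_skipped == 1
        assert summary.entry(0.0).n == 6

    def test_raising_threshold_never_earlier(self, spec45, noiseless_model):
        curve = make_monitored(spec45, noiseless_model)
        t_low = detect_trigger(curve, ProtocolConfig(trigger_delta=100.0))
        t_high = detect_trigger(curve, ProtocolConfig(trigger_delta=300.0))
        assert t_high >= t_low
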