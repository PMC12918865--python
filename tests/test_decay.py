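import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akima_oracle import akima_deriv, akima_eval
from conftest import make_trace_with_events
from synquant.decay import (
    SeparationError,
    akima_spline,
    analyze_decay_distribution,
    classify_events,
    find_critical_value,
    find_modes,
    fit_decay_3070,
    measure_decays,
)
from synquant.decay import test_multimodality as multimodality_p
from synquant.detect import Event, detect_events
from synquant.traceio import Trace, lowpass_filter


def exponential_decay_trace(tau_ms, amp=15.0, rate=20_000.0, peak_s=0.05, dur_s=0.3):
    t_ms = np.arange(int(dur_s * rate)) / rate * 1000.0
    y = amp * np.exp(-np.maximum(t_ms - peak_s * 1000, 0) / tau_ms) * (t_ms >= peak_s * 1000)
    trace = Trace(rate, -y, polarity="inward")
    event = Event(onset_time=peak_s - 0.001, peak_time=peak_s, amplitude=amp,
                  peak_index=int(peak_s * rate), baseline=0.0)
    return trace, event


class TestFitDecay:
    @pytest.mark.parametrize("tau", [2.0, 5.0, 8.0])
    def test_noise_free_monoexponential_recovered_exactly(self, tau):
        trace, event = exponential_decay_trace(tau)
        est = fit_decay_3070(trace, event)
        assert est == pytest.approx(tau, abs=1e-3)

    @pytest.mark.parametrize("tau", [2.0, 8.0])
    def test_transit_metric_equals_tau_ln_7_3(self, tau):
        trace, event = exponential_decay_trace(tau)
        est = fit_decay_3070(trace, event, metric="transit")
        assert est == pytest.approx(tau * np.log(7.0 / 3.0), abs=1e-3)

    def test_noisy_replicates_bias_under_10pct(self):
        tau, ests = 2.0, []
        for s in range(100):
            raw = make_trace_with_events([0.02], [15.0], [tau], 0.2, rms_noise=1.4, seed=s)
            filt = lowpass_filter(raw)
            events = detect_events(filt, 7.0, measure_trace=raw)
            if len(events) != 1:
                continue
            est = fit_decay_3070(filt, events[0])
            if est is not None:
                ests.append(est)
        assert len(ests) > 80
        assert abs(np.mean(ests) - tau) / tau < 0.10

    def test_truncated_decay_flagged_unmeasurable(self):
        trace, event = exponential_decay_trace(8.0)
        # next event onset arrives before the decay reaches 30% of peak
        next_onset = event.peak_index + int(0.002 * trace.sampling_rate)
        assert fit_decay_3070(trace, event, next_onset_index=next_onset) is None

    def test_measure_decays_fills_events_in_order(self):
        raw = make_trace_with_events([0.05, 0.25], [15.0, 15.0], [2.0, 8.0], 0.5)
        filt = lowpass_filter(raw)
        events = detect_events(filt, 7.0)
        measure_decays(filt, events)
        assert events[0].decay_metric == pytest.approx(2.0, rel=0.15)
        assert events[1].decay_metric == pytest.approx(8.0, rel=0.15)


class TestMultimodality:
    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            multimodality_p(np.arange(10))

    def test_bimodal_mixture_detected(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            x = np.concatenate([r.normal(2, 0.3, 150), r.normal(8, 0.8, 150)])
            hits += multimodality_p(x) < 0.05
        assert hits >= 19

    def test_unimodal_normal_rarely_rejected(self):
        keeps = 0
        for s in range(30):
            r = np.random.default_rng(1000 + s)
            keeps += multimodality_p(r.normal(5, 1, 300)) >= 0.05
        assert keeps >= 27  # near-nominal size

    def test_constant_values_are_unimodal(self):
        assert multimodality_p(np.full(50, 3.0)) == 1.0


class TestAkimaSpline:
    def test_collinear_nodes_reproduce_the_line(self):
        x = np.arange(8.0)
        sp = akima_spline(np.column_stack([x, 2 * x]))
        q = np.linspace(0, 7, 100)
        np.testing.assert_allclose(sp(q), 2 * q, atol=1e-12)
        np.testing.assert_allclose(sp.derivative()(q), 2.0, atol=1e-12)

    def test_interpolation_passes_through_nodes(self, rng):
        x = np.sort(rng.uniform(0, 10, 12))
        y = rng.uniform(0, 50, 12)
        sp = akima_spline(np.column_stack([x, y]))
        np.testing.assert_allclose(sp(x), y, atol=1e-10)

    def test_matches_independent_brute_force_oracle(self):
        """Dual-route check: spline and first derivative agree with a
        from-the-formulas Akima implementation to <= 1e-9."""
        for s in range(10):
            r = np.random.default_rng(s)
            n = r.integers(6, 25)
            x = np.sort(r.uniform(0, 20, n))
            while np.min(np.diff(x)) < 1e-3:
                x = np.sort(r.uniform(0, 20, n))
            y = r.uniform(-5, 50, n)
            sp = akima_spline(np.column_stack([x, y]))
            q = np.linspace(x[0], x[-1] - 1e-9, 200)
            np.testing.assert_allclose(sp(q), akima_eval(x, y, q), atol=1e-9)
            np.testing.assert_allclose(sp.derivative()(q), akima_deriv(x, y, q), atol=1e-9)

    def test_too_few_or_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError, match="5 nodes"):
            akima_spline([[0, 1], [1, 2], [2, 3], [3, 4]])
        with pytest.raises(ValueError, match="strictly increasing"):
            akima_spline([[0, 1], [1, 2], [1, 3], [3, 4], [4, 5]])


class TestCriticalValue:
    def test_symmetric_histogram_gives_exact_midpoint(self):
        x = np.arange(1.0, 8.0)
        counts = np.array([1.0, 10.0, 3.0, 1.0, 3.0, 10.0, 1.0])  # symmetric about 4
        sp = akima_spline(np.column_stack([x, counts]))
        modes = find_modes(sp, min_separation=2.0)
        # the spline maxima sit symmetrically about x = 4
        assert modes[0] + modes[1] == pytest.approx(8.0, abs=0.01)
        cv = find_critical_value(sp, modes)
        assert cv == pytest.approx(4.0, abs=1e-6)

    def test_asymmetric_histogram_matches_brute_force_argmin(self):
        x = np.arange(1.0, 11.0)
        counts = np.array([2.0, 14.0, 6.0, 2.0, 1.5, 3.0, 8.0, 11.0, 5.0, 1.0])
        sp = akima_spline(np.column_stack([x, counts]))
        modes = find_modes(sp, min_separation=2.0)
        cv = find_critical_value(sp, modes)
        grid = np.linspace(modes[0], modes[1], 200_001)
        brute = grid[np.argmin(sp(grid))]
        assert cv == pytest.approx(brute, abs=1e-4)

    def test_unimodal_spline_not_separable(self):
        x = np.arange(1.0, 8.0)
        counts = np.array([1.0, 3.0, 8.0, 12.0, 8.0, 3.0, 1.0])
        sp = akima_spline(np.column_stack([x, counts]))
        with pytest.raises(SeparationError):
            modes = find_modes(sp, min_separation=2.0)
            find_critical_value(sp, modes)


def _events_with_decays(decays):
    return [Event(onset_time=i * 0.1, peak_time=i * 0.1, amplitude=10.0, decay_metric=d)
            for i, d in enumerate(decays)]


class TestClassification:
    def test_all_fast_events_degenerate_split(self):
        typed = classify_events(_events_with_decays([1.0, 1.5, 2.0]), critical_value=4.0,
                                analyzed_duration=30.0)
        assert len(typed.type1_events) == 3 and len(typed.type2_events) == 0
        assert typed.type2_frequency == 0.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.5, 20.0), min_size=1, max_size=50), st.floats(1.0, 10.0))
    def test_partition_conserves_events_and_frequency(self, decays, cv):
        events = _events_with_decays(decays)
        typed = classify_events(events, cv, analyzed_duration=60.0)
        assert len(typed.type1_events) + len(typed.type2_events) == len(events)
        assert typed.type1_frequency + typed.type2_frequency == pytest.approx(len(events) / 60.0)
        assert all(e.decay_metric < cv for e in typed.type1_events)
        assert all(e.decay_metric >= cv for e in typed.type2_events)

    def test_unmeasured_decays_excluded(self):
        events = _events_with_decays([1.0, None, 8.0])
        typed = classify_events(events, 4.0, analyzed_duration=30.0)
        assert len(typed.type1_events) == 1 and len(typed.type2_events) == 1

    def test_planted_mixture_misclassification_below_5pct(self):
        rates = []
        for s in range(10):
            r = np.random.default_rng(3000 + s)
            tau = np.concatenate([2 * np.exp(r.normal(0, 0.2, 150) - 0.02),
                                  8 * np.exp(r.normal(0, 0.2, 150) - 0.02)])
            labels = np.array([1] * 150 + [2] * 150)
            dist = analyze_decay_distribution(tau)
            assert dist.separable
            pred = np.where(tau < dist.critical_value, 1, 2)
            rates.append(np.mean(pred != labels))
        assert np.mean(rates) <= 0.05

    def test_critical_value_between_component_means(self):
        cvs = []
        for s in range(20):
            r = np.random.default_rng(4000 + s)
            tau = np.concatenate([2 * np.exp(r.normal(0, 0.2, 150) - 0.02),
                                  8 * np.exp(r.normal(0, 0.2, 150) - 0.02)])
            dist = analyze_decay_distribution(tau)
            if dist.separable:
                cvs.append(dist.critical_value)
        assert len(cvs) >= 18
        assert 2.0 < np.median(cvs) < 8.0

    def test_misclassification_shrinks_with_separation(self):
        """Wider kinetic separation between the populations must not make
        classification worse."""
        rates = []
        for tau2 in (3.5, 5.0, 8.0):
            errs = []
            for s in range(5):
                r = np.random.default_rng(5000 + s)
                tau = np.concatenate([2 * np.exp(r.normal(0, 0.15, 150)),
                                      tau2 * np.exp(r.normal(0, 0.15, 150))])
                labels = np.array([1] * 150 + [2] * 150)
                dist = analyze_decay_distribution(tau)
                if not dist.separable:
                    errs.append(0.5)
                    continue
                pred = np.where(tau < dist.critical_value, 1, 2)
                errs.append(np.mean(pred != labels))
            rates.append(np.mean(errs))
        assert rates[0] >= rates[1] - 0.01 >= rates[2] - 0.02
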