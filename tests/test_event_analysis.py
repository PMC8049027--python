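"""Event detection, rate/dwell statistics, zero-voltage extrapolation."""

import math

import numpy as np
import pytest

from porethru import event_analysis as ea
from porethru import trace_synth as ts


def match_events(detected: ea.EventTable, ledger: ts.EventLedger, tol_s: float):
    """Pair detected events to ground-truth events by onset proximity."""
    matched = 0
    used = np.zeros(len(detected), dtype=bool)
    for onset in ledger.onsets:
        d = np.abs(detected.onsets - onset)
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol_s and not used[j]:
            used[j] = True
            matched += 1
    false_pos = int((~used).sum())
    return matched, false_pos


class TestDetection:
    def test_noiseless_detection_equals_ledger(self, noiseless_trace):
        trace, ledger, cfg = noiseless_trace
        fs = trace.sampling_rate
        table = ea.detect_events(trace)
        # every interior event clearly above the min-dwell bound must be
        # recovered with sample-exact timing; extras are only permitted at
        # the min-dwell quantisation boundary
        keep = [
            (o, d)
            for o, d in zip(ledger.onsets, ledger.dwells)
            if d >= table.min_dwell + 2.0 / fs
            and o + d < trace.duration - 1.0 / fs
        ]
        for o, d in keep:
            j = int(np.argmin(np.abs(table.onsets - o)))
            assert abs(table.onsets[j] - o) <= 1.0 / fs
            assert abs(table.dwells[j] - d) <= 2.0 / fs
        for onset, dwell in zip(table.onsets, table.dwells):
            j = int(np.argmin(np.abs(ledger.onsets - onset)))
            assert abs(ledger.onsets[j] - onset) <= 1.0 / fs
            assert abs(ledger.dwells[j] - dwell) <= 2.0 / fs

    def test_noisy_filtered_recovery_no_false_positives(self):
        # millisecond-scale events, 5% amplitude noise, 2.5 kHz filter
        gating = ts.GatingModel(k_on0=8.0, alpha_on=0.0, tau0=8e-3, alpha_off=0.0)
        cfg = ts.TraceConfig(duration=60.0, noise_sd=2.5, i_open=50.0, seed=23)
        trace, ledger = ts.simulate_trace(gating, cfg, 1.0, -50.0)
        table = ea.detect_events(trace)
        resolvable = ts.EventLedger(
            onsets=ledger.onsets[ledger.dwells >= 1e-3],
            dwells=ledger.dwells[ledger.dwells >= 1e-3],
        )
        matched, _ = match_events(table, resolvable, tol_s=1e-3)
        assert matched >= 0.99 * len(resolvable)
        # false positives: detected events matching nothing in the full ledger
        _, false_pos = match_events(table, ledger, tol_s=1e-3)
        assert false_pos == 0

    def test_event_free_trace_gives_empty_table(self):
        cfg = ts.TraceConfig(duration=2.0, noise_sd=2.0, seed=31)
        trace, _ = ts.simulate_trace(
            ts.GatingModel(k_on0=1e-9), cfg, 1.0, 0.0
        )
        table = ea.detect_events(trace)
        assert len(table) == 0

    def test_amplitude_rescaling_leaves_events_unchanged(self, noiseless_trace):
        trace, _, _ = noiseless_trace
        scaled = ts.CurrentTrace(
            sampling_rate=trace.sampling_rate, samples=trace.samples * 3.7
        )
        a = ea.detect_events(trace)
        b = ea.detect_events(scaled)
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.dwells, b.dwells)

    def test_short_trace_rejected(self):
        trace = ts.CurrentTrace(sampling_rate=1000.0, samples=np.ones(50))
        with pytest.raises(ValueError, match="too short"):
            ea.detect_events(trace)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ea.DetectionConfig(threshold_fraction=1.5)


class TestEventRate:
    def _table(self, n, duration):
        onsets = np.linspace(0.1, duration - 0.1, n) if n else np.empty(0)
        return ea.EventTable(
            onsets=onsets, dwells=np.full(n, 1e-3), mean_blocked=np.zeros(n),
            trace_duration=duration,
        )

    def test_simple_arithmetic(self):
        rate, _ = ea.event_rate(self._table(120, 60.0))
        assert rate == 2.0

    def test_zero_events_exact_poisson_bound(self):
        rate, (lo, hi) = ea.event_rate(self._table(0, 10.0))
        assert rate == 0.0 and lo == 0.0
        # upper bound 3.689 / duration, the exact Poisson zero-count limit
        assert hi == pytest.approx(-math.log(0.025) / 10.0, rel=1e-6)

    def test_ci_covers_true_rate_on_simulation(self):
        gating = ts.GatingModel(k_on0=5.0, alpha_on=0.0, tau0=1e-3, alpha_off=0.0)
        cfg = ts.TraceConfig(duration=200.0, noise_sd=0.0, filter_cutoff=None,
                             seed=37)
        _, ledger = ts.simulate_trace(gating, cfg, 1.0, 0.0)
        table = ea.EventTable(
            onsets=ledger.onsets, dwells=ledger.dwells,
            mean_blocked=np.zeros(len(ledger)), trace_duration=200.0,
        )
        rate, _ = ea.event_rate(table)
        # entry rate 5/s, dead time tau -> renewal rate ~ 4.975/s
        expected = 1.0 / (1.0 / 5.0 + 1e-3)
        assert abs(rate - expected) < 3 * math.sqrt(expected * 200.0) / 200.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            ea.event_rate(self._table(0, 0.0))


class TestDwellFit:
    def _table_from(self, dwells, t_min=0.0):
        n = len(dwells)
        return ea.EventTable(
            onsets=np.arange(n, dtype=float), dwells=np.asarray(dwells),
            mean_blocked=np.zeros(n), trace_duration=float(n), min_dwell=t_min,
        )

    def test_mle_consistency(self):
        rng = np.random.default_rng(41)
        tau = 5e-3
        dwells = rng.exponential(tau, size=10_000)
        fit = ea.fit_dwell(self._table_from(dwells))
        assert abs(fit.tau_d - tau) < 3 * tau / math.sqrt(10_000)
        assert fit.ci_low <= fit.tau_d <= fit.ci_high

    def test_truncation_bound_does_not_bias_the_estimate(self):
        # memorylessness: dwells above t_min are t_min + Exp(tau)
        rng = np.random.default_rng(43)
        tau = 5e-3
        raw = rng.exponential(tau, size=200_000)
        kept = raw[raw >= tau]  # truncate at t_min = tau
        fit = ea.fit_dwell(self._table_from(kept, t_min=tau))
        assert fit.tau_d == pytest.approx(tau, rel=0.02)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            ea.fit_dwell(self._table_from(np.full(10, 1e-3)))

    def test_degenerate_dwells_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ea.fit_dwell(self._table_from(np.full(100, 1e-3)))

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(47)
        dwells = rng.exponential(1e-2, size=500)
        a = ea.fit_dwell(self._table_from(dwells), seed=5)
        b = ea.fit_dwell(self._table_from(dwells), seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestZeroVoltageExtrapolation:
    def test_exact_log_linear_points(self):
        points = [(-v, 2.0 * math.exp(0.02 * v)) for v in (20, 40, 60, 80)]
        trend = ea.extrapolate_zero_voltage(points, "event_rate")
        assert trend.intercept_at_zero == pytest.approx(2.0, rel=1e-9)
        assert trend.slope_per_mV == pytest.approx(0.02, rel=1e-9)
        assert trend.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_generative_model_recovery_from_ledger_rates(self):
        # simulate at 1 uM with k_on0 = 1 /s/uM: the zero-voltage intercept
        # is the spontaneous entry rate, in the 1-2 events/s range
        gating = ts.GatingModel(k_on0=1.0, alpha_on=0.03, tau0=0.1,
                                alpha_off=0.02)
        points = []
        for i, v in enumerate((-20, -40, -60, -80, -100)):
            cfg = ts.TraceConfig(duration=150.0, noise_sd=0.0,
                                 filter_cutoff=None, seed=300 + i)
            _, ledger = ts.simulate_trace(gating, cfg, 1.0, v)
            points.append((v, len(ledger) / 150.0))
        trend = ea.extrapolate_zero_voltage(points, "event_rate")
        assert abs(trend.intercept_at_zero - 1.0) / 1.0 < 0.15

    def test_guards(self):
        with pytest.raises(ValueError, match="positive"):
            ea.extrapolate_zero_voltage(
                [(-20, 1.0), (-40, 0.0), (-60, 2.0)], "event_rate"
            )
        with pytest.raises(ValueError, match="3 voltage"):
            ea.extrapolate_zero_voltage([(-20, 1.0), (-40, 2.0)], "event_rate")
        with pytest.raises(ValueError, match="quantity"):
            ea.extrapolate_zero_voltage(
                [(-20, 1.0), (-40, 2.0), (-60, 3.0)], "bogus"
            )
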