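"""Step-response quantification: spike changes, transient excision,
log-normal fits, half-decay."""

import dataclasses

import numpy as np
import pytest

from brushcell.pipeline import analyze_step_trace
from brushcell.steps import (
    fit_lognormal_peak,
    half_decay_time,
    remove_stimulus_transients,
    step_spike_changes,
)
from brushcell.synth import (
    continuum_params,
    make_step_protocol,
    response_intensity,
)
from brushcell.types import RateTrace, ValidationError

DT = 1e-3


def make_trace(t_stop, fn):
    t = np.arange(0.0, t_stop, DT)
    return RateTrace(0.0, DT, np.clip(fn(t), 0.0, None))


class TestStepSpikeChanges:
    def test_constant_trace_gives_zero_changes(self):
        trace = make_trace(10.0, lambda t: np.full_like(t, 12.0))
        during, after = step_spike_changes(trace, 4.0, 5.0)
        assert during == pytest.approx(0.0, abs=1e-6)
        assert after == pytest.approx(0.0, abs=1e-6)

    def test_rectangular_step_above_reference(self):
        def fn(t):
            return 10.0 + 20.0 * ((t >= 4.0) & (t < 5.0))

        trace = make_trace(10.0, fn)
        during, after = step_spike_changes(trace, 4.0, 5.0)
        assert during == pytest.approx(20.0, abs=0.1)
        assert after == pytest.approx(0.0, abs=0.1)

    def test_off_cell_reduces_firing_during_step(self):
        # simulator + quadrature oracle: slowest cell, 60 spk/s step
        pattern = make_step_protocol(5.0, [60.0], lead=6.0, tail=6.0)
        trace = response_intensity(continuum_params(1.0), pattern,
                                   t_stop=pattern.t_last + 6.0)
        step = pattern.by_kind("step")[0]
        during, _ = step_spike_changes(trace, step.t0, step.t1)
        assert during < 0
        # independent quadrature
        i0, i1 = trace.slice_indices(step.t0, step.t1)
        ref0, ref1 = trace.slice_indices(step.t0 - 1.0, step.t0)
        expected = np.trapezoid(
            trace.values[i0:i1 + 1], dx=DT
        ) - trace.values[ref0:ref1].mean() * 1.0
        assert during == pytest.approx(expected, abs=0.05)

    def test_insufficient_coverage_rejected(self):
        trace = make_trace(6.0, lambda t: np.zeros_like(t))
        with pytest.raises(ValidationError):
            step_spike_changes(trace, 4.0, 5.0)


class TestTransientExcision:
    def test_no_stimuli_is_identity(self):
        trace = make_trace(5.0, lambda t: 10.0 + t)
        out = remove_stimulus_transients(trace, [], 0.1)
        np.testing.assert_array_equal(out.values, trace.values)

    def test_bump_on_constant_recovered_exactly(self):
        def fn(t):
            return 20.0 + 50.0 * ((t >= 2.0) & (t < 2.05))

        trace = make_trace(5.0, fn)
        out = remove_stimulus_transients(trace, [2.0], 0.1)
        np.testing.assert_allclose(out.values, 20.0, atol=1e-9)

    def test_ramp_with_bumps_recovers_ramp(self):
        stims = [1.0, 2.0, 3.0]

        def ramp(t):
            return 5.0 + 4.0 * t

        def fn(t):
            out = ramp(t)
            for s in stims:
                out = out + 60.0 * ((t >= s) & (t < s + 0.06))
            return out

        trace = make_trace(5.0, fn)
        out = remove_stimulus_transients(trace, stims, 0.1)
        expected = ramp(trace.times)
        np.testing.assert_allclose(out.values, expected, atol=4.0 * 2 * DT)

    def test_overlapping_excisions_merge(self):
        def fn(t):
            return 10.0 + 80.0 * ((t >= 2.0) & (t < 2.15))

        trace = make_trace(5.0, fn)
        out = remove_stimulus_transients(trace, [2.0, 2.05, 2.1], 0.08)
        np.testing.assert_allclose(out.values, 10.0, atol=1e-9)

    def test_idempotent(self, rng):
        trace = RateTrace(0.0, DT, rng.uniform(0, 50, 5000))
        once = remove_stimulus_transients(trace, [1.0, 2.5], 0.1)
        twice = remove_stimulus_transients(once, [1.0, 2.5], 0.1)
        np.testing.assert_array_equal(once.values, twice.values)


class TestLogNormalFit:
    A, MU, SIGMA = 50.0, np.log(0.5), 0.5

    def _trace(self, noise_sd=0.0, seed=0):
        t = np.arange(0.0, 5.0, DT)
        with np.errstate(divide="ignore"):
            y = self.A * np.exp(
                -(((np.log(np.maximum(t, 1e-12)) - self.MU) / self.SIGMA) ** 2)
            )
        y[0] = 0.0
        if noise_sd:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
        return RateTrace(0.0, DT, np.clip(y, 0.0, None))

    def test_noiseless_parameters_recovered(self):
        fit = fit_lognormal_peak(self._trace(), 0.0, 3.0, 0.0)
        assert fit.fit_ok
        assert fit.amplitude == pytest.approx(self.A, rel=1e-6)
        assert fit.mu == pytest.approx(self.MU, rel=1e-6)
        assert fit.sigma == pytest.approx(self.SIGMA, rel=1e-6)
        assert fit.time_to_peak == pytest.approx(0.5, rel=1e-6)
        assert fit.residual < 1e-6

    def test_noisy_recovery_within_tolerance(self):
        errors = []
        for seed in range(30):
            fit = fit_lognormal_peak(self._trace(2.0, seed), 0.0, 3.0, 0.0)
            errors.append(abs(fit.time_to_peak - 0.5))
        assert np.median(errors) < 0.05

    def test_zero_trace_fit_not_ok(self):
        trace = RateTrace(0.0, DT, np.zeros(4000))
        fit = fit_lognormal_peak(trace, 0.0, 3.0, 0.0)
        assert not fit.fit_ok

    def test_small_response_flagged_not_ok(self):
        trace = self._trace()
        small = trace.with_values(trace.values * 0.1)  # peak 5 < 8 spk/s
        fit = fit_lognormal_peak(small, 0.0, 3.0, 0.0)
        assert not fit.fit_ok


class TestHalfDecay:
    def test_exponential_decay_closed_form(self):
        tau, peak_t, base = 0.8, 2.0, 5.0

        def fn(t):
            decay = 40.0 * np.exp(-np.clip(t - peak_t, 0, None) / tau)
            return base + np.where(t < peak_t, 40.0 * (t / peak_t), decay)

        trace = make_trace(10.0, fn)
        out = half_decay_time(trace, peak_t, base + 40.0, base,
                              step_offset=peak_t)
        assert out.half_decay == pytest.approx(tau * np.log(2), abs=2 * DT)

    def test_never_decaying_trace_is_undefined(self):
        trace = make_trace(6.0, lambda t: np.full_like(t, 50.0))
        out = half_decay_time(trace, 2.0, 50.0, 10.0, step_offset=2.0)
        assert out.half_decay is None

    def test_matches_bruteforce_scan_on_simulated_cell(self):
        pattern = make_step_protocol(5.0, [60.0], lead=6.0, tail=10.0)
        params = continuum_params(0.8)
        trace = response_intensity(params, pattern,
                                   t_stop=pattern.t_last + 10.0)
        step = pattern.by_kind("step")[0]
        rows = analyze_step_trace(trace, pattern)
        got = rows[0]["half_decay"]
        # brute-force scan on the independently excised trace
        in_step = (pattern.stimulus_times >= step.t0) & (
            pattern.stimulus_times < step.t1
        )
        excised = remove_stimulus_transients(
            trace, pattern.stimulus_times[~in_step], 0.1
        )
        ref0, ref1 = excised.slice_indices(step.t0 - 1.0, step.t0)
        baseline = trace.values[ref0:ref1].mean()
        i0, i1 = excised.slice_indices(step.t0, step.t1 + 3.0)
        j = i0 + int(np.argmax(excised.values[i0:i1]))
        peak = excised.values[j]
        thr = baseline + (peak - baseline) / 2.0
        k = j + int(np.argmax(excised.values[j:] <= thr))
        expected = excised.times[k] - step.t1
        assert got == pytest.approx(expected, abs=2 * DT)


class TestStepInvariants:
    def test_time_to_peak_nondecreasing_in_mglur23_weight(self):
        pattern = make_step_protocol(5.0, [60.0], lead=6.0, tail=10.0)
        base = continuum_params(0.5)
        tps = []
        for a2 in (0.0, 2.0, 4.0, 6.0, 8.0):
            p = dataclasses.replace(base, a_2=a2)
            trace = response_intensity(p, pattern, t_stop=pattern.t_last + 10.0)
            tps.append(analyze_step_trace(trace, pattern)[0]["time_to_peak"])
        assert all(b >= a - 1e-6 for a, b in zip(tps, tps[1:]))

    def test_half_decay_nondecreasing_in_mglur1_tau(self):
        pattern = make_step_protocol(5.0, [60.0], lead=6.0, tail=10.0)
        base = continuum_params(0.5)
        hds = []
        for tau1 in (0.3, 0.6, 1.2, 2.4, 4.0):
            p = dataclasses.replace(base, tau_1=tau1)
            trace = response_intensity(p, pattern, t_stop=pattern.t_last + 10.0)
            hds.append(analyze_step_trace(trace, pattern)[0]["half_decay"])
        assert all(hd is not None for hd in hds)
        assert all(b >= a - 1e-6 for a, b in zip(hds, hds[1:]))
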