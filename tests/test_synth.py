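"""Stimulus builders, the receptor continuum model, and the spike sampler."""

import dataclasses

import numpy as np
import pytest

from brushcell.pipeline import burst_metrics_from_trace
from brushcell.synth import (
    TAU1_MAX,
    TAU1_MIN,
    ReceptorParams,
    apply_block,
    continuum_params,
    make_burst_pattern,
    make_invivo_burst_train,
    make_step_protocol,
    response_components,
    response_intensity,
    sample_trials,
)
from brushcell.types import RateTrace, ValidationError


class TestBurstPattern:
    def test_twenty_stimuli_at_100_hz(self):
        pattern = make_burst_pattern(20, 100.0, 0.0)
        np.testing.assert_allclose(pattern.stimulus_times, np.arange(20) * 0.01)
        ann = pattern.by_kind("burst")[0]
        assert ann.t0 == 0.0 and ann.t1 == pytest.approx(0.19, abs=1e-5)

    def test_single_stimulus(self):
        pattern = make_burst_pattern(1, 100.0, 2.0)
        np.testing.assert_allclose(pattern.stimulus_times, [2.0])

    def test_spacing_and_span(self):
        pattern = make_burst_pattern(5, 50.0, 0.0)
        np.testing.assert_allclose(np.diff(pattern.stimulus_times), 0.02)
        assert pattern.t_last == pytest.approx(0.08)


class TestStepProtocol:
    def test_six_steps_at_four_second_intervals(self):
        pattern = make_step_protocol(5.0, [10, 20, 30, 40, 50, 60], 1.0, 4.0)
        steps = pattern.by_kind("step")
        assert len(steps) == 6
        onsets = np.array([s.t0 for s in steps])
        np.testing.assert_allclose(np.diff(onsets), 4.0)
        assert all(s.t1 - s.t0 == pytest.approx(1.0) for s in steps)
        assert [s.nominal_rate for s in steps] == [10, 20, 30, 40, 50, 60]

    def test_no_steps_gives_pure_baseline_train(self):
        pattern = make_step_protocol(5.0, [], 1.0, 4.0)
        assert not pattern.by_kind("step")
        np.testing.assert_allclose(np.diff(pattern.stimulus_times), 0.2,
                                   atol=1e-9)

    def test_step_stimulus_count_is_rate_times_duration(self):
        pattern = make_step_protocol(5.0, [60.0], 1.0, 4.0)
        step = pattern.by_kind("step")[0]
        assert pattern.times_in(step.t0, step.t1).size == 60

    def test_step_longer_than_interval_rejected(self):
        with pytest.raises(ValidationError):
            make_step_protocol(5.0, [60.0], 4.0, 4.0)

    def test_step_rate_must_exceed_baseline(self):
        with pytest.raises(ValidationError):
            make_step_protocol(5.0, [5.0])


class TestInvivoTrain:
    def test_deterministic_for_fixed_seed(self):
        a = make_invivo_burst_train(30.0, (2, 23), 300.0, 0.5, seed=1)
        b = make_invivo_burst_train(30.0, (2, 23), 300.0, 0.5, seed=1)
        assert a == b

    def test_degenerate_size_range(self):
        pattern = make_invivo_burst_train(30.0, (2, 2), 300.0, 0.5, seed=1)
        for ann in pattern.by_kind("burst"):
            assert pattern.times_in(ann.t0, ann.t1).size == 2

    def test_burst_count_matches_renewal_rate(self):
        # Monte-Carlo oracle: mean burst count ~ duration * burst_rate
        counts = [
            len(make_invivo_burst_train(30.0, (2, 23), 300.0, 0.5, seed=s)
                .by_kind("burst"))
            for s in range(100)
        ]
        expected = 30.0 * 0.5
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * max(se, 1e-9)


class TestContinuum:
    def test_fast_endpoint_is_pure_on_cell(self):
        p = continuum_params(0.0)
        assert p.a_2 == 0.0 and p.r0 == 0.0 and p.a_A > 0

    def test_slow_endpoint_is_off_dominated(self):
        p = continuum_params(1.0)
        assert p.a_A == 0.0 and p.a_2 > 0 and p.r0 > 0

    def test_tau1_midpoint_is_geometric_mean(self):
        p = continuum_params(0.5)
        assert p.tau_1 == pytest.approx(np.sqrt(TAU1_MIN * TAU1_MAX))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            continuum_params(1.5)


class TestBlocking:
    def test_idempotent(self):
        p = continuum_params(0.5)
        once = apply_block(p, "AMPAR")
        assert apply_block(once, "AMPAR") == once

    def test_order_independent(self):
        p = continuum_params(0.5)
        ab = apply_block(apply_block(p, "AMPAR"), "mGluR1")
        ba = apply_block(apply_block(p, "mGluR1"), "AMPAR")
        assert ab.blocked == ba.blocked

    def test_unknown_receptor_rejected(self):
        with pytest.raises(ValidationError):
            apply_block(continuum_params(0.5), "GABA_A")

    def test_full_blockade_reduces_to_spontaneous_rate(self):
        p = continuum_params(0.6)
        for r in ("mGluR2/3", "AMPAR", "mGluR1"):
            p = apply_block(p, r)
        trace = response_intensity(p, make_burst_pattern(20, 100.0, 2.0))
        np.testing.assert_allclose(trace.values, p.r0)

    def test_blocking_mglur23_never_decreases_intensity(self):
        p = continuum_params(0.7)
        pattern = make_burst_pattern(20, 100.0, 2.0)
        base = response_intensity(p, pattern)
        blocked = response_intensity(apply_block(p, "mGluR2/3"), pattern)
        assert np.all(blocked.values >= base.values - 1e-12)


class TestIntensityModel:
    def test_no_stimuli_gives_constant_spontaneous_rate(self):
        p = continuum_params(0.8)
        pattern = dataclasses.replace(
            make_burst_pattern(1, 100.0, 2.0), stimulus_times=np.array([])
        )
        trace = response_intensity(p, pattern, t_stop=5.0)
        np.testing.assert_allclose(trace.values, p.r0)

    def test_single_stimulus_cannot_activate_mglur1(self):
        # high half-activation: one glutamate increment stays far below K_g
        p = ReceptorParams(a_A=0.0, a_1=1000.0, K_g=50.0, r0=0.0)
        trace = response_intensity(p, make_burst_pattern(1, 100.0, 2.0))
        assert trace.values.max() < 0.01 * p.a_1

    def test_off_cell_silenced_after_long_burst(self):
        p = continuum_params(1.0)
        trace = response_intensity(p, make_burst_pattern(20, 100.0, 2.0))
        sel = (trace.times >= 2.2) & (trace.times <= 2.7)
        assert np.all(trace.values[sel] == 0.0)

    def test_component_separability(self):
        # with r0 large the rectifier never engages and superposition is exact
        p = dataclasses.replace(continuum_params(0.5), r0=500.0)
        pattern = make_burst_pattern(10, 100.0, 2.0)
        full = response_intensity(p, pattern)
        comps = response_components(p, pattern)
        for receptor in ("AMPAR", "mGluR1", "mGluR2/3"):
            blocked = response_intensity(apply_block(p, receptor), pattern)
            diff = full.values - blocked.values
            np.testing.assert_allclose(diff, comps[receptor], atol=1e-9)

    def test_rectification_only_nonlinearity(self):
        p = dataclasses.replace(continuum_params(0.9), r0=500.0)
        pattern = make_burst_pattern(10, 100.0, 2.0)
        comps = response_components(p, pattern)
        total = comps["r0"] + comps["AMPAR"] + comps["mGluR1"] + comps["mGluR2/3"]
        trace = response_intensity(p, pattern)
        np.testing.assert_allclose(trace.values, total, atol=1e-9)

    def test_monotone_continuum_half_width_and_pause(self):
        pattern = make_burst_pattern(20, 100.0, 2.0)
        half_widths, pauses = [], []
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            trace = response_intensity(continuum_params(c), pattern)
            m = burst_metrics_from_trace(trace, pattern)
            half_widths.append(m["half_width"])
            if m["pause_duration"] is not None:
                pauses.append(m["pause_duration"])
        assert all(hw is not None for hw in half_widths)
        assert all(b >= a - 1e-9 for a, b in zip(half_widths, half_widths[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(pauses, pauses[1:]))

    def test_rebound_option_adds_nonnegative_bump(self):
        p = continuum_params(0.2)
        pattern = make_burst_pattern(20, 100.0, 2.0)
        base = response_intensity(p, pattern)
        reb = response_intensity(dataclasses.replace(p, rebound=True), pattern)
        assert np.all(reb.values >= base.values - 1e-12)
        assert reb.values.max() > base.values.max()


class TestSampler:
    def test_zero_intensity_gives_empty_trains(self):
        lam = RateTrace(0.0, 1e-3, np.zeros(1000))
        trains = sample_trials(lam, n_trials=3, seed=0)
        assert all(t.n_spikes == 0 for t in trains)

    def test_constant_rate_poisson_counts(self):
        lam = RateTrace(0.0, 1e-3, np.full(10_000, 50.0))
        trains = sample_trials(lam, t_ref=0.0, n_trials=200, seed=3)
        counts = np.array([t.n_spikes for t in trains])
        se = np.sqrt(500.0 / 200.0)
        assert abs(counts.mean() - 500.0) < 3 * se

    def test_refractory_period_is_hard(self):
        lam = RateTrace(0.0, 1e-3, np.full(5_000, 200.0))
        trains = sample_trials(lam, t_ref=0.002, n_trials=20, seed=5)
        for t in trains:
            if t.n_spikes > 1:
                assert np.diff(t.spike_times).min() >= 0.002

    def test_deterministic_per_seed_and_trial(self):
        lam = RateTrace(0.0, 1e-3, np.full(2_000, 30.0))
        a = sample_trials(lam, n_trials=3, seed=11)
        b = sample_trials(lam, n_trials=3, seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.spike_times, y.spike_times)
        c = sample_trials(lam, n_trials=3, seed=12)
        assert any(
            x.spike_times.size != y.spike_times.size
            or not np.array_equal(x.spike_times, y.spike_times)
            for x, y in zip(a, c)
        )
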