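"""End-to-end orchestration: simulate cohorts, analyze recordings, and run
the receptor decomposition.

These helpers chain the low-level modules the way the CLI and the worked
examples use them: spike trains -> trial-averaged instantaneous rate ->
burst/step metrics -> population table -> wash-in decomposition.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import steps as _steps
from .population import sort_population, washin_decomposition
from .rates import preprocess_trials, smooth_trace
from .synth import (
    ReceptorParams,
    apply_block,
    continuum_params,
    make_burst_pattern,
    response_intensity,
    sample_trials,
)
from .types import CellRecording, RateTrace, StimulusPattern, ValidationError

__all__ = [
    "BURST_LENGTHS",
    "WASHIN_STAGES",
    "reference_burst_pattern",
    "derive_seed",
    "simulate_cell",
    "simulate_continuum_cohort",
    "burst_metrics_from_trace",
    "analyze_burst_recording",
    "analyze_step_trace",
    "analyze_step_recording",
    "population_table",
    "continuum_pipeline",
    "intensity_evoked_count",
    "decompose_intensity",
]

#: Burst lengths probed at 100 spk/s.
BURST_LENGTHS = (1, 2, 5, 10, 20)

#: Cumulative wash-in stages (receptors blocked at each stage).
WASHIN_STAGES = (
    frozenset(),
    frozenset({"mGluR2/3"}),
    frozenset({"mGluR2/3", "AMPAR"}),
    frozenset({"mGluR2/3", "AMPAR", "mGluR1"}),
)


def reference_burst_pattern(t0: float = 2.0) -> StimulusPattern:
    """The reference categorization stimulus: 20 stimuli at 100 spk/s."""
    return make_burst_pattern(20, 100.0, t0)


def derive_seed(seed: int, *indices: int) -> int:
    """A reproducible sub-seed below 2**31 from a base seed and indices."""
    ss = np.random.SeedSequence([int(seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cell(
    params: ReceptorParams,
    pattern: StimulusPattern,
    n_trials: int = 8,
    seed: int = 0,
    cell_id: str = "cell0",
    grid_dt: float = 1e-3,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> CellRecording:
    """Simulate one cell: intensity model -> thinned Poisson trials."""
    intensity = response_intensity(params, pattern, grid_dt, t_start, t_stop)
    trials = sample_trials(intensity, params.t_ref, n_trials, seed)
    return CellRecording(
        cell_id=cell_id,
        protocol_id=pattern.protocol_id,
        blocked=params.blocked,
        trials=tuple(trials),
        stimulus=pattern,
    )


def simulate_continuum_cohort(
    n_cells: int = 31,
    pattern: StimulusPattern | None = None,
    n_trials: int = 8,
    seed: int = 0,
    grid_dt: float = 1e-3,
) -> tuple[list[CellRecording], np.ndarray]:
    """A cohort with continuum coordinates evenly spaced on [0, 1]."""
    if pattern is None:
        pattern = reference_burst_pattern()
    c_values = np.linspace(0.0, 1.0, n_cells)
    recordings = []
    for i, c in enumerate(c_values):
        params = continuum_params(float(c))
        recordings.append(
            simulate_cell(
                params,
                pattern,
                n_trials=n_trials,
                seed=derive_seed(seed, i),
                cell_id=f"cell{i:03d}",
                grid_dt=grid_dt,
            )
        )
    return recordings, c_values


def burst_metrics_from_trace(
    trace: RateTrace,
    pattern: StimulusPattern,
    t_search: float = 4.0,
    response_start_frac: float = 0.1,
    include_stim_period: bool = False,
) -> dict:
    """Burst metrics + evoked-spike count from a rate trace, using the
    pattern's first burst annotation as the stimulation window."""
    bursts = pattern.by_kind("burst")
    if not bursts:
        raise ValidationError(f"pattern {pattern.protocol_id!r} has no burst")
    ann = bursts[0]
    m = _metrics.burst_response_metrics(
        trace, ann.t0, ann.t1, t_search, response_start_frac, include_stim_period
    )
    evoked = _metrics.evoked_spike_count(
        trace, ann.t0, m.response_start, m.half_width, m.baseline_rate
    )
    return {
        "n_stimuli": int(pattern.times_in(ann.t0, ann.t1).size),
        "baseline_rate": m.baseline_rate,
        "peak_rate": m.peak_rate,
        "peak_change": m.peak_change,
        "half_width": m.half_width,
        "pause_duration": m.pause_duration,
        "response_start": m.response_start,
        "evoked_spikes": evoked.count,
        "evoked_fallback": evoked.fallback,
    }


def analyze_burst_recording(
    recording: CellRecording,
    grid_dt: float = 1e-3,
    median_window: int = 21,
    smooth_window: int = 301,
    **metric_kwargs,
) -> dict:
    """Trial-average a recording and compute its burst metrics.

    The averaged trace is median-smoothed (``smooth_window`` samples,
    ~0.3 s at the default grid) before the threshold-crossing metrics so
    that half-width and pause measurements are robust to the narrow spikes
    reciprocal-ISI averages retain from short ISIs.
    """
    trace = preprocess_trials(
        recording.trials,
        recording.t_start,
        grid_dt,
        recording.t_stop,
        median_window=median_window,
    )
    trace = smooth_trace(trace, smooth_window)
    rec = burst_metrics_from_trace(trace, recording.stimulus, **metric_kwargs)
    rec = {
        "cell_id": recording.cell_id,
        "protocol_id": recording.protocol_id,
        "condition": recording.condition,
        **rec,
    }
    return rec


def analyze_step_trace(
    trace: RateTrace,
    pattern: StimulusPattern,
    excision_window: float = 0.1,
    fit_window: float = 3.0,
    min_peak_change: float = 8.0,
) -> list[dict]:
    """Per-step metrics from a rate trace for a step protocol."""
    step_anns = pattern.by_kind("step")
    if not step_anns:
        raise ValidationError(f"pattern {pattern.protocol_id!r} has no steps")
    in_step = np.zeros(pattern.stimulus_times.size, dtype=bool)
    for ann in step_anns:
        in_step |= (pattern.stimulus_times >= ann.t0) & (
            pattern.stimulus_times < ann.t1
        )
    baseline_stims = pattern.stimulus_times[~in_step]
    excised = _steps.remove_stimulus_transients(trace, baseline_stims, excision_window)
    out = []
    for ann in step_anns:
        during, after = _steps.step_spike_changes(trace, ann.t0, ann.t1)
        reference = trace.window_mean(ann.t0 - 1.0, ann.t0)
        fit = _steps.fit_lognormal_peak(
            trace, ann.t0, fit_window, reference, min_peak_change
        )
        # peak of the transient-excised trace after the step onset
        i0, i1 = excised.slice_indices(ann.t0, ann.t1 + 3.0)
        seg = excised.values[i0:i1]
        half_decay = None
        if seg.size:
            j = int(np.argmax(seg))
            peak_rate = float(seg[j])
            peak_time = float(excised.times[i0 + j])
            if peak_rate > reference:
                hd = _steps.half_decay_time(
                    excised, peak_time, peak_rate, reference, ann.t1
                )
                half_decay = hd.half_decay
        out.append(
            {
                "step_rate": ann.nominal_rate,
                "spikes_during": during,
                "spikes_after": after,
                "amplitude": fit.amplitude,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "time_to_peak": fit.time_to_peak,
                "half_decay": half_decay,
                "fit_ok": fit.fit_ok,
            }
        )
    return out


def analyze_step_recording(
    recording: CellRecording,
    grid_dt: float = 1e-3,
    median_window: int = 21,
    smooth_window: int = 301,
    **kwargs,
) -> list[dict]:
    trace = preprocess_trials(
        recording.trials,
        recording.t_start,
        grid_dt,
        recording.t_stop,
        median_window=median_window,
    )
    trace = smooth_trace(trace, smooth_window)
    rows = analyze_step_trace(trace, recording.stimulus, **kwargs)
    for row in rows:
        row.update(
            cell_id=recording.cell_id,
            protocol_id=recording.protocol_id,
            condition=recording.condition,
        )
    return rows


def population_table(records: Iterable[dict]) -> pd.DataFrame:
    """Sorted population table from reference-burst metric records."""
    df = pd.DataFrame(list(records))
    return sort_population(df)


def continuum_pipeline(
    n_cells: int = 31,
    n_trials: int = 8,
    seed: int = 0,
    grid_dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate the standard continuum cohort and run the full burst
    pipeline; returns the sorted population table with the true continuum
    coordinate ``c`` attached."""
    recordings, c_values = simulate_continuum_cohort(
        n_cells=n_cells, n_trials=n_trials, seed=seed, grid_dt=grid_dt
    )
    records = []
    for rec, c in zip(recordings, c_values):
        row = analyze_burst_recording(rec, grid_dt=grid_dt)
        row["c"] = float(c)
        records.append(row)
    return population_table(records)


def intensity_evoked_count(
    params: ReceptorParams,
    pattern: StimulusPattern,
    grid_dt: float = 1e-3,
    **metric_kwargs,
) -> float:
    """Evoked-spike count of the noiseless intensity trace."""
    trace = response_intensity(params, pattern, grid_dt)
    rec = burst_metrics_from_trace(trace, pattern, **metric_kwargs)
    return float(rec["evoked_spikes"])


def decompose_intensity(
    params: ReceptorParams,
    pattern: StimulusPattern,
    grid_dt: float = 1e-3,
    denominator: str = "pre-block",
):
    """Wash-in decomposition on noiseless intensities: evoked-spike counts
    for the four cumulative stages, then receptor percentages."""
    counts = []
    for blocked in WASHIN_STAGES:
        p = params
        for receptor in blocked:
            p = apply_block(p, receptor)
        counts.append(intensity_evoked_count(p, pattern, grid_dt))
    return washin_decomposition(*counts, denominator=denominator)
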