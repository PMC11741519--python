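"""Burst-response metrics and the constant-rate per-stimulus analysis.

Definitions (all on trial-averaged rate traces, times in seconds):

* baseline rate — mean rate over the 1 s preceding MF stimulation;
* peak rate / peak change — maximum rate after the end of stimulation
  (search window configurable, default 4 s), minus baseline;
* half-width — time between the rate first exceeding and then decaying to
  half the baseline-corrected peak, with linear interpolation between grid
  samples;
* pause duration — time from stimulation end until the rate recovers to
  min(5 spk/s, half the peak rate); undefined for cells that never fire at
  baseline;
* evoked spikes — baseline-corrected trapezoid integral of the rate from
  stimulation start to twice the half-width past the response start.

For constant-rate protocols (1/2.5/5 spk/s), per-stimulus responses are
averaged excluding the first five stimuli, without baseline correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .types import RateTrace, ValidationError

__all__ = [
    "BurstResponseMetrics",
    "burst_response_metrics",
    "EvokedSpikeCount",
    "evoked_spike_count",
    "ConstantRateResponse",
    "constant_rate_response",
    "integrate_trace",
    "first_crossing",
]


def integrate_trace(trace: RateTrace, a: float, b: float) -> float:
    """Trapezoid integral of the (piecewise-linear) trace over [a, b]."""
    if b <= a:
        return 0.0
    a = max(a, trace.t0)
    b = min(b, trace.t_stop - trace.dt)  # last defined sample
    if b <= a:
        return 0.0
    t = trace.times
    i0 = int(np.searchsorted(t, a, side="right"))
    i1 = int(np.searchsorted(t, b, side="left"))
    ts = np.concatenate(([a], t[i0:i1], [b]))
    vs = np.concatenate(
        ([trace.value_at(a)], trace.values[i0:i1], [trace.value_at(b)])
    )
    return float(np.trapezoid(vs, ts))


def first_crossing(
    trace: RateTrace,
    threshold: float,
    t_from: float,
    t_to: float | None = None,
    direction: str = "up",
) -> float | None:
    """First time in [t_from, t_to) the trace reaches ``threshold``.

    ``direction="up"`` finds the first time the value is >= threshold
    (``"down"``: <= threshold), linearly interpolating between grid samples;
    returns ``t_from`` itself when the condition already holds there.
    Ties are broken by earliest time. None when there is no crossing.
    """
    if t_to is None:
        t_to = trace.t_stop
    i0 = max(trace.index_of(t_from), 0)
    i1 = min(trace.index_of(t_to) + 1, trace.values.size)
    if i0 >= i1:
        return None
    t = trace.times[i0:i1]
    v = trace.values[i0:i1]
    sign = 1.0 if direction == "up" else -1.0
    ok = sign * v >= sign * threshold
    v_from = trace.value_at(t_from)
    if sign * v_from >= sign * threshold:
        return t_from
    hit = np.flatnonzero(ok & (t >= t_from))
    if hit.size == 0:
        return None
    j = int(hit[0])
    # interpolate between sample j-1 (below) and j (at/above)
    if j == 0:
        t_prev, v_prev = t_from, v_from
    else:
        t_prev, v_prev = t[j - 1], v[j - 1]
        if t_prev < t_from:
            t_prev, v_prev = t_from, v_from
    if v[j] == v_prev:
        t_cross = t[j]
    else:
        t_cross = t_prev + (threshold - v_prev) * (t[j] - t_prev) / (v[j] - v_prev)
    t_cross = min(max(t_cross, t_prev), t[j])
    return float(t_cross) if t_cross < t_to else None


@dataclass(frozen=True)
class BurstResponseMetrics:
    """Scalar summary of one cell's response to a MF burst."""

    baseline_rate: float
    peak_rate: float
    peak_change: float
    peak_time: float
    half_width: float | None
    pause_duration: float | None
    response_start: float | None

    def __post_init__(self):
        if abs(self.peak_change - (self.peak_rate - self.baseline_rate)) > 1e-9:
            raise ValidationError("peak_change must equal peak_rate - baseline_rate")
        if self.pause_duration is not None and self.pause_duration < 0:
            raise ValidationError("pause_duration must be >= 0")


def burst_response_metrics(
    trace: RateTrace,
    stim_onset: float,
    stim_end: float,
    t_search: float = 4.0,
    response_start_frac: float = 0.1,
    include_stim_period: bool = False,
) -> BurstResponseMetrics:
    """Compute baseline, peak change, half-width, pause and response start
    for one MF burst.

    The peak is searched in ``(stim_end, stim_end + t_search]`` (from
    ``stim_onset`` with ``include_stim_period=True``). The trace must cover
    ``[stim_onset - 1, stim_end + t_search]``.
    """
    tol = trace.dt + 1e-9
    if trace.t0 > stim_onset - 1.0 + tol or trace.t_stop < stim_end + t_search - tol:
        raise ValidationError(
            f"trace [{trace.t0}, {trace.t_stop}) does not cover "
            f"[{stim_onset - 1.0}, {stim_end + t_search}]"
        )
    baseline = trace.window_mean(stim_onset - 1.0, stim_onset)

    search_from = stim_onset if include_stim_period else stim_end
    i0 = trace.index_of(search_from) + (0 if include_stim_period else 1)
    i1 = min(trace.index_of(stim_end + t_search) + 1, trace.values.size)
    if i1 <= i0:
        raise ValidationError("empty peak search window")
    seg = trace.values[i0:i1]
    j = int(np.argmax(seg))  # argmax takes the earliest tie
    peak_rate = float(seg[j])
    peak_time = float(trace.times[i0 + j])
    peak_change = peak_rate - baseline

    half_width = None
    response_start = None
    if peak_change > 0:
        thr = baseline + peak_change / 2.0
        t_up = first_crossing(trace, thr, stim_onset, peak_time + trace.dt, "up")
        t_down = None
        if t_up is not None:
            t_down = first_crossing(
                trace, thr, max(peak_time, t_up), trace.t_stop, "down"
            )
        if t_up is not None and t_down is not None:
            half_width = t_down - t_up
        response_start = first_crossing(
            trace,
            baseline + response_start_frac * peak_change,
            stim_onset,
            trace.t_stop,
            "up",
        )

    pause = None
    if baseline > 0:
        theta = min(5.0, peak_rate / 2.0)
        t_reach = first_crossing(trace, theta, stim_end, trace.t_stop, "up")
        pause = None if t_reach is None else t_reach - stim_end

    return BurstResponseMetrics(
        baseline_rate=baseline,
        peak_rate=peak_rate,
        peak_change=peak_change,
        peak_time=peak_time,
        half_width=half_width,
        pause_duration=pause,
        response_start=response_start,
    )


class EvokedSpikeCount(NamedTuple):
    count: float
    truncated: bool = False
    fallback: bool = False

    def __float__(self):
        return float(self.count)


def evoked_spike_count(
    trace: RateTrace,
    stim_onset: float,
    response_start: float | None,
    half_width: float | None,
    baseline_rate: float,
    fallback_window: float = 2.0,
) -> EvokedSpikeCount:
    """Baseline-corrected number of evoked spikes.

    Integrates the rate from stimulation start to twice the half-width past
    the response start; when the half-width (or response start) is
    undefined a fixed ``fallback_window`` is used instead and the result is
    flagged. Windows reaching past the trace are truncated and flagged.
    """
    fallback = half_width is None or response_start is None
    if fallback:
        t_end = stim_onset + fallback_window
    else:
        t_end = response_start + 2.0 * half_width
    truncated = t_end > trace.t_stop
    t_end_eff = min(t_end, trace.t_stop - trace.dt)
    integral = integrate_trace(trace, stim_onset, t_end_eff)
    count = integral - baseline_rate * (t_end_eff - stim_onset)
    return EvokedSpikeCount(count=count, truncated=truncated, fallback=fallback)


class ConstantRateResponse(NamedTuple):
    mean_trace: RateTrace       # stimulus-aligned mean response, t0 = 0
    peak_rate: float            # peak of the mean response, spk/s
    spikes_per_stimulus: float  # integral of the mean response (no baseline
                                # correction)
    n_segments: int


def constant_rate_response(
    traces: Sequence[RateTrace],
    stimulus_times: Sequence[float],
    window: float,
    n_exclude: int = 5,
) -> ConstantRateResponse:
    """Per-stimulus analysis for constant-rate MF input.

    Segments ``[t_k, t_k + window)`` for stimuli ``k >= n_exclude`` are
    extracted from every trial trace, averaged, and summarized by the peak
    of the mean segment and its time integral (spikes per stimulus, not
    baseline corrected).
    """
    stimulus_times = np.asarray(stimulus_times, dtype=float)
    if stimulus_times.size < n_exclude + 1:
        raise ValidationError(
            f"need more than {n_exclude} stimuli, got {stimulus_times.size}"
        )
    if not traces:
        raise ValidationError("at least one trace required")
    dt = traces[0].dt
    m = int(round(window / dt))
    rel = dt * np.arange(m)
    segments = []
    for trace in traces:
        for t_k in stimulus_times[n_exclude:]:
            if t_k + window > trace.t_stop + 1e-9:
                continue  # window past trace end
            segments.append(np.interp(t_k + rel, trace.times, trace.values))
    if not segments:
        raise ValidationError("no stimulus window fully covered by the traces")
    mean_vals = np.vstack(segments).mean(axis=0)
    mean_trace = RateTrace(0.0, dt, mean_vals)
    peak = float(mean_vals.max())
    count = float(np.trapezoid(mean_vals, rel))
    return ConstantRateResponse(mean_trace, peak, count, len(segments))
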