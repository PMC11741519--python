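"""Quantification of responses to 1 s steps in MF input rate.

Covers: baseline-corrected spike counts during (1 s) and after (3 s) each
step; a log-normal fit of the step response, A*exp{-[(ln(t)-mu)/sigma]^2},
whose peak location exp(mu) gives the time to peak; and the half-decay time
measured on a trace from which responses to individual baseline stimuli
have been excised and linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .metrics import first_crossing, integrate_trace
from .types import RateTrace, ValidationError

__all__ = [
    "step_spike_changes",
    "remove_stimulus_transients",
    "LogNormalFit",
    "fit_lognormal_peak",
    "HalfDecay",
    "half_decay_time",
    "StepResponseMetrics",
]


def step_spike_changes(
    trace: RateTrace, step_onset: float, step_offset: float
) -> tuple[float, float]:
    """Baseline-corrected spikes during the step and in the 3 s after it.

    The reference rate is the mean over the 1 s preceding the step. The
    trace must cover ``[step_onset - 1, step_offset + 3)``.
    """
    tol = trace.dt + 1e-9
    if trace.t0 > step_onset - 1.0 + tol or trace.t_stop < step_offset + 3.0 - tol:
        raise ValidationError(
            f"trace [{trace.t0}, {trace.t_stop}) does not cover "
            f"[{step_onset - 1.0}, {step_offset + 3.0})"
        )
    reference = trace.window_mean(step_onset - 1.0, step_onset)
    during = integrate_trace(trace, step_onset, step_offset)
    after = integrate_trace(trace, step_offset, step_offset + 3.0)
    spikes_during = during - reference * (step_offset - step_onset)
    spikes_after = after - reference * 3.0
    return float(spikes_during), float(spikes_after)


def remove_stimulus_transients(
    trace: RateTrace,
    baseline_stimulus_times: Sequence[float],
    excision_window: float = 0.1,
) -> RateTrace:
    """Excise the response to each baseline stimulus and bridge the gap.

    Samples in ``[t_k, t_k + excision_window)`` are replaced by linear
    interpolation between the sample just before ``t_k`` and the sample
    just after the window; overlapping excisions merge into one interval.
    Idempotent: the anchor samples lie outside every excised interval.
    """
    if excision_window <= 0:
        raise ValidationError("excision_window must be > 0")
    stims = np.sort(np.asarray(baseline_stimulus_times, dtype=float))
    if stims.size == 0:
        return trace
    # merge overlapping [t_k, t_k + w) intervals
    intervals: list[list[float]] = []
    for t_k in stims:
        if intervals and t_k <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], t_k + excision_window)
        else:
            intervals.append([t_k, t_k + excision_window])
    values = trace.values.copy()
    n = values.size
    t = trace.times
    for a, b in intervals:
        i0, i1 = trace.slice_indices(a, b)
        if i1 <= i0:
            continue
        i_before = i0 - 1
        i_after = i1
        if i_before < 0 and i_after >= n:
            continue  # excision covers the whole trace; nothing to anchor on
        if i_before < 0:
            values[i0:i1] = values[i_after]
            continue
        if i_after >= n:
            values[i0:i1] = values[i_before]
            continue
        values[i0:i1] = np.interp(
            t[i0:i1], [t[i_before], t[i_after]], [values[i_before], values[i_after]]
        )
    return trace.with_values(np.clip(values, 0.0, None))


class LogNormalFit(NamedTuple):
    amplitude: float
    mu: float
    sigma: float
    time_to_peak: float
    fit_ok: bool
    residual: float


def _lognormal(t, amplitude, mu, sigma):
    return amplitude * np.exp(-(((np.log(t) - mu) / sigma) ** 2))


def fit_lognormal_peak(
    trace: RateTrace,
    step_onset: float,
    fit_window: float = 3.0,
    baseline: float = 0.0,
    min_peak_change: float = 8.0,
) -> LogNormalFit:
    """Least-squares log-normal fit of the baseline-subtracted step response.

    ``t`` is time since step onset; samples at ``t <= dt`` are excluded
    (ln t singularity). Initialization is multi-start over a log-spaced grid
    of candidate peak locations. ``fit_ok`` is False when the response peak
    is below ``min_peak_change`` (no significant increase in firing) or the
    optimizer fails.
    """
    if fit_window <= 0:
        raise ValidationError("fit_window must be > 0")
    tol = trace.dt + 1e-9
    if trace.t0 > step_onset + tol or trace.t_stop < step_onset + fit_window - tol:
        raise ValidationError("trace does not cover the fit window")
    i0, i1 = trace.slice_indices(step_onset, step_onset + fit_window)
    t = trace.times[i0:i1] - step_onset
    y = trace.values[i0:i1] - baseline
    keep = t > trace.dt
    t, y = t[keep], y[keep]
    nan = float("nan")
    if t.size < 4 or not np.any(y > 0):
        return LogNormalFit(nan, nan, nan, nan, False, nan)
    peak_change = float(y.max())
    log_t = np.log(t)

    def resid(p):
        z = (log_t - p[1]) / p[2]
        return p[0] * np.exp(-(z ** 2)) - y

    def jac(p):
        z = (log_t - p[1]) / p[2]
        e = np.exp(-(z ** 2))
        return np.column_stack(
            [e, p[0] * e * 2.0 * z / p[2], p[0] * e * 2.0 * z ** 2 / p[2]]
        )

    best = None
    a0 = peak_change
    t_argmax = float(t[np.argmax(y)])
    starts = {t_argmax}
    starts.update(np.geomspace(max(2 * trace.dt, 0.02), fit_window, 4))
    for t_peak0 in sorted(starts):
        try:
            sol = least_squares(
                resid,
                x0=[a0, np.log(t_peak0), 0.5],
                jac=jac,
                bounds=([0.0, np.log(trace.dt / 10), 1e-3],
                        [np.inf, np.log(100.0), 10.0]),
                max_nfev=400,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return LogNormalFit(nan, nan, nan, nan, False, nan)
    amplitude, mu, sigma = best.x
    residual = float(np.sqrt(2.0 * best.cost))
    fit_ok = peak_change >= min_peak_change
    return LogNormalFit(
        float(amplitude), float(mu), float(sigma), float(np.exp(mu)),
        fit_ok, residual,
    )


class HalfDecay(NamedTuple):
    half_decay: float | None  # s after the step offset; None if no crossing
    truncated: bool           # trace shorter than 3 s past the peak


def half_decay_time(
    trace: RateTrace,
    peak_time: float,
    peak_rate: float,
    baseline: float,
    step_offset: float | None = None,
) -> HalfDecay:
    """Time after the step offset for the rate to decay to half the
    baseline-corrected peak, on a transient-excised trace.

    The first time after ``peak_time`` where the trace falls to
    ``baseline + (peak_rate - baseline)/2`` (linear interpolation) is
    referenced to ``step_offset`` (default: the peak time); negative values
    are clamped to 0. None when the trace never decays that far.
    """
    if peak_rate <= baseline:
        raise ValidationError("peak_rate must exceed baseline")
    if step_offset is None:
        step_offset = peak_time
    truncated = trace.t_stop < peak_time + 3.0
    thr = baseline + (peak_rate - baseline) / 2.0
    t_cross = first_crossing(trace, thr, peak_time, trace.t_stop, "down")
    if t_cross is None:
        return HalfDecay(None, truncated)
    return HalfDecay(max(t_cross - step_offset, 0.0), truncated)


@dataclass(frozen=True)
class StepResponseMetrics:
    """Per-step scalar summary (one row per step rate)."""

    step_rate: float
    spikes_during: float
    spikes_after: float
    amplitude: float
    mu: float
    sigma: float
    time_to_peak: float
    half_decay: float | None
    fit_ok: bool
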