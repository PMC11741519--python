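"""Instantaneous firing-rate estimation.

The instantaneous rate of a single trial is the reciprocal of the
inter-spike interval (ISI) containing each time point, sampled on a uniform
grid: a parameter-free step function that matches the stepped appearance of
single-trial cell-attached traces. The rate is defined as 0 before the
first and after the last spike (loose-seal recordings carry no information
there), and a train with fewer than two spikes has an all-zero trace.

Trial averaging applies a temporal running-median filter to each trial's
trace (suppressing single-ISI outliers) before taking the pointwise mean
across trials. A Gaussian-kernel rate estimate and a pointwise across-trial
median are available as alternatives.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter

from .types import RateTrace, SpikeTrain, ValidationError

__all__ = ["instantaneous_rate", "preprocess_trials", "smooth_trace"]


def smooth_trace(trace: RateTrace, window: int) -> RateTrace:
    """Running-median smooth of a rate trace (edge replication).

    Used by the analysis pipeline on trial-averaged traces before
    threshold-crossing measurements: reciprocal-ISI averages retain narrow
    spikes from short ISIs, and a median wide enough to span several ISIs
    (a few hundred ms) suppresses them without blunting multi-second
    response envelopes. ``window`` is in samples and must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be an odd positive integer")
    if window == 1:
        return trace
    return trace.with_values(
        median_filter(trace.values, size=window, mode="nearest")
    )


def instantaneous_rate(
    train: SpikeTrain,
    t0: float,
    dt: float,
    t_stop: float,
    method: str = "isi",
    kernel_sd: float = 0.025,
) -> RateTrace:
    """Rate trace of one trial on the grid ``t0 + k*dt`` covering
    ``[t0, t_stop)``.

    ``method="isi"`` (default): 1/ISI step function. ``method="kernel"``:
    Gaussian smoothing of the spike train with bandwidth ``kernel_sd`` (s).
    """
    if dt > 1e-3 + 1e-12:
        raise ValidationError("dt must be <= 1 ms")
    n = int(np.ceil((t_stop - t0) / dt - 1e-9))
    t = t0 + dt * np.arange(n)
    spikes = train.spike_times
    if method == "isi":
        values = np.zeros(n)
        if spikes.size >= 2:
            # index of the ISI containing t: spikes[i] <= t < spikes[i+1]
            idx = np.searchsorted(spikes, t, side="right") - 1
            inside = (idx >= 0) & (idx < spikes.size - 1)
            isi = np.diff(spikes)
            values[inside] = 1.0 / isi[idx[inside]]
        return RateTrace(t0, dt, values)
    if method == "kernel":
        values = np.zeros(n)
        for s in spikes:
            values += np.exp(-0.5 * ((t - s) / kernel_sd) ** 2)
        values /= kernel_sd * np.sqrt(2.0 * np.pi)
        return RateTrace(t0, dt, values)
    raise ValidationError(f"unknown rate method {method!r}")


def preprocess_trials(
    trains: Sequence[SpikeTrain],
    t0: float,
    dt: float,
    t_stop: float,
    median_window: int = 3,
    method: str = "isi",
    trial_combine: str = "mean",
) -> RateTrace:
    """Trial-averaged rate: per-trial 1/ISI traces, temporal running-median
    filter of width ``median_window`` samples per trial, then pointwise mean
    (or median, with ``trial_combine="median"``) across trials.

    The running median uses edge replication at the trace boundaries.
    """
    if not trains:
        raise ValidationError("at least one trial required")
    if median_window < 1 or median_window % 2 == 0:
        raise ValidationError("median_window must be an odd positive integer")
    filtered = []
    for train in trains:
        trace = instantaneous_rate(train, t0, dt, t_stop, method=method)
        vals = trace.values
        if median_window > 1:
            vals = median_filter(vals, size=median_window, mode="nearest")
        filtered.append(vals)
    stack = np.vstack(filtered)
    if trial_combine == "mean":
        out = stack.mean(axis=0)
    elif trial_combine == "median":
        out = np.median(stack, axis=0)
    else:
        raise ValidationError(f"unknown trial_combine {trial_combine!r}")
    return RateTrace(t0, dt, out)
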