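"""Core data model for mossy-fiber (MF) stimulation experiments on
unipolar brush cells (UBCs).

All times are in seconds throughout the package. Annotated intervals are
half-open ``[t0, t1)``: an event exactly at ``t1`` belongs to the next
interval, so "during" and "after" windows partition time without double
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Annotation",
    "StimulusPattern",
    "SpikeTrain",
    "CellRecording",
    "RateTrace",
    "ValidationError",
    "RECEPTORS",
    "CONDITION_TOKENS",
    "condition_to_blocked",
    "blocked_to_condition",
]

#: Receptor names in cumulative wash-in order (antagonists LY341495,
#: NBQX, JNJ16259685, R-CPP respectively).
RECEPTORS = ("mGluR2/3", "AMPAR", "mGluR1", "NMDAR")

#: Drug-token encoding of blocked receptors used in condition strings.
CONDITION_TOKENS = {
    "LY": "mGluR2/3",
    "NBQX": "AMPAR",
    "JNJ": "mGluR1",
    "CPP": "NMDAR",
}
_RECEPTOR_TO_TOKEN = {v: k for k, v in CONDITION_TOKENS.items()}


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


def condition_to_blocked(condition: str) -> frozenset[str]:
    """Parse a condition label like ``"LY+NBQX"`` into blocked receptors.

    ``"baseline"`` (or empty) means nothing is blocked.
    """
    condition = condition.strip()
    if condition in ("", "baseline"):
        return frozenset()
    blocked = set()
    for tok in condition.split("+"):
        tok = tok.strip()
        if tok not in CONDITION_TOKENS:
            raise ValidationError(
                f"unknown condition token {tok!r} (expected one of "
                f"{sorted(CONDITION_TOKENS)})"
            )
        blocked.add(CONDITION_TOKENS[tok])
    return frozenset(blocked)


def blocked_to_condition(blocked: Iterable[str]) -> str:
    """Inverse of :func:`condition_to_blocked`; tokens in wash-in order."""
    blocked = set(blocked)
    unknown = blocked - set(RECEPTORS)
    if unknown:
        raise ValidationError(f"unknown receptors {sorted(unknown)}")
    if not blocked:
        return "baseline"
    ordered = [r for r in RECEPTORS if r in blocked]
    return "+".join(_RECEPTOR_TO_TOKEN[r] for r in ordered)


@dataclass(frozen=True)
class Annotation:
    """A labeled half-open interval ``[t0, t1)`` of the stimulus pattern."""

    kind: str  # burst | step | baseline
    t0: float
    t1: float
    nominal_rate: float | None = None

    def __post_init__(self):
        if self.kind not in ("burst", "step", "baseline"):
            raise ValidationError(f"unknown annotation kind {self.kind!r}")
        if not self.t0 < self.t1:
            raise ValidationError(
                f"annotation interval requires t0 < t1, got [{self.t0}, {self.t1})"
            )


@dataclass(frozen=True)
class StimulusPattern:
    """Ordered MF stimulus times plus protocol annotations."""

    stimulus_times: np.ndarray
    annotations: tuple[Annotation, ...] = ()
    protocol_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.stimulus_times, dtype=float)
        object.__setattr__(self, "stimulus_times", times)
        object.__setattr__(self, "annotations", tuple(self.annotations))
        if times.ndim != 1:
            raise ValidationError("stimulus_times must be 1-D")
        if times.size and times[0] < 0:
            raise ValidationError("stimulus times must be >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("stimulus times must be strictly increasing")
        horizon = (times[-1] + 10.0) if times.size else 10.0
        by_kind: dict[str, list[Annotation]] = {}
        for ann in self.annotations:
            if ann.t0 < 0 or ann.t1 > horizon:
                raise ValidationError(
                    f"annotation [{ann.t0}, {ann.t1}) outside [0, {horizon}]"
                )
            by_kind.setdefault(ann.kind, []).append(ann)
        for kind, anns in by_kind.items():
            anns = sorted(anns, key=lambda a: a.t0)
            for a, b in zip(anns, anns[1:]):
                if b.t0 < a.t1:
                    raise ValidationError(
                        f"overlapping {kind!r} annotations at {b.t0}"
                    )

    def __eq__(self, other):
        if not isinstance(other, StimulusPattern):
            return NotImplemented
        return (
            np.array_equal(self.stimulus_times, other.stimulus_times)
            and self.annotations == other.annotations
            and self.protocol_id == other.protocol_id
        )

    @property
    def t_last(self) -> float:
        return float(self.stimulus_times[-1]) if self.stimulus_times.size else 0.0

    def by_kind(self, kind: str) -> tuple[Annotation, ...]:
        return tuple(a for a in self.annotations if a.kind == kind)

    def times_in(self, t0: float, t1: float) -> np.ndarray:
        """Stimulus times in the half-open window ``[t0, t1)``."""
        lo, hi = np.searchsorted(self.stimulus_times, [t0, t1], side="left")
        return self.stimulus_times[lo:hi]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one trial, on ``[t_start, t_stop)``."""

    spike_times: np.ndarray
    trial_id: int = 0
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise ValidationError("spike_times must be 1-D")
        if self.trial_id < 0:
            raise ValidationError("trial_id must be >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"trial {self.trial_id}: spike times must be strictly increasing"
            )
        t_stop = self.t_stop
        if t_stop is None:
            t_stop = (times[-1] + 1e-9) if times.size else self.t_start + 1.0
            object.__setattr__(self, "t_stop", float(t_stop))
        if times.size:
            if times[0] < self.t_start or times[-1] >= self.t_stop:
                raise ValidationError(
                    f"trial {self.trial_id}: spikes outside [t_start, t_stop)"
                )

    def __eq__(self, other):
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            np.array_equal(self.spike_times, other.spike_times)
            and self.trial_id == other.trial_id
            and self.t_start == other.t_start
            and self.t_stop == other.t_stop
        )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return float(self.t_stop - self.t_start)


@dataclass(frozen=True)
class CellRecording:
    """All trials of one cell under one protocol and antagonist condition."""

    cell_id: str
    protocol_id: str
    blocked: frozenset[str]
    trials: tuple[SpikeTrain, ...]
    stimulus: StimulusPattern

    def __post_init__(self):
        object.__setattr__(self, "blocked", frozenset(self.blocked))
        object.__setattr__(self, "trials", tuple(self.trials))
        unknown = self.blocked - set(RECEPTORS)
        if unknown:
            raise ValidationError(f"unknown receptors {sorted(unknown)}")
        if self.trials:
            t0 = self.trials[0].t_start
            t1 = self.trials[0].t_stop
            for tr in self.trials[1:]:
                if abs(tr.t_start - t0) > 1e-3 or abs(tr.t_stop - t1) > 1e-3:
                    raise ValidationError(
                        f"cell {self.cell_id}: trials disagree on "
                        "t_start/t_stop by more than 1 ms"
                    )

    @property
    def condition(self) -> str:
        return blocked_to_condition(self.blocked)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def t_start(self) -> float:
        return self.trials[0].t_start if self.trials else 0.0

    @property
    def t_stop(self) -> float:
        return self.trials[0].t_stop if self.trials else 0.0


def check_cumulative_conditions(blocked_sets: Sequence[Iterable[str]]) -> None:
    """Validate that a wash-in series is cumulative (each condition a
    superset of the previous one), mirroring the successive-antagonist
    experimental design."""
    prev: frozenset[str] = frozenset()
    for i, b in enumerate(blocked_sets):
        b = frozenset(b)
        if not b >= prev:
            raise ValidationError(
                f"wash-in stage {i} ({sorted(b)}) is not a superset of the "
                f"previous stage ({sorted(prev)})"
            )
        prev = b


@dataclass(frozen=True)
class RateTrace:
    """Instantaneous firing rate (spk/s) on a uniform time grid.

    ``values[i]`` is the rate at time ``t0 + i*dt``.
    """

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if vals.ndim != 1:
            raise ValidationError("values must be 1-D")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("rate values must be finite")
        if vals.size and vals.min() < 0:
            raise ValidationError("rate values must be >= 0")

    def __eq__(self, other):
        if not isinstance(other, RateTrace):
            return NotImplemented
        return (
            self.t0 == other.t0
            and self.dt == other.dt
            and np.array_equal(self.values, other.values)
        )

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_stop(self) -> float:
        return self.t0 + self.dt * self.values.size

    def index_of(self, t: float) -> int:
        """Grid index of the sample at or immediately before time ``t``."""
        return int(np.floor((t - self.t0) / self.dt + 1e-9))

    def value_at(self, t: float) -> float:
        """Linearly interpolated rate at time ``t``."""
        return float(np.interp(t, self.times, self.values))

    def slice_indices(self, t0: float, t1: float) -> tuple[int, int]:
        """Grid index range [i0, i1) covering samples in ``[t0, t1)``."""
        i0 = int(np.ceil((t0 - self.t0) / self.dt - 1e-9))
        i1 = int(np.ceil((t1 - self.t0) / self.dt - 1e-9))
        return max(i0, 0), min(max(i1, 0), self.values.size)

    def window_mean(self, t0: float, t1: float) -> float:
        """Mean rate over the half-open window ``[t0, t1)``."""
        i0, i1 = self.slice_indices(t0, t1)
        if i1 <= i0:
            raise ValidationError(f"window [{t0}, {t1}) has no samples")
        return float(self.values[i0:i1].mean())

    def with_values(self, values: np.ndarray) -> "RateTrace":
        return replace(self, values=np.asarray(values, dtype=float))
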