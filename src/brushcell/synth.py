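"""Synthetic MF stimulus protocols and a phenomenological UBC continuum model.

The generator has two halves:

* **Stimulus builders** reproduce the protocols used to probe UBCs:
  100 spk/s bursts of 1-20 stimuli, smooth-pursuit-like trains (constant
  baseline stimulation with 1 s rate steps every few seconds), and
  in-vivo-like trains of brief high-frequency bursts.

* **Response model**: a linear-nonlinear cascade with three receptor
  components. Each MF stimulus drives (i) a fast AMPAR kernel (difference of
  exponentials) with strong short-term depression, (ii) a slow excitatory
  mGluR1 pathway gated by a Hill function of accumulated glutamate — so
  single stimuli are ineffective but bursts saturate — and (iii) an
  inhibitory mGluR2/3 kernel with a slow (G-protein-timescale) rise. The
  firing intensity is

      lambda(t) = max(0, r0 + a_A*x_A(t) + a_1*x_1(t) - a_2*x_2(t))

  Rectification is the only nonlinearity applied after summation, so
  component contributions superpose exactly wherever lambda > 0, and
  "blocking" a receptor (zeroing its weight) mimics antagonist wash-in.

A single continuum coordinate ``c`` in [0, 1] maps onto the fast-ON
(``c = 0``: strong AMPAR, no spontaneous firing) to slow/OFF (``c = 1``:
strong mGluR2/3, spontaneously active, slow mGluR1 kinetics) spectrum
observed across the UBC population.

Spike trains are drawn from the intensity by inhomogeneous-Poisson thinning
with an absolute refractory period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .types import Annotation, RateTrace, SpikeTrain, StimulusPattern, ValidationError

__all__ = [
    "ReceptorParams",
    "make_burst_pattern",
    "make_step_protocol",
    "make_invivo_burst_train",
    "continuum_params",
    "apply_block",
    "response_intensity",
    "response_components",
    "sample_trials",
    "BLOCKABLE_RECEPTORS",
]

BLOCKABLE_RECEPTORS = ("mGluR2/3", "AMPAR", "mGluR1")

# Continuum-model package constants (spk/s unless noted). These are design
# constants of the generator, documented in docs/methods.md; they are tunable
# and are not measured quantities.
A_MAX = 180.0     # AMPAR weight of the fastest cell
AMPAR_EXPONENT = 2.0  # a_A falls off as (1 - c)**2 along the continuum
G2_MAX = 10.0     # mGluR2/3 weight (per unit-peak kernel) of the slowest cell
R_MAX = 20.0      # spontaneous rate of the slowest (OFF) cell
A1_WEIGHT = 300.0  # mGluR1 weight, constant across the continuum
K_G = 2.5         # glutamate half-activation of the mGluR1 Hill gate (a.u.)
N_HILL = 3.0      # Hill coefficient of the mGluR1 gate
TAU1_MIN = 0.2    # s, mGluR1 output kernel decay at c = 0
TAU1_MAX = 4.0    # s, mGluR1 output kernel decay at c = 1
TAU_G_MIN = 0.25  # s, glutamate clearance at c = 0
TAU_G_SLOPE = 0.4  # s, extra clearance time at c = 1


@dataclass(frozen=True)
class ReceptorParams:
    """Parameters of the three-receptor UBC continuum model.

    Weights are in spk/s per unit kernel; time constants in seconds.
    ``blocked`` receptors contribute exactly zero to the intensity.
    """

    c: float = 0.0             # continuum coordinate, 0 = fast ON, 1 = slow OFF
    r0: float = 0.0            # spontaneous drive, spk/s
    a_A: float = A_MAX         # AMPAR weight
    tau_A_rise: float = 0.005
    tau_A_decay: float = 0.1
    u_dep: float = 0.9         # per-stimulus depression fraction
    tau_D: float = 0.6         # depression recovery
    a_1: float = A1_WEIGHT     # mGluR1 weight
    tau_g: float = 0.45        # glutamate accumulation decay
    K_g: float = K_G           # half-activation of accumulation (a.u.)
    n_hill: float = N_HILL
    tau_1: float = TAU1_MIN    # mGluR1 output kernel decay
    a_2: float = 0.0           # mGluR2/3 weight
    tau_2_rise: float = 0.08   # mGluR2/3 kernel rise (G-protein onset)
    tau_2: float = 1.0         # mGluR2/3 kernel decay
    t_ref: float = 0.002       # absolute refractory period
    blocked: frozenset = field(default_factory=frozenset)
    rebound: bool = False      # optional slow AMPAR rebound after bursts

    def __post_init__(self):
        object.__setattr__(self, "blocked", frozenset(self.blocked))
        for name in ("tau_A_rise", "tau_A_decay", "tau_D", "tau_g",
                     "tau_1", "tau_2", "tau_2_rise"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.tau_A_rise < self.tau_A_decay:
            raise ValidationError("tau_A_rise must be < tau_A_decay")
        if not self.tau_2_rise < self.tau_2:
            raise ValidationError("tau_2_rise must be < tau_2")
        for name in ("r0", "a_A", "a_1", "a_2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.u_dep <= 1.0:
            raise ValidationError("u_dep must be in [0, 1]")
        if self.n_hill < 1:
            raise ValidationError("n_hill must be >= 1")
        if self.t_ref < 0:
            raise ValidationError("t_ref must be >= 0")
        unknown = self.blocked - set(BLOCKABLE_RECEPTORS)
        if unknown:
            raise ValidationError(f"cannot block {sorted(unknown)}")


def continuum_params(c: float) -> ReceptorParams:
    """Map the continuum coordinate ``c`` in [0, 1] to model parameters.

    The AMPAR weight fades as ``(1 - c)**2`` — intermediate and slow cells
    have weak spike-timing responses — while the mGluR2/3 weight and the
    spontaneous rate grow linearly with ``c`` (OFF cells are spontaneously
    active). The mGluR1 kernel slows geometrically from 0.2 s to 4 s, and
    glutamate clearance slows modestly along the continuum.
    """
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"continuum coordinate c={c} outside [0, 1]")
    return ReceptorParams(
        c=c,
        r0=R_MAX * c,
        a_A=A_MAX * (1.0 - c) ** AMPAR_EXPONENT,
        a_2=G2_MAX * c,
        tau_1=TAU1_MIN * (TAU1_MAX / TAU1_MIN) ** c,
        tau_g=TAU_G_MIN + TAU_G_SLOPE * c,
    )


def apply_block(params: ReceptorParams, receptor: str) -> ReceptorParams:
    """Return params with ``receptor`` antagonized (idempotent, set-like)."""
    if receptor not in BLOCKABLE_RECEPTORS:
        raise ValidationError(
            f"unknown receptor {receptor!r}; expected one of {BLOCKABLE_RECEPTORS}"
        )
    return dataclasses.replace(params, blocked=params.blocked | {receptor})


# ---------------------------------------------------------------------------
# Stimulus builders


def make_burst_pattern(
    n_stimuli: int, rate: float, t0: float, protocol_id: str | None = None
) -> StimulusPattern:
    """A burst of ``n_stimuli`` stimuli at ``rate`` spk/s starting at ``t0``."""
    if n_stimuli < 1:
        raise ValidationError("n_stimuli must be >= 1")
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    times = t0 + np.arange(n_stimuli) / rate
    eps = 1e-6
    ann = Annotation("burst", t0, t0 + (n_stimuli - 1) / rate + eps, nominal_rate=rate)
    if protocol_id is None:
        protocol_id = f"burst{n_stimuli}x{rate:g}"
    return StimulusPattern(times, (ann,), protocol_id)


def make_step_protocol(
    baseline_rate: float,
    step_rates,
    step_duration: float = 1.0,
    interval: float = 4.0,
    lead: float = 4.0,
    tail: float = 4.0,
    protocol_id: str | None = None,
) -> StimulusPattern:
    """Smooth-pursuit-like train: constant ``baseline_rate`` stimulation with
    ``step_duration``-long steps to each of ``step_rates``.

    Step onsets are ``interval`` apart (the first after ``lead`` seconds of
    baseline). During a step, stimuli run at the step rate phase-aligned to
    the onset; afterwards the baseline resumes on its own absolute grid.
    """
    step_rates = list(step_rates)
    if baseline_rate < 0:
        raise ValidationError("baseline_rate must be >= 0")
    if any(r <= baseline_rate for r in step_rates):
        raise ValidationError("step rates must exceed the baseline rate")
    if step_duration <= 0 or interval <= 0:
        raise ValidationError("step_duration and interval must be > 0")
    if step_duration >= interval:
        raise ValidationError("step_duration must be < interval")
    total = lead + len(step_rates) * interval + tail
    onsets = [lead + k * interval for k in range(len(step_rates))]
    steps = list(zip(onsets, step_rates))

    times: list[float] = []
    if baseline_rate > 0:
        period = 1.0 / baseline_rate
        grid = np.arange(0.0, total, period)
        in_step = np.zeros(grid.size, dtype=bool)
        for onset, _ in steps:
            in_step |= (grid >= onset) & (grid < onset + step_duration)
        times.extend(grid[~in_step])
    for onset, rate in steps:
        n = int(round(rate * step_duration))
        times.extend(onset + np.arange(n) / rate)
    times = np.unique(np.asarray(times, dtype=float))

    annotations = [Annotation("baseline", 0.0, total, nominal_rate=baseline_rate)]
    for onset, rate in steps:
        annotations.append(
            Annotation("step", onset, onset + step_duration, nominal_rate=rate)
        )
    if protocol_id is None:
        rates_txt = "-".join(f"{r:g}" for r in step_rates) or "none"
        protocol_id = f"steps{baseline_rate:g}to{rates_txt}"
    return StimulusPattern(times, tuple(annotations), protocol_id)


def make_invivo_burst_train(
    duration: float,
    burst_size_range=(2, 23),
    intra_burst_rate: float = 300.0,
    burst_rate: float = 0.5,
    seed: int = 0,
    protocol_id: str | None = None,
) -> StimulusPattern:
    """In-vivo-like MF train: bursts of 2-23 stimuli at very high frequency,
    with burst onsets from a seeded exponential renewal process."""
    lo, hi = int(burst_size_range[0]), int(burst_size_range[1])
    if not (2 <= lo <= hi):
        raise ValidationError("burst sizes must satisfy 2 <= min <= max")
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    times: list[float] = []
    annotations: list[Annotation] = []
    t = rng.exponential(1.0 / burst_rate)
    prev_end = -np.inf
    while t < duration:
        onset = max(t, prev_end + 1e-3)  # keep consecutive bursts disjoint
        size = int(rng.integers(lo, hi + 1))
        burst = onset + np.arange(size) / intra_burst_rate
        times.extend(burst)
        span = (size - 1) / intra_burst_rate + 1e-6
        annotations.append(
            Annotation("burst", onset, onset + span, nominal_rate=intra_burst_rate)
        )
        prev_end = onset + span
        t += rng.exponential(1.0 / burst_rate)
    if protocol_id is None:
        protocol_id = f"invivo{duration:g}s"
    return StimulusPattern(
        np.asarray(times, dtype=float), tuple(annotations), protocol_id
    )


# ---------------------------------------------------------------------------
# Intensity model


def _alpha_kernel(t, tau_rise, tau_decay):
    """Difference of exponentials normalized to unit peak, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * np.log(tau_decay / tau_rise))
    norm = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.where(
        t >= 0, np.exp(-np.clip(t, 0, None) / tau_decay)
        - np.exp(-np.clip(t, 0, None) / tau_rise), 0.0
    )
    return out / norm


def depression_factors(stim_times, u_dep, tau_D):
    """Per-stimulus depression multipliers D_k (D_0 = 1).

    After each stimulus the available resource drops by the fraction
    ``u_dep`` and recovers exponentially with ``tau_D``:
    D_{k+1} = 1 - (1 - D_k*(1 - u_dep)) * exp(-dt/tau_D).
    """
    stim_times = np.asarray(stim_times, dtype=float)
    D = np.empty(stim_times.size)
    if not D.size:
        return D
    D[0] = 1.0
    for k in range(stim_times.size - 1):
        dt = stim_times[k + 1] - stim_times[k]
        D[k + 1] = 1.0 - (1.0 - D[k] * (1.0 - u_dep)) * np.exp(-dt / tau_D)
    return D


def _stim_counts(stim_times, t_grid0, dt, n):
    """Per-bin stimulus counts on the grid (stimuli binned to floor index)."""
    idx = np.floor((np.asarray(stim_times) - t_grid0) / dt + 1e-9).astype(int)
    counts = np.zeros(n)
    ok = (idx >= 0) & (idx < n)
    np.add.at(counts, idx[ok], 1.0)
    return counts


def _exp_filter(x, tau, dt, unit_area: bool):
    """First-order exponential filter.

    With ``unit_area`` the DC gain is 1 (smoothing kernel); otherwise each
    unit input produces a unit-peak decaying exponential.
    """
    a = np.exp(-dt / tau)
    b = (1.0 - a) if unit_area else 1.0
    return lfilter([b], [1.0, -a], x)


def response_components(
    params: ReceptorParams,
    pattern: StimulusPattern,
    grid_dt: float = 1e-3,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> dict:
    """Weighted component drives on the grid, before rectification.

    Returns a dict with keys ``"t0"``, ``"dt"``, ``"AMPAR"``, ``"mGluR1"``,
    ``"mGluR2/3"`` (signed contributions in spk/s; the mGluR2/3 entry is
    negative) and ``"r0"``. Blocked components are identically zero.
    """
    if grid_dt > 1e-3 + 1e-12:
        raise ValidationError("grid_dt must be <= 1 ms")
    if t_stop is None:
        t_stop = pattern.t_last + 10.0
    n = int(np.ceil((t_stop - t_start) / grid_dt - 1e-9))
    t = t_start + grid_dt * np.arange(n)
    stims = pattern.stimulus_times

    x_A = np.zeros(n)
    if "AMPAR" not in params.blocked and params.a_A > 0 and stims.size:
        D = depression_factors(stims, params.u_dep, params.tau_D)
        for tk, dk in zip(stims, D):
            i0 = max(int(np.floor((tk - t_start) / grid_dt)), 0)
            if i0 >= n:
                continue
            x_A[i0:] += dk * _alpha_kernel(
                t[i0:] - tk, params.tau_A_rise, params.tau_A_decay
            )
        if params.rebound:
            # Slow rebound as AMPARs recover from desensitization while
            # glutamate lingers after each burst: a small, slow bump scaled
            # by how depressed the synapse was at burst end.
            for ann in pattern.by_kind("burst"):
                in_burst = (stims >= ann.t0) & (stims < ann.t1)
                if in_burst.sum() < 2:
                    continue
                d_end = D[np.flatnonzero(in_burst)[-1]]
                x_A += 0.3 * (1.0 - d_end) * _alpha_kernel(t - ann.t1, 0.05, 0.3)

    counts = _stim_counts(stims, t_start, grid_dt, n)

    x_1 = np.zeros(n)
    if "mGluR1" not in params.blocked and params.a_1 > 0 and stims.size:
        g = _exp_filter(counts, params.tau_g, grid_dt, unit_area=False)
        hill = g ** params.n_hill / (g ** params.n_hill + params.K_g ** params.n_hill)
        x_1 = _exp_filter(hill, params.tau_1, grid_dt, unit_area=True)

    x_2 = np.zeros(n)
    if "mGluR2/3" not in params.blocked and params.a_2 > 0 and stims.size:
        # unit-peak difference of exponentials: slow G-protein-style onset
        t_peak = (params.tau_2_rise * params.tau_2
                  / (params.tau_2 - params.tau_2_rise)
                  * np.log(params.tau_2 / params.tau_2_rise))
        norm = np.exp(-t_peak / params.tau_2) - np.exp(-t_peak / params.tau_2_rise)
        x_2 = (
            _exp_filter(counts, params.tau_2, grid_dt, unit_area=False)
            - _exp_filter(counts, params.tau_2_rise, grid_dt, unit_area=False)
        ) / norm

    return {
        "t0": t_start,
        "dt": grid_dt,
        "AMPAR": params.a_A * x_A,
        "mGluR1": params.a_1 * x_1,
        "mGluR2/3": -params.a_2 * x_2,
        "r0": params.r0,
    }


def response_intensity(
    params: ReceptorParams,
    pattern: StimulusPattern,
    grid_dt: float = 1e-3,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> RateTrace:
    """Noiseless firing intensity lambda(t) of the model cell (spk/s)."""
    comp = response_components(params, pattern, grid_dt, t_start, t_stop)
    lam = comp["r0"] + comp["AMPAR"] + comp["mGluR1"] + comp["mGluR2/3"]
    return RateTrace(comp["t0"], comp["dt"], np.clip(lam, 0.0, None))


# ---------------------------------------------------------------------------
# Point-process sampling


def sample_trials(
    intensity: RateTrace,
    t_ref: float = 0.0,
    n_trials: int = 1,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Sample spike trains from an intensity by Poisson thinning with an
    absolute refractory period.

    Each trial uses an independent substream derived from ``(seed, trial)``,
    so individual trials are reproducible.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if t_ref < 0:
        raise ValidationError("t_ref must be >= 0")
    lam_max = float(intensity.values.max()) if intensity.values.size else 0.0
    t0, t_stop = intensity.t0, intensity.t_stop
    duration = t_stop - t0
    t_grid = intensity.times
    trains = []
    for trial in range(n_trials):
        rng = np.random.default_rng([seed, trial])
        if lam_max <= 0:
            trains.append(SpikeTrain(np.array([]), trial, t0, t_stop))
            continue
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(t0, t_stop, n_cand))
        u = rng.uniform(0.0, 1.0, n_cand)
        lam = np.interp(cand, t_grid, intensity.values)
        accepted = cand[u * lam_max < lam]
        if t_ref > 0 and accepted.size:
            kept = [accepted[0]]
            for s in accepted[1:]:
                if s - kept[-1] >= t_ref:
                    kept.append(s)
            accepted = np.asarray(kept)
        trains.append(SpikeTrain(accepted, trial, t0, t_stop))
    return trains
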