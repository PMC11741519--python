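# Methods

This note documents the models, estimators, and numerical choices behind
`brushcell`: what each stage assumes, which knobs matter, and what the
synthetic generator does and does not emulate.

All times are seconds; all rates are spikes per second (spk/s). Annotated
intervals are half-open `[t0, t1)`, so "during" and "after" windows
partition time with no double counting.

## Rate estimation

The instantaneous firing rate of a single trial is the reciprocal of the
inter-spike interval (ISI) containing each time point, sampled on a
uniform grid (default `dt` = 1 ms). It is parameter-free and reproduces
the stepped appearance of single-trial cell-attached traces. The rate is
defined as 0 before the first and after the last spike — a loose-seal
recording carries no rate information there — and trains with fewer than
two spikes give an all-zero trace. A Gaussian-kernel estimator
(`method="kernel"`) is available but is not the default.

Trial averaging applies a temporal running median (default 21 samples)
to each trial's trace and then takes the pointwise mean across trials.
A pointwise median across trials is available as an option
(`trial_combine="median"`). The running median uses edge replication.

Reciprocal-ISI averages retain narrow spikes wherever two spikes happen
to fall close together (a 4 ms ISI reads as 250 spk/s). Threshold-crossing
measurements (half-width, pause) are sensitive to these, so the analysis
pipeline median-smooths the *averaged* trace (default 301 samples,
~0.3 s) before computing metrics. The window was chosen to span several
ISIs at plausible peak rates while leaving sub-second response envelopes
intact; it is a parameter (`smooth_window`) and can be set to 1 to
disable smoothing. The `preprocess_trials` primitive itself is left
exactly as defined above so that its behavior is independently testable.

## Burst metrics

For a burst with stimulation window `[onset, end)`:

- **baseline** — mean rate over `[onset - 1 s, onset)`;
- **peak** — maximum rate in `(end, end + T_search]`, `T_search` = 4 s by
  default (the longest responses span seconds); an option includes the
  stimulation period for cells that fire during the burst;
- **half-width** — time between the first up-crossing and the first
  subsequent down-crossing of baseline + half the peak change, linearly
  interpolated between grid samples, ties broken earliest;
- **pause** — time from stimulation end until the rate first reaches
  θ = min(5 spk/s, peak/2). Cells with zero baseline rate get an
  undefined pause ("recovery" presupposes baseline firing); cells whose
  rate never drops below θ get 0;
- **response start** — first time the rate exceeds baseline + 10% of the
  peak change (the 10% fraction is configurable and reported, so it is
  auditable);
- **evoked spikes** — trapezoid integral of the rate over
  `[onset, response_start + 2 × half_width)` minus baseline × window
  length. When the half-width is undefined a flagged 2 s fallback window
  is used; windows reaching past the trace are truncated and flagged.

For constant-rate protocols (1, 2.5, 5 spk/s), responses are averaged
over stimulus-aligned segments excluding the first five stimuli, and the
peak and time integral of the mean segment are reported without baseline
correction.

## Step metrics

Steps are 1 s elevations of a constant-rate baseline train. Spikes during
the step and in the 3 s after are integrals corrected by the mean rate in
the 1 s preceding the step. Time to peak comes from a least-squares fit
of `A*exp{-[(ln t - mu)/sigma]^2}` to the baseline-subtracted response
(`t` = time since step onset; samples at `t <= dt` are excluded because
of the `ln t` singularity). The fit is multi-start — the empirical
argmax plus a four-point log-spaced grid of candidate peak locations —
with an analytic Jacobian; `fit_ok` is false when the response peak is
below 8 spk/s (no significant increase in firing; the same threshold
used for population sorting) or the optimizer fails.

Half-decay is measured on a trace where the response to each baseline
stimulus is excised: samples in a 100 ms window after each baseline
stimulus are replaced by linear interpolation between the neighboring
samples (overlapping windows merge; the operation is idempotent because
anchor samples lie outside every excised interval). The half-decay time
is the first time after the peak that the excised trace falls to baseline
plus half the baseline-corrected peak, referenced to the step offset and
clamped at 0. The 100 ms excision window and the 3 s fit window are
explicit knobs; neither has a canonical value.

## Population analysis

Cells whose reference-burst (20 stimuli at 100 spk/s) peak change
strictly exceeds 8 spk/s are ordered by ascending half-width; the rest
follow, ordered by ascending pause duration. The sort is stable, ties
break by cell id, and missing keys place a cell last in its group with a
flag. Heatmap rows are normalized per cell to the peak of a chosen
reference protocol (or each row's own peak); the normalization choice
changes values, never ordering.

The receptor decomposition follows the cumulative wash-in design
(mGluR2/3 blocked first, then AMPARs, then mGluR1s). Each receptor's
percentage of the evoked spikes is estimated from the drop in spike count
when it is blocked, relative to the stage immediately before the block;
a common-denominator variant (the mGluR2/3-blocked count for both
percentages) is available. Percentages are undefined when the denominator
stage has fewer than 5 evoked spikes; negative values are legitimate (a
block can increase firing). Because each stage's evoked count uses that
stage's own integration window, percentages can exceed 100 or go negative
when a block reshapes the response rather than scaling it.

Paired comparisons use a two-sided Wilcoxon signed-rank test with zero
differences dropped: an exact permutation null (dynamic programming over
doubled ranks, valid under ties) for n ≤ 25 and a normal approximation
with continuity and tie corrections above. Correlations use Spearman's
coefficient (average ranks, Student-t p-value approximation). Raw
p-values are reported; Holm adjustment is left to the caller. Both
statistics are implemented in-package with fixed conventions and are
cross-checked against scipy in the test suite.

## The synthetic continuum model

The generator exists so that every pipeline stage has a ground truth. It
is a phenomenological linear-nonlinear cascade, not a biophysical model:

    lambda(t) = max(0, r0 + a_A*x_A(t) + a_1*x_1(t) - a_2*x_2(t))

- **AMPAR** (`x_A`): per-stimulus difference-of-exponentials kernel
  (rise 5 ms, decay 100 ms, unit peak) scaled by a depression variable
  `D_k` with near-complete per-stimulus depression
  (`u_dep` = 0.9, recovery `tau_D` = 0.6 s):
  `D_{k+1} = 1 - (1 - D_k (1 - u_dep)) exp(-Δt/tau_D)`, `D_0` = 1.
  Strong depression reflects the pronounced desensitization at this
  synapse during 100 spk/s trains and makes fast-cell peaks roughly
  burst-length independent. An optional `rebound` flag adds a small slow
  post-burst bump (AMPARs recovering from desensitization while
  glutamate lingers); it is off by default to keep the model minimal.
- **mGluR1** (`x_1`): stimuli increment a glutamate accumulator `g`
  (decay `tau_g`); a Hill gate `g^n/(g^n + K_g^n)` with `K_g` = 2.5,
  `n` = 3 makes single stimuli ineffective while bursts of ≥5 stimuli
  saturate; the gated drive is smoothed by a unit-area exponential
  kernel `tau_1`, so slow cells' excitation builds and decays over
  seconds without changing its total weight.
- **mGluR2/3** (`x_2`): per-stimulus unit-peak difference of
  exponentials with an 80 ms rise and 1 s decay — the slow onset of a
  G-protein → GIRK pathway — summed linearly.

Rectification is the only nonlinearity applied after summation, so
component contributions superpose exactly wherever the rate is positive,
and "blocking" a receptor (zeroing its weight) is exact. This makes the
decomposition testable against ground truth.

One coordinate `c` in [0, 1] spans the population:

| parameter | mapping | meaning |
|---|---|---|
| `a_A` | `180 (1-c)^2` spk/s | AMPAR weight, fades quickly past mid-continuum |
| `a_2` | `10 c` spk/s | mGluR2/3 weight |
| `r0`  | `20 c` spk/s | spontaneous drive (OFF cells fire at rest) |
| `tau_1` | `0.2 (4/0.2)^c` s | mGluR1 kernel, geometric 0.2 → 4 s |
| `tau_g` | `0.25 + 0.4 c` s | glutamate clearance, slower in slow cells |

with `a_1` = 300 spk/s constant. These constants were chosen once so
that the model reproduces the qualitative population phenotype: fast
cells peak above 100 spk/s even for 1-2 stimuli with roughly flat peaks
across burst lengths; mid and slow cells' peaks grow monotonically with
burst duration; half-width and pause duration grow along the continuum;
OFF cells are silenced for well over half a second after a 20-stimulus
burst and pause for about a second. The quadratic AMPAR fade-out, the
slow mGluR2/3 rise, the steep Hill gate, and the `c`-dependent clearance
are all needed for those monotonicities to hold simultaneously; with a
linear AMPAR fade or an instant-rise inhibitory kernel, intermediate
cells' peak responses are non-monotone in burst length. The constants
are package constants, tunable per-cell, and are not measurements.
The half-width of the noiseless 20-stimulus response has a shallow local
dip near `c` ≈ 0.35 where the response shape hands over from an
AMPAR-dominated plateau to an mGluR1 peak; it is monotone on the
five-point grid {0, 0.25, 0.5, 0.75, 1} used by the tests.

Spike trains are drawn by Poisson thinning of the intensity with an
absolute refractory period (default 2 ms, enforced by deletion), with an
independent, reproducible random substream per (seed, trial).

### What the generator does not emulate

Real UBC recordings contain slow drift, bursty non-Poisson firing,
stimulation artifacts, wash-in instability, and NMDAR contributions; the
generator has none of these. Passing tests therefore demonstrate that the
*estimators and pipeline logic* are correct and that the model family can
express the published phenomenology — not that the model is a fitted
account of any recorded cell. Fitting `ReceptorParams` to data is
explicitly out of scope.

## Problem sizes and determinism

The standard validation cohort is 31 cells evenly spaced on the
continuum, 8 trials per cell, 1 ms grids over ~12 s of simulated time —
small enough that the whole suite and the acceptance script run in a few
minutes on one CPU. All stochastic steps take explicit integer seeds;
sub-seeds are derived with `numpy.random.SeedSequence` and kept below
2^31. Noiseless model computations are exactly reproducible; sampled
quantities are reproducible for a fixed seed.

## Known limitations

- The reciprocal-ISI estimator is biased upward at response peaks after
  averaging few trials; the pipeline's post-average median controls but
  does not remove this.
- Half-width is undefined for traces whose half-amplitude crossings do
  not exist (flat or purely suppressive responses); such cells are
  pause-sorted, as in the population analysis.
- The exact Wilcoxon null is conditional on the observed tie pattern;
  with many ties and n ≤ 25 it can differ from tables that assume
  distinct ranks.
- File readers target the package's own CSV dialects only; vendor
  formats (ABF, NWB, Igor) are out of scope.
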