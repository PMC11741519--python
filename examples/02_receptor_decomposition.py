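"""Decompose a UBC's burst responses into receptor components by
simulated antagonist wash-in.

Antagonists are applied cumulatively (mGluR2/3 -> AMPAR -> mGluR1), and
each receptor's share of the evoked spikes is estimated from the drop in
spike count when it is blocked. On noiseless model intensities the
decomposition is exact, so the printed percentages directly expose the
model's burst-length dependence: AMPARs carry short bursts, mGluR1 takes
over as bursts lengthen.
"""

from brushcell.pipeline import decompose_intensity
from brushcell.synth import continuum_params, make_burst_pattern

cell = continuum_params(0.4)  # intermediate cell with all three components
print("burst  n_baseline  n_mGluR2/3-  n_+AMPAR-  n_+mGluR1-   %AMPAR  %mGluR1")
for n in (1, 2, 5, 10, 20):
    pattern = make_burst_pattern(n, 100.0, 2.0)
    bd = decompose_intensity(cell, pattern)
    pct_a = "excl." if bd.pct_ampar is None else f"{bd.pct_ampar:6.1f}"
    pct_1 = "excl." if bd.pct_mglur1 is None else f"{bd.pct_mglur1:6.1f}"
    print(
        f"{n:5d}  {bd.n_baseline:10.1f}  {bd.n_mglur23_blocked:11.1f}  "
        f"{bd.n_ampar_blocked:9.1f}  {bd.n_mglur1_blocked:10.1f}  "
        f"{pct_a}  {pct_1}"
    )
print(
    "\nColumns are evoked-spike counts at each wash-in stage (baseline,"
    "\nmGluR2/3 blocked, +AMPAR blocked, +mGluR1 blocked). Percentages are"
    "\nthe spikes removed by each block relative to the stage before it;"
    "\nstages with fewer than 5 spikes are excluded. The AMPAR share falls"
    "\nand the mGluR1 share rises with burst duration."
)
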