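"""Simulate UBCs across the fast-ON -> slow-OFF continuum and quantify
their responses to the reference 20-stimulus, 100 spk/s mossy fiber burst.

Each cell is defined by a continuum coordinate c in [0, 1]: c = 0 is a
fast ON cell (strong AMPAR, silent at rest), c = 1 an OFF cell (strong
mGluR2/3, spontaneously active). We sample 8 cell-attached-like trials per
cell, estimate trial-averaged instantaneous firing rates, and print the
burst metrics used to order the population.
"""

import numpy as np
import pandas as pd

from brushcell.pipeline import (
    analyze_burst_recording,
    reference_burst_pattern,
    simulate_cell,
)
from brushcell.population import sort_population
from brushcell.synth import continuum_params

pattern = reference_burst_pattern()  # burst starts at t = 2 s
rows = []
for i, c in enumerate(np.linspace(0.0, 1.0, 7)):
    rec = simulate_cell(
        continuum_params(float(c)), pattern, n_trials=8, seed=100 + i,
        cell_id=f"c={c:.2f}",
    )
    row = analyze_burst_recording(rec)
    row["c"] = round(float(c), 2)
    rows.append(row)

table = sort_population(pd.DataFrame(rows))
cols = ["cell_id", "baseline_rate", "peak_change", "half_width",
        "pause_duration", "evoked_spikes"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nReading the table: along the continuum the baseline (spontaneous)"
    "\nrate rises, the peak response shrinks, the half-width of the firing"
    "\nincrease broadens from under a second to several seconds, and the"
    "\nslowest cells pause for around a second before firing again -"
    "\nthe fast-to-slow ordering the population heatmaps are sorted by."
)
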