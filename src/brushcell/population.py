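"""Population-level sorting, heatmap normalization, and the receptor-
component decomposition across cumulative antagonist conditions.

The UBC population is treated as a continuum: cells with a clear increase
in firing (peak change > 8 spk/s on the reference 20 x 100 spk/s burst) are
ordered by the half-width of that increase, fast to slow; the remaining
(OFF-like) cells follow, ordered by their pause duration.

The wash-in series blocks receptors cumulatively —
baseline -> +mGluR2/3 -> +AMPAR -> +mGluR1 — and each receptor's share of
the evoked spikes is estimated from the drop in spike count when it is
blocked, relative to the stage immediately before the block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import RateTrace, ValidationError

__all__ = [
    "PEAK_CHANGE_THRESHOLD",
    "MIN_SPIKES_FOR_PERCENTAGE",
    "sort_population",
    "normalize_for_heatmap",
    "component_percentage",
    "block_effect_ratio",
    "ComponentBreakdown",
    "washin_decomposition",
]

#: Cells whose reference-burst peak change exceeds this (spk/s) are sorted
#: by half-width; the rest by pause duration.
PEAK_CHANGE_THRESHOLD = 8.0

#: Component percentages are undefined when the denominator-stage response
#: has fewer evoked spikes than this.
MIN_SPIKES_FOR_PERCENTAGE = 5.0


def sort_population(table: pd.DataFrame, descending: bool = False) -> pd.DataFrame:
    """Order cells fast-to-slow and assign ``order_index``.

    ``table`` needs columns ``cell_id``, ``peak_change``, ``half_width``,
    ``pause_duration`` (metrics of the reference 20 x 100 spk/s burst).
    Cells with ``peak_change`` strictly above 8 spk/s come first, in
    ascending half-width; the rest follow in ascending pause duration.
    Missing sort keys place a cell last within its group (flagged in
    ``sort_key_missing``); ties break by ``cell_id``. ``descending``
    reverses the within-group key order (slow-to-fast display).
    """
    for col in ("cell_id", "peak_change", "half_width", "pause_duration"):
        if col not in table.columns:
            raise ValidationError(f"missing column {col!r}")
    df = table.copy()
    excitatory = df["peak_change"].to_numpy(dtype=float) > PEAK_CHANGE_THRESHOLD
    key = np.where(
        excitatory,
        df["half_width"].to_numpy(dtype=float),
        df["pause_duration"].to_numpy(dtype=float),
    )
    missing = ~np.isfinite(key)
    key = np.where(missing, np.inf, key)
    if descending:
        key = np.where(np.isfinite(key), -key, np.inf)
    df["sort_key"] = np.where(excitatory, "half_width", "pause_duration")
    df["sort_key_missing"] = missing
    order = sorted(
        range(len(df)),
        key=lambda i: (
            0 if excitatory[i] else 1,
            key[i],
            str(df["cell_id"].iloc[i]),
        ),
    )
    df = df.iloc[order].reset_index(drop=True)
    df["order_index"] = np.arange(len(df))
    return df


def normalize_for_heatmap(
    traces_by_cell: Mapping[str, Mapping[str, RateTrace]],
    order: Sequence[str],
    reference: str | None,
) -> tuple[dict[str, np.ndarray], dict[str, bool]]:
    """Build per-protocol heatmap matrices normalized per cell.

    ``reference`` names the protocol whose peak rate normalizes every row
    of a cell (e.g. the 20 x 100 spk/s burst, under whichever condition the
    traces were measured); ``None`` normalizes each row to its own peak.
    Rows are ordered by ``order`` (cell ids, e.g. from
    :func:`sort_population`). Cells whose reference peak is <= 0 are
    flagged and left unnormalized.
    """
    labels: list[str] = []
    for cell in order:
        for label in traces_by_cell[cell]:
            if label not in labels:
                labels.append(label)
    matrices: dict[str, np.ndarray] = {}
    flags: dict[str, bool] = {}
    for cell in order:
        if reference is not None:
            if reference not in traces_by_cell[cell]:
                raise ValidationError(f"cell {cell!r} lacks reference {reference!r}")
            ref_peak = float(traces_by_cell[cell][reference].values.max())
            flags[cell] = ref_peak <= 0.0
    for label in labels:
        rows = []
        for cell in order:
            trace = traces_by_cell[cell].get(label)
            if trace is None:
                raise ValidationError(f"cell {cell!r} lacks protocol {label!r}")
            vals = trace.values
            if reference is None:
                peak = float(vals.max())
                flags.setdefault(cell, False)
                if peak > 0:
                    vals = vals / peak
                else:
                    flags[cell] = True
            else:
                ref_peak = float(traces_by_cell[cell][reference].values.max())
                if ref_peak > 0:
                    vals = vals / ref_peak
            rows.append(vals)
        matrices[label] = np.vstack(rows)
    return matrices, flags


def component_percentage(n_before: float, n_after: float) -> float | None:
    """Percentage of the evoked spikes removed by blocking a receptor:
    ``100 * (n_before - n_after) / n_before``.

    Undefined (None) when the pre-block response is smaller than 5 spikes.
    Negative values are permitted (the block increased firing).
    """
    if n_before < MIN_SPIKES_FOR_PERCENTAGE:
        return None
    return 100.0 * (n_before - n_after) / n_before


def block_effect_ratio(
    n_baseline: float, n_blocked: float, n_reference: float
) -> tuple[float, float] | None:
    """Spike counts before/after a block, each normalized to the cell's
    reference-protocol baseline count. None when the reference is <= 0."""
    if n_reference <= 0:
        return None
    return (n_baseline / n_reference, n_blocked / n_reference)


@dataclass(frozen=True)
class ComponentBreakdown:
    """Receptor decomposition of one cell/protocol-item from the cumulative
    wash-in series (stages: baseline, +mGluR2/3 block, +AMPAR block,
    +mGluR1 block)."""

    n_baseline: float
    n_mglur23_blocked: float
    n_ampar_blocked: float
    n_mglur1_blocked: float
    mglur23_ratio: float | None   # n after mGluR2/3 block / n at baseline
    pct_ampar: float | None       # % of spikes removed by blocking AMPARs
    pct_mglur1: float | None      # % removed by additionally blocking mGluR1s
    excluded: bool                # True when both percentages are undefined


def washin_decomposition(
    n_baseline: float,
    n_mglur23_blocked: float,
    n_ampar_blocked: float,
    n_mglur1_blocked: float,
    denominator: str = "pre-block",
) -> ComponentBreakdown:
    """Decompose evoked-spike counts across the wash-in series.

    With ``denominator="pre-block"`` (default) each component is estimated
    from the effect of blocking it on the then-current response:
    pct_ampar uses the mGluR2/3-blocked count, pct_mglur1 the
    mGluR2/3+AMPAR-blocked count. ``denominator="mglur23-blocked"`` uses
    the common mGluR2/3-blocked count for both. The <5 spike exclusion
    applies to the denominator stage.
    """
    if denominator not in ("pre-block", "mglur23-blocked"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    pct_ampar = component_percentage(n_mglur23_blocked, n_ampar_blocked)
    if denominator == "pre-block":
        pct_mglur1 = component_percentage(n_ampar_blocked, n_mglur1_blocked)
    else:
        if n_mglur23_blocked < MIN_SPIKES_FOR_PERCENTAGE:
            pct_mglur1 = None
        else:
            pct_mglur1 = (
                100.0 * (n_ampar_blocked - n_mglur1_blocked) / n_mglur23_blocked
            )
    ratio = (
        n_mglur23_blocked / n_baseline if n_baseline > 0 else None
    )
    return ComponentBreakdown(
        n_baseline=n_baseline,
        n_mglur23_blocked=n_mglur23_blocked,
        n_ampar_blocked=n_ampar_blocked,
        n_mglur1_blocked=n_mglur1_blocked,
        mglur23_ratio=ratio,
        pct_ampar=pct_ampar,
        pct_mglur1=pct_mglur1,
        excluded=pct_ampar is None and pct_mglur1 is None,
    )
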