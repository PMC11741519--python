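"""Nonparametric statistics used for paired pharmacology comparisons.

Both tests are implemented here so their conventions are explicit and
fixed: the Wilcoxon signed-rank test drops zero differences, uses the
exact permutation null (dynamic programming over rank sums, valid with
ties) for n <= 25 and a normal approximation with continuity and tie
corrections above; Spearman's correlation uses average ranks for ties and
a Student-t approximation for the p-value.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .types import ValidationError

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank",
           "SpearmanResult", "spearman_correlation"]


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int       # pairs after dropping zero differences
    all_tied: bool


def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p for doubled ranks ``ranks2`` and doubled observed
    positive-rank sum ``w2``; enumerates all sign assignments by DP."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[:-r] if r else counts
    n_assign = counts.sum()  # 2^n
    p_le = counts[: w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon's convention). With every pair
    tied the test is degenerate: p = 1, flagged via ``all_tied``.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("pairs must be a sequence of (value, value)")
    d = pairs[:, 1] - pairs[:, 0]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, True)
    ranks = rankdata(np.abs(d))  # average ranks; doubled they are integers
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2 = int(np.rint(2.0 * w_plus))
        p = _exact_signed_rank_p(ranks2, w2)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(w_plus, 1.0, n, True)
        dev = w_plus - mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        from scipy.stats import norm

        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, float(p), n, False)


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    defined: bool


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a t-approximation p-value.

    Constant input vectors leave the correlation undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), False)
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return SpearmanResult(float(np.sign(rho)), 0.0, True)
    t_stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return SpearmanResult(rho, min(p, 1.0), True)
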