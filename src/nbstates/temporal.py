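"""Dwell-time and volatility statistics of hard-assigned state sequences.

A dwell spell is a maximal run of consecutive timepoints assigned to one
state, converted to seconds via the TR.  Statistics are pooled across a
model's states (one mean/sd pair per region-network combination); local
volatility is the sample sd of per-segment mean dwell times with runs
truncated at segment edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import check_partition


def dwell_times(state_seq, tr_seconds: float) -> dict[int, list[float]]:
    """Per-state dwell spell lists (seconds), in temporal order."""
    seq = np.asarray(state_seq, dtype=int)
    if seq.size == 0:
        raise ValueError("state sequence is empty")
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [seq.size]])
    spells: dict[int, list[float]] = {int(k): [] for k in np.unique(seq)}
    for a, b in zip(starts, ends):
        spells[int(seq[a])].append((b - a) * tr_seconds)
    return spells


def dwell_summary(spells: dict[int, list[float]]) -> tuple[float, float]:
    """Pooled (mean, sample sd) over all spells of all states."""
    pooled = [d for lst in spells.values() for d in lst]
    if not pooled:
        raise ValueError("no dwell spells")
    arr = np.asarray(pooled, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def local_volatility(state_seq, segment_bounds, tr_seconds: float) -> float:
    """Sample sd of per-segment mean dwell times (runs truncated at edges)."""
    seq = np.asarray(state_seq, dtype=int)
    bounds = check_partition(segment_bounds, seq.size)
    if len(bounds) < 2:
        raise ValueError("need at least 2 segments for local volatility")
    means = []
    for a, b in bounds:
        spells = dwell_times(seq[a:b], tr_seconds)
        means.append(dwell_summary(spells)[0])
    return float(np.asarray(means).std(ddof=1))


def group_dwell_table(
    solutions: dict[tuple, "object"],
    segment_bounds,
    tr_seconds: float,
) -> pd.DataFrame:
    """Long-format dwell summary: one row per (subject, combination).

    ``solutions`` maps (subject_id, combination_name) to a fitted
    :class:`~nbstates.hmm.HMMSolution`.  With the study layout of 15
    subjects x 14 combinations this yields 210 rows.
    """
    from .hmm import hard_assign

    rows = []
    for (subject_id, combination), sol in sorted(solutions.items()):
        seq = hard_assign(sol.gamma)
        spells = dwell_times(seq, tr_seconds)
        mean, sd = dwell_summary(spells)
        vol = local_volatility(seq, segment_bounds, tr_seconds)
        rows.append(
            {
                "subject": subject_id,
                "combination": combination,
                "mean_dwell_s": mean,
                "sd_dwell_s": sd,
                "volatility_s": vol,
            }
        )
    return pd.DataFrame(rows)
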