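"""Shared helpers: seeding, validation, TSV round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def check_matrix(x, name: str = "X", ndim: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def check_partition(segment_bounds, n_timepoints: int) -> list[tuple[int, int]]:
    """Validate that half-open intervals partition [0, n_timepoints)."""
    bounds = sorted((int(a), int(b)) for a, b in segment_bounds)
    cursor = 0
    for a, b in bounds:
        if a != cursor or b <= a:
            raise ValueError(
                f"segment bounds {bounds} do not partition [0, {n_timepoints})"
            )
        cursor = b
    if cursor != n_timepoints:
        raise ValueError(
            f"segment bounds {bounds} do not partition [0, {n_timepoints})"
        )
    return bounds


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
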