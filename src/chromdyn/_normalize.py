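"""Count normalisation and time-axis transforms shared across the pipeline.

All count tables use the same wide layout: rows are features, columns a
two-level MultiIndex ``(replicate, time_minutes)``. Normalisation is
library-size scaling to counts-per-million per sample, then ``log2(x + 1)``;
profile-level mean-centring happens at model-fit time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Sampling grid of the stimulation time course, in minutes.
TIME_GRID = (0, 20, 60, 120, 240, 1440)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) to counts-per-million of its library size.

    Zero-total columns are passed through unscaled rather than producing NaN.
    """
    lib = counts.sum(axis=0).astype(float)
    lib = lib.where(lib > 0, 1.0)
    return counts / lib * 1e6


def log2p1(x):
    """log2(x + 1) variance-stabilising transform."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """CPM per sample followed by log2(x + 1)."""
    return pd.DataFrame(
        log2p1(cpm(counts).to_numpy()), index=counts.index, columns=counts.columns
    )


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average a (replicate, time) MultiIndex column table over replicates.

    Returns a features x time-points table with plain integer time columns.
    """
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("expected (replicate, time) MultiIndex columns")
    out = table.T.groupby(level=1).mean().T
    return out[sorted(out.columns)]


def transform_times(minutes, mode: str = "log2"):
    """Map minutes to the model time axis.

    ``log2`` (default) uses log2(1 + minutes), de-compressing the long gap
    between 4 h and 24 h; ``hours`` uses the raw scale in hours.
    """
    m = np.asarray(minutes, dtype=float)
    if mode == "log2":
        return np.log2(1.0 + m)
    if mode == "hours":
        return m / 60.0
    raise ValueError(f"unknown time transform {mode!r}")
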