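"""Time-at-temperature (TAT) summaries.

Archival tags report, for each 12-hour window, the fraction of time spent in
a fixed set of temperature bins.  This module aggregates those records into
mean occupancy histograms (per tag or pooled) and threshold fractions such as
"fraction of time in water warmer than 22 degC".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Tag temperature bin boundaries in degC; the last bin is open-ended (>30).
TAT_BIN_EDGES = np.array([0.0, 5.0, 10.0, 15.0, 18.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0, np.inf])
N_TAT_BINS = len(TAT_BIN_EDGES) - 1  # 11


def tat_bin_columns() -> list[str]:
    """Column names for the 11 fraction columns, lower-closed bins."""
    cols = []
    for lo, hi in zip(TAT_BIN_EDGES[:-1], TAT_BIN_EDGES[1:]):
        cols.append(f"frac_gt_{lo:g}" if np.isinf(hi) else f"frac_{lo:g}_{hi:g}")
    return cols


def validate_tat(records: pd.DataFrame, tol: float = 1e-6) -> None:
    """Check that each record has 11 fractions in [0, 1] summing to 1."""
    cols = tat_bin_columns()
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"TAT records missing fraction columns: {missing}")
    frac = records[cols].to_numpy(dtype=float)
    if (frac < -tol).any() or (frac > 1 + tol).any():
        raise ValueError("TAT fractions must lie in [0, 1]")
    sums = frac.sum(axis=1)
    bad = np.abs(sums - 1.0) > tol
    if bad.any():
        raise ValueError(f"{int(bad.sum())} TAT record(s) do not sum to 1 within {tol}")


def aggregate_tat(records: pd.DataFrame, group: str = "pooled") -> pd.DataFrame:
    """Mean fraction per temperature bin.

    Because every window has the same 12-h length, the time-weighted mean is
    the simple mean over records.  ``group='per-tag'`` returns one row per
    tag; ``group='pooled'`` one row over all records.
    """
    if len(records) == 0:
        raise ValueError("no TAT records to aggregate")
    validate_tat(records)
    cols = tat_bin_columns()
    if group == "per-tag":
        out = records.groupby("tag_id", sort=True)[cols].mean().reset_index()
    elif group == "pooled":
        out = records[cols].mean().to_frame().T
        out.insert(0, "tag_id", "ALL")
    else:
        raise ValueError(f"unknown group {group!r}; use 'per-tag' or 'pooled'")
    return out


def fraction_above(aggregate: pd.DataFrame | pd.Series | np.ndarray, threshold: float) -> float:
    """Fraction of time in bins whose lower edge is at or above ``threshold``.

    ``threshold`` must coincide with a bin boundary; bins are lower-closed, so
    the value is the summed occupancy of all water strictly classified warmer
    than the boundary.
    """
    finite_edges = TAT_BIN_EDGES[:-1]
    if threshold not in finite_edges:
        raise ValueError(
            f"threshold {threshold} is not a TAT bin boundary; valid: {list(finite_edges)}"
        )
    if isinstance(aggregate, pd.DataFrame):
        if len(aggregate) != 1:
            raise ValueError("pass a single aggregate row (pooled or one tag)")
        frac = aggregate[tat_bin_columns()].to_numpy(dtype=float).ravel()
    elif isinstance(aggregate, pd.Series):
        frac = aggregate[tat_bin_columns()].to_numpy(dtype=float)
    else:
        frac = np.asarray(aggregate, dtype=float)
    if frac.shape != (N_TAT_BINS,):
        raise ValueError(f"aggregate must have {N_TAT_BINS} bin fractions")
    keep = finite_edges >= threshold
    return float(frac[keep].sum())
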