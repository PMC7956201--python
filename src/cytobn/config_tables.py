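"""Marker-configuration tables: frequency and response probability per
joint level tuple of the Markov-neighborhood markers.

With five ternary markers there are 3^5 = 243 possible configurations; the
table lists the observed ones with their empirical frequency and the raw
conditional responder fraction among the cells showing them (cells inherit
their patient's label; patients are pooled, unweighted).  Two sort orders
are provided — keep the most frequent rows then re-sort by response
probability, or sort everything by probability — plus a frequency-dropoff
rule for choosing how many rows to keep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .discretize import DiscretizedMatrix, discretize_matrix, equal_frequency_edges, apply_edges
from .io import CellMatrix

__all__ = ["ConfigTable", "build_config_table", "sort_table",
           "select_cutoff", "binary_marker_response"]

SORT_MODES = ("frequency_then_probability", "probability_only")


@dataclass
class ConfigTable:
    """Observed marker configurations with frequency and P(response | config).

    ``rows`` is a DataFrame with columns ``config`` (tuple of int levels),
    ``frequency`` and ``p_response``.  Pre-truncation, frequencies sum to 1
    and their p_response-weighted sum equals the overall responder-cell
    fraction (unsmoothed counts).
    """

    markers: list
    rows: pd.DataFrame
    sort_mode: str | None = None
    cutoff: int | None = None

    @property
    def n_configs_possible(self) -> int:
        return int(np.prod(self._cards))

    _cards: tuple = ()


def build_config_table(data: DiscretizedMatrix, markers, response=None) -> ConfigTable:
    """Count observed configurations of ``markers`` and the responder
    fraction among cells carrying each.  Unobserved configurations are
    omitted (a zero count has no defined conditional probability)."""
    markers = list(markers)
    missing = [m for m in markers if m not in data.labels.columns]
    if missing:
        raise ValueError(f"markers not in data: {missing}")
    if response is None:
        response = data.annotations["response"].to_numpy()
    response = np.asarray(response).astype(bool)
    if len(response) != len(data.labels):
        raise ValueError("response labels not aligned with cells")

    sub = data.labels[markers].to_numpy(dtype=np.int64)
    n = len(sub)
    grouped = pd.DataFrame(sub, columns=markers)
    grouped["__resp"] = response
    agg = grouped.groupby(markers, sort=True).agg(
        count=("__resp", "size"), resp=("__resp", "sum")).reset_index()
    rows = pd.DataFrame({
        "config": [tuple(int(x) for x in t) for t in agg[markers].itertuples(index=False)],
        "frequency": agg["count"] / n,
        "p_response": agg["resp"] / agg["count"],
    })
    table = ConfigTable(markers, rows)
    table._cards = tuple(data.cardinality(m) for m in markers)
    return table


def sort_table(table: ConfigTable, mode: str, top_n: int | None = None) -> ConfigTable:
    """Apply one of the two presentation orders.

    frequency_then_probability : keep the ``top_n`` most frequent
        configurations, then re-sort those by descending response
        probability (the headline-table layout).
    probability_only : sort all rows by descending response probability.

    p_response ties break toward the higher-frequency row.
    """
    if mode not in SORT_MODES:
        raise ValueError(f"unknown sort mode {mode!r}; expected one of {SORT_MODES}")
    rows = table.rows
    if mode == "frequency_then_probability":
        top_n = len(rows) if top_n is None else min(top_n, len(rows))
        kept = rows.sort_values(["frequency", "p_response"],
                                ascending=False, kind="mergesort").head(top_n)
        out = kept.sort_values(["p_response", "frequency"],
                               ascending=False, kind="mergesort")
    else:
        out = rows.sort_values(["p_response", "frequency"],
                               ascending=False, kind="mergesort")
        if top_n is not None:
            out = out.head(top_n)
    new = ConfigTable(table.markers, out.reset_index(drop=True), sort_mode=mode,
                      cutoff=top_n)
    new._cards = table._cards
    return new


def select_cutoff(frequencies, min_rel_drop: float = 0.15,
                  max_rows: int = 40) -> int:
    """Row count chosen at the first noticeable frequency dropoff.

    Given frequencies sorted descending, returns the smallest i <= max_rows
    with (f_i - f_{i+1}) / f_i >= min_rel_drop (1-based i), else max_rows.
    The default 0.15 flags a ~0.02 -> ~0.017 dropoff.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        return 0
    if np.any(np.diff(f) > 0):
        raise ValueError("frequencies must be sorted descending")
    limit = min(max_rows, f.size)
    for i in range(1, limit):
        if f[i - 1] > 0 and (f[i - 1] - f[i]) / f[i - 1] >= min_rel_drop:
            return i
    return limit


def binary_marker_response(cells: CellMatrix, marker: str,
                           response=None) -> tuple:
    """Responder fraction among high-bin vs low-bin cells of one marker
    under a two-bin equal-frequency split (median cut on the full sample).

    Returns ``(p_high, p_low)``.
    """
    if marker not in cells.values.columns:
        raise ValueError(f"unknown marker {marker!r}")
    if response is None:
        response = cells.annotations["response"].to_numpy()
    response = np.asarray(response).astype(bool)
    v = cells.values[marker].to_numpy()
    edges = equal_frequency_edges(v, marker, 2)
    labels = apply_edges(v, edges)
    high = labels == labels.max()
    if high.all() or not high.any():
        raise ValueError(f"degenerate two-bin split for marker {marker!r}")
    p_high = float(response[high].mean())
    p_low = float(response[~high].mean())
    return p_high, p_low
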