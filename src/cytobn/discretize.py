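"""Full-sample equal-frequency discretization of continuous markers.

Each marker is binned independently into k in [2, 8] bins whose edges are
the empirical quantiles of the *pooled* sample (all patients and cells in
scope), so that every bin holds approximately the same number of cells.
Label 0 is "low", k-1 is "high".

Quantiles are inverse-ECDF (type-1), so every edge is an observed data
value and identical raw values can never straddle a bin boundary: duplicate
quantiles caused by heavy ties are collapsed, reducing the effective bin
count for that marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellMatrix

__all__ = ["BinEdges", "DiscretizedMatrix", "equal_frequency_edges",
           "apply_edges", "discretize_matrix"]

K_MIN, K_MAX = 2, 8


@dataclass(frozen=True)
class BinEdges:
    """Interior cut points for one marker.

    ``edges`` has at most k-1 strictly ascending values; value v maps to the
    largest bin b such that v >= edges[b-1] (bin 0 when v < edges[0]).
    """

    marker: str
    edges: tuple
    k: int

    @property
    def n_bins(self) -> int:
        """Effective bin count after tie collapse."""
        return len(self.edges) + 1


@dataclass
class DiscretizedMatrix:
    """Integer bin labels (cells x variables) plus the edge map.

    Markers carry their :class:`BinEdges`; extra categorical variables
    (response labels, contrast indicators) appear in ``labels`` without an
    edge-map entry.  Annotations are carried over from the source
    :class:`~cytobn.io.CellMatrix`.
    """

    labels: pd.DataFrame
    edge_map: dict
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.annotations):
            raise ValueError("labels and annotations row counts differ")

    @property
    def variables(self) -> list[str]:
        return list(self.labels.columns)

    def cardinality(self, var: str) -> int:
        if var in self.edge_map:
            return self.edge_map[var].n_bins
        return int(self.labels[var].max()) + 1

    def cardinalities(self) -> dict:
        return {v: self.cardinality(v) for v in self.variables}


def equal_frequency_edges(values, marker: str, k: int) -> BinEdges:
    """Equal-frequency (quantile) cut points for one marker.

    Edge i is the inverse-ECDF quantile at i/k taken exclusively: the
    smallest observed value whose ECDF exceeds i/k (for distinct values,
    the first value of bin i).  Edges are therefore always data values;
    duplicates from heavy ties are collapsed.  Raises for constant input,
    where no binning exists.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if not (K_MIN <= k <= K_MAX):
        raise ValueError(f"k={k} outside supported range [{K_MIN}, {K_MAX}]")
    if np.min(v) == np.max(v):
        raise ValueError(f"constant marker, cannot discretize: {marker}")
    v_sorted = np.sort(v)
    positions = (np.arange(1, k) * v.size) // k
    edges = np.unique(v_sorted[positions])
    # An edge equal to the global minimum produces an empty bottom bin.
    edges = edges[edges > v_sorted[0]]
    return BinEdges(marker, tuple(float(e) for e in edges), k)


def apply_edges(values, bins: BinEdges) -> np.ndarray:
    """Map values to bin labels: largest b with value >= edges[b-1]."""
    v = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(bins.edges), v, side="right").astype(np.int64)


def discretize_matrix(cells: CellMatrix, k: int) -> DiscretizedMatrix:
    """Discretize every marker with its own full-sample quantile edges."""
    edge_map = {}
    cols = {}
    for m in cells.marker_names:
        try:
            be = equal_frequency_edges(cells.values[m].to_numpy(), m, k)
        except ValueError as exc:
            raise ValueError(f"marker {m!r}: {exc}") from None
        edge_map[m] = be
        cols[m] = apply_edges(cells.values[m].to_numpy(), be)
    labels = pd.DataFrame(cols, columns=cells.marker_names)
    return DiscretizedMatrix(labels, edge_map, cells.annotations.copy())


def edges_to_frame(edge_map: dict) -> pd.DataFrame:
    """Serializable long-format table of the edge map (marker, index, edge)."""
    rows = [(m, i, e) for m, be in edge_map.items() for i, e in enumerate(be.edges)]
    return pd.DataFrame(rows, columns=["marker", "edge_index", "edge"])
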