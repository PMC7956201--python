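"""Cross-condition network comparison with contrast (indicator) variables.

To compare immune networks across regimes (responder vs nonresponder,
pre vs post therapy), the stratified datasets are pooled and a categorical
indicator column records each cell's regime.  A "supergraph" network is
then learned over markers plus indicator(s): any regime-specific change in
the joint distribution — a dependency edge appearing or disappearing, or a
single marker shifting location — pulls the indicator into the Markov
neighborhood of the affected variables, because the affected family's
distribution differs by indicator state.  Conditioning the supergraph on
one indicator state (filter rows, drop the column, relearn) recovers the
stratified network for that regime.

Indicator columns are never discretized and are forced into every node's
candidate pool, so mutual-information pruning cannot mask a weak but real
regime difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn import BayesianNetwork, SearchConfig, learn_network
from .io import CellMatrix
from .markov import classify_edges, markov_neighborhood

__all__ = ["ContrastSpec", "pool_with_contrast", "build_supergraph",
           "contrast_report", "condition_on_contrast", "diff_networks"]

DEFAULT_CONTRAST_BINS = 8  # high-specificity binning for stratified analyses


@dataclass(frozen=True)
class ContrastSpec:
    """An indicator variable pooling several subdatasets.

    ``assignment`` maps subdataset id -> state label; states are the
    ordered, distinct labels the indicator can take (e.g. the four
    day x response combinations, or binary Response / Day).
    """

    name: str
    states: tuple
    assignment: dict

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a contrast needs at least 2 states")
        unknown = set(self.assignment.values()) - set(self.states)
        if unknown:
            raise ValueError(f"assignment uses undeclared states: {sorted(unknown)}")


def pool_with_contrast(datasets: dict, spec: ContrastSpec) -> tuple:
    """Concatenate datasets row-wise and record each cell's contrast state.

    ``datasets`` maps subdataset id -> CellMatrix; every id must appear in
    ``spec.assignment`` and all marker panels must agree.  Returns
    ``(pooled CellMatrix, contrast DataFrame)`` with the contrast column
    named ``spec.name``.
    """
    ids = list(datasets)
    missing = [i for i in ids if i not in spec.assignment]
    if missing:
        raise ValueError(f"datasets not covered by contrast assignment: {missing}")
    ref = datasets[ids[0]].marker_names
    for i in ids[1:]:
        if datasets[i].marker_names != ref:
            diff = set(datasets[i].marker_names) ^ set(ref)
            raise ValueError(f"marker mismatch between datasets ({i} vs {ids[0]}): {sorted(diff)}")
    values = pd.concat([datasets[i].values for i in ids], ignore_index=True)
    anns = pd.concat([datasets[i].annotations for i in ids], ignore_index=True)
    states = np.concatenate([
        np.repeat(spec.assignment[i], datasets[i].n_cells) for i in ids])
    contrast = pd.DataFrame({spec.name: pd.Categorical(states, categories=spec.states)})
    return CellMatrix(values, anns), contrast


def build_supergraph(pooled: CellMatrix, contrast_cols: pd.DataFrame,
                     config: SearchConfig,
                     k_bins: int = DEFAULT_CONTRAST_BINS) -> tuple:
    """Learn the pooled network with the contrast column(s) as categorical
    nodes forced into every candidate pool.  Returns (network, discretized).
    """
    return learn_network(pooled, k_bins, config,
                         extra_discrete_vars=contrast_cols,
                         forced_candidates=tuple(contrast_cols.columns))


def contrast_report(net: BayesianNetwork, contrast_nodes,
                    rel_threshold: float = 0.3) -> dict:
    """Per contrast node: its Markov neighborhood with strengths and the
    strong/weak partition — the markers that differentiate the pooled
    regimes.  An isolated contrast node reports no differentiating markers.
    """
    report = {}
    for node in contrast_nodes:
        mn = classify_edges(markov_neighborhood(net, node), rel_threshold)
        report[node] = {
            "members": sorted(mn.members),
            "strengths": {m: mn.strengths[m] for m in sorted(mn.members)},
            "strong": sorted(mn.strong),
            "weak": sorted(mn.weak),
            "no_differentiating_markers": not mn.members,
        }
    return report


def condition_on_contrast(pooled: CellMatrix, contrast_cols: pd.DataFrame,
                          spec: ContrastSpec, state, config: SearchConfig,
                          k_bins: int = DEFAULT_CONTRAST_BINS) -> tuple:
    """Stratified network for one contrast state: filter the pooled rows to
    that state, drop the contrast column, relearn.  Returns
    (network, discretized)."""
    if state not in spec.states:
        raise ValueError(f"unknown state {state!r} for contrast {spec.name!r}")
    mask = (contrast_cols[spec.name] == state).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells in contrast state {state!r}")
    return learn_network(pooled.select(mask), k_bins, config)


def diff_networks(a: BayesianNetwork, b: BayesianNetwork) -> dict:
    """Skeleton-level edge difference between two networks over the same
    nodes; shared edges carry both strengths, with direction flips noted."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError(f"node sets differ: {sorted(set(a.nodes) ^ set(b.nodes))}")
    sk_a, sk_b = a.skeleton(), b.skeleton()

    def _directed(net, pair):
        u, v = sorted(pair)
        if u in net.parents[v]:
            return (u, v)
        return (v, u)

    shared = []
    for pair in sorted(sk_a & sk_b, key=sorted):
        da, db = _directed(a, pair), _directed(b, pair)
        shared.append({
            "edge": tuple(sorted(pair)),
            "strength_a": a.edge_strengths.get(da),
            "strength_b": b.edge_strengths.get(db),
            "direction_a": da, "direction_b": db,
            "direction_flip": da != db,
        })
    return {
        "only_in_a": sorted(tuple(sorted(p)) for p in sk_a - sk_b),
        "only_in_b": sorted(tuple(sorted(p)) for p in sk_b - sk_a),
        "shared": shared,
    }
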