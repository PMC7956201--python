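"""Markov neighborhoods and blankets around a target node.

The Markov neighborhood (MN) of a node is every node directly linked to it
(parent or child) — a simplified Markov blanket, which additionally
includes the children's other parents.  Direct links are partitioned into
"strong" and "weak" by a relative strength threshold, mirroring the usual
two-tone rendering of response-node neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bn import BayesianNetwork

__all__ = ["MarkovNeighborhood", "markov_neighborhood", "markov_blanket",
           "classify_edges", "mn_report"]

DEFAULT_REL_THRESHOLD = 0.3


@dataclass
class MarkovNeighborhood:
    """Direct links of a target node, with strengths and a strong/weak split."""

    target: str
    members: set
    strengths: dict
    directions: dict  # member -> "parent" | "child"
    strong: set = field(default_factory=set)
    weak: set = field(default_factory=set)


def markov_neighborhood(net: BayesianNetwork, target: str) -> MarkovNeighborhood:
    """Parents and children of ``target`` with their edge strengths."""
    if target not in net.nodes:
        raise ValueError(f"unknown node {target!r}")
    members, strengths, directions = set(), {}, {}
    for u in net.parents[target]:
        members.add(u)
        directions[u] = "parent"
        strengths[u] = net.edge_strengths.get((u, target))
    for v in net.children(target):
        members.add(v)
        directions[v] = "child"
        strengths[v] = net.edge_strengths.get((target, v))
    return MarkovNeighborhood(target, members, strengths, directions)


def markov_blanket(net: BayesianNetwork, target: str) -> set:
    """Parents, children, and children's other parents."""
    if target not in net.nodes:
        raise ValueError(f"unknown node {target!r}")
    blanket = set(net.parents[target])
    for child in net.children(target):
        blanket.add(child)
        blanket.update(u for u in net.parents[child] if u != target)
    return blanket


def classify_edges(mn: MarkovNeighborhood,
                   rel_threshold: float = DEFAULT_REL_THRESHOLD) -> MarkovNeighborhood:
    """Split MN members into strong/weak at a fraction of the MN maximum.

    A member is strong iff its strength >= rel_threshold * max strength in
    the MN, so the partition is invariant to rescaling all strengths —
    only within-network relative magnitudes matter.
    """
    if not (0 < rel_threshold < 1):
        raise ValueError("rel_threshold must be in (0, 1)")
    if not mn.members:
        mn.strong, mn.weak = set(), set()
        return mn
    top = max(mn.strengths[m] for m in mn.members)
    mn.strong = {m for m in mn.members if mn.strengths[m] >= rel_threshold * top}
    mn.weak = mn.members - mn.strong
    return mn


def flag_artifacts(mn: MarkovNeighborhood, net: BayesianNetwork,
                   dominance: float = 3.0) -> set:
    """Advisory flags for weak MN edges likely induced by a stronger path.

    A weak member m is flagged when it shares an edge with another MN
    member whose strength exceeds m's link to the target by ``dominance``x:
    the target-m link may be an artifact of that stronger dependence.
    Flagging never removes the edge.
    """
    flags = set()
    for m in mn.weak:
        s_tm = mn.strengths[m]
        if s_tm is None or s_tm <= 0:
            continue
        for other in mn.members - {m}:
            s = net.edge_strengths.get((m, other)) or net.edge_strengths.get((other, m))
            if s is not None and s >= dominance * s_tm:
                flags.add(m)
                break
    return flags


def mn_report(mn: MarkovNeighborhood, net: BayesianNetwork | None = None) -> pd.DataFrame:
    """Tabular MN report: member, direction, strength, class, artifact flag."""
    flags = flag_artifacts(mn, net) if net is not None else set()
    rows = [(m, mn.directions[m], mn.strengths[m],
             "strong" if m in mn.strong else "weak",
             "possible artifact" if m in flags else "")
            for m in sorted(mn.members, key=lambda m: -(mn.strengths[m] or 0))]
    return pd.DataFrame(rows, columns=["member", "direction", "strength",
                                       "class", "flag"])
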