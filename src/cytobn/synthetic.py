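"""Synthetic ground-truth networks and FACS-like cohorts.

Every pipeline stage is testable without external downloads: this module
builds discrete Bayesian networks with known structure, forward-samples
them, and simulates annotated flow-cytometry cohorts shaped like the study
design — a handful of patients (default 13, of whom 4 respond), a
14-marker panel, around a thousand cells per patient and two timepoints.

Continuous intensities are log-normal around latent-state-dependent means,
matching the heavy right tails of compensated cytometry data.  Regime
differences are expressed either as single-marker location shifts or as
the presence/absence of single dependency edges, the two difference types
the contrast analysis is built to detect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn import BayesianNetwork
from .discretize import BinEdges, DiscretizedMatrix
from .io import CellMatrix

__all__ = ["CohortSpec", "make_bn", "random_bn", "sample_bn",
           "marginalize_edge", "make_contrast_scenario",
           "default_contrast_scenario", "simulate_cohort", "skeleton_shd"]

REGIMES = ("day1_R", "day1_NR", "day21_R", "day21_NR")

DEFAULT_MARKERS = ("TIGIT", "PD-1", "LAG-3", "TIM-3", "CD160", "4-1BB",
                   "OX40", "BTLA", "KLRG1", "CXCR5", "CD27", "CD28",
                   "ICOS", "CD25")


# ---------------------------------------------------------------------------
# Ground-truth networks
# ---------------------------------------------------------------------------

def make_bn(cardinalities: dict, parents: dict, cpts: dict) -> BayesianNetwork:
    """Assemble a ground-truth network from explicit CPTs.

    ``cpts[node]`` must have shape (q, r) with rows row-major in the order
    of ``parents[node]``.
    """
    nodes = list(cardinalities)
    fam = {}
    full = {}
    for v in nodes:
        ps = tuple(parents.get(v, ()))
        q = int(np.prod([cardinalities[p] for p in ps])) if ps else 1
        t = np.asarray(cpts[v], dtype=float).reshape(q, cardinalities[v])
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {v!r} do not sum to 1")
        full[v] = t
        fam[v] = 0.0
    return BayesianNetwork(nodes=nodes,
                           cardinalities=dict(cardinalities),
                           parents={v: tuple(parents.get(v, ())) for v in nodes},
                           cpts=full, family_scores=fam)


def _modular_cpt(card_child: int, parent_cards, contrast: float) -> np.ndarray:
    """CPT where the child tracks (sum of parents) mod r with prob
    ``contrast`` and is otherwise uniform over the remaining states.
    Every parent matters, so the structure is recoverable."""
    q = int(np.prod(parent_cards)) if len(parent_cards) else 1
    r = card_child
    t = np.full((q, r), (1.0 - contrast) / max(r - 1, 1))
    if q == 1 and not len(parent_cards):
        t = np.full((1, r), 1.0 / r)
        return t
    for j, combo in enumerate(itertools.product(*[range(c) for c in parent_cards])):
        t[j, sum(combo) % r] = contrast
    return t


def random_bn(n_nodes: int = 8, k_states: int = 3, n_edges: int = 8,
              contrast: float = 0.85, max_parents: int = 2,
              seed: int = 0) -> BayesianNetwork:
    """Random DAG (edges respect a random topological order) with strong
    modular-sum CPTs; roots are mildly non-uniform so every state occurs."""
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    possible = [(int(order[i]), int(order[j]))
                for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    rng.shuffle(possible)
    parents = {v: [] for v in names}
    count = 0
    for u, v in possible:
        if count >= n_edges:
            break
        if len(parents[names[v]]) < max_parents:
            parents[names[v]].append(names[u])
            count += 1
    cards = {v: k_states for v in names}
    cpts = {}
    for v in names:
        ps = parents[v]
        if not ps:
            w = 0.6 + 0.8 * rng.random(k_states)
            cpts[v] = (w / w.sum()).reshape(1, k_states)
        else:
            cpts[v] = _modular_cpt(k_states, [cards[p] for p in ps], contrast)
    return make_bn(cards, {v: tuple(ps) for v, ps in parents.items()}, cpts)


# ---------------------------------------------------------------------------
# Forward sampling
# ---------------------------------------------------------------------------

def _topo_order(net: BayesianNetwork) -> list:
    remaining = {v: set(net.parents[v]) for v in net.nodes}
    order = []
    while remaining:
        ready = [v for v, ps in remaining.items() if not ps]
        if not ready:
            raise ValueError("network contains a cycle")
        for v in ready:
            order.append(v)
            del remaining[v]
        for ps in remaining.values():
            ps.difference_update(ready)
    return order


def sample_bn(net: BayesianNetwork, n: int, seed: int) -> DiscretizedMatrix:
    """Ancestral sampling: draw each node given its sampled parents."""
    rng = np.random.default_rng(seed)
    cols = {}
    for v in _topo_order(net):
        if v not in net.cpts or net.cpts[v] is None:
            raise ValueError(f"node {v!r} has no CPT")
        ps = net.parents[v]
        t = np.asarray(net.cpts[v])
        if ps:
            code = np.zeros(n, dtype=np.int64)
            for p in ps:
                code = code * net.cardinalities[p] + cols[p]
            rows = t[code]
        else:
            rows = np.broadcast_to(t[0], (n, t.shape[1]))
        u = rng.random(n)
        cols[v] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)
    labels = pd.DataFrame({v: cols[v] for v in net.nodes})
    ann = pd.DataFrame({"patient_id": ["sim"] * n, "day": [1] * n,
                        "response": [False] * n, "tsize": [0.0] * n})
    edge_map = {v: BinEdges(v, tuple(float(b) for b in range(1, net.cardinalities[v])),
                            net.cardinalities[v]) for v in net.nodes}
    return DiscretizedMatrix(labels, edge_map, ann)


# ---------------------------------------------------------------------------
# Exact edge removal
# ---------------------------------------------------------------------------

def _joint_distribution(net: BayesianNetwork) -> tuple:
    """Full joint over all configurations (exponential; small nets only)."""
    nodes = list(net.nodes)
    cards = [net.cardinalities[v] for v in nodes]
    idx = {v: i for i, v in enumerate(nodes)}
    configs = np.array(list(itertools.product(*[range(c) for c in cards])),
                       dtype=np.int64)
    prob = np.ones(len(configs))
    for v in nodes:
        ps = net.parents[v]
        t = np.asarray(net.cpts[v])
        if ps:
            code = np.zeros(len(configs), dtype=np.int64)
            for p in ps:
                code = code * net.cardinalities[p] + configs[:, idx[p]]
            prob *= t[code, configs[:, idx[v]]]
        else:
            prob *= t[0, configs[:, idx[v]]]
    return configs, prob, nodes


def marginalize_edge(net: BayesianNetwork, edge) -> BayesianNetwork:
    """Remove edge u -> v, replacing v's CPT with the exact conditional
    P(v | remaining parents) under the original joint distribution.

    Computed by full joint enumeration, so intended for the small
    ground-truth networks used in simulations.
    """
    u, v = edge
    if u not in net.parents[v]:
        raise ValueError(f"edge {u!r}->{v!r} not in network")
    keep = tuple(p for p in net.parents[v] if p != u)
    configs, prob, nodes = _joint_distribution(net)
    idx = {n: i for i, n in enumerate(nodes)}
    r = net.cardinalities[v]
    q = int(np.prod([net.cardinalities[p] for p in keep])) if keep else 1
    code = np.zeros(len(configs), dtype=np.int64)
    for p in keep:
        code = code * net.cardinalities[p] + configs[:, idx[p]]
    joint = np.zeros((q, r))
    np.add.at(joint, (code, configs[:, idx[v]]), prob)
    denom = joint.sum(axis=1, keepdims=True)
    # unreachable parent configurations get a uniform row
    cpt = np.where(denom > 0, joint / np.where(denom > 0, denom, 1.0), 1.0 / r)
    parents = {n: net.parents[n] for n in nodes}
    parents[v] = keep
    cpts = {n: np.asarray(net.cpts[n]).copy() for n in nodes}
    cpts[v] = cpt
    return make_bn(dict(net.cardinalities), parents, cpts)


def make_contrast_scenario(base: BayesianNetwork, changed_edge,
                           n_per_regime: int, seed: int) -> tuple:
    """Two-regime dataset pair: regime 0 from ``base``, regime 1 from
    ``base`` with ``changed_edge`` removed (child CPT exactly
    marginalized).  Deterministic given seed."""
    alt = marginalize_edge(base, changed_edge)
    d0 = sample_bn(base, n_per_regime, seed)
    d1 = sample_bn(alt, n_per_regime, seed + 1)
    return d0, d1


def default_contrast_scenario(n_per_regime: int = 4000, seed: int = 0) -> tuple:
    """The default contrast power scenario: 6 ternary markers, one edge
    with CPT contrast 0.85 present only in regime 0.  Returns
    ``(regime0, regime1, changed_edge)``."""
    base = random_bn(n_nodes=6, k_states=3, n_edges=5, contrast=0.85,
                     max_parents=2, seed=7)
    edge = next(iter(sorted((u, v) for v in base.nodes for u in base.parents[v])))
    d0, d1 = make_contrast_scenario(base, edge, n_per_regime, seed)
    return d0, d1, edge


def skeleton_shd(a: BayesianNetwork, b: BayesianNetwork) -> int:
    """Structural Hamming distance between skeletons (undirected edges
    present in exactly one of the two graphs)."""
    return len(a.skeleton() ^ b.skeleton())


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    location_effects : list of (marker, regime, shift) where shift is a
        location offset in units of the marker's intensity SD, applied to
        cells of that regime.
    edge_effects : list of ((u, v), regime, present); when present is
        False the dependency edge is removed (CPT marginalized) in that
        regime's ground-truth network.
    """

    n_patients: int = 13
    n_responders: int = 4
    cells_per_patient: int = 1000
    days: tuple = (1, 21)
    markers: tuple = DEFAULT_MARKERS
    latent_bn: BayesianNetwork | None = None
    base_log_location: float = 5.0     # log intensity at the middle state
    state_step: float = 0.8            # log-mean separation between states
    log_scale: float = 0.5             # log-normal shape
    location_effects: list = field(default_factory=list)
    edge_effects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_responders > self.n_patients:
            raise ValueError("n_responders cannot exceed n_patients")
        for marker, regime, _ in self.location_effects:
            if marker not in self.markers:
                raise ValueError(f"effect marker {marker!r} not in panel")
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}")
        for (u, v), regime, _ in self.edge_effects:
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}")
            if self.latent_bn is not None and u not in self.latent_bn.parents.get(v, ()):
                raise ValueError(f"effect edge {u}->{v} not in latent network")


def _default_latent_bn(markers) -> BayesianNetwork:
    """A sparse chain-with-branches dependency structure over the panel."""
    rng_edges = [(markers[i], markers[i + 1]) for i in range(0, len(markers) - 1, 2)]
    parents = {m: () for m in markers}
    for u, v in rng_edges:
        parents[v] = (u,)
    cards = {m: 3 for m in markers}
    cpts = {}
    for i, m in enumerate(markers):
        if parents[m]:
            cpts[m] = _modular_cpt(3, [3], 0.7)
        else:
            w = np.array([0.3, 0.4, 0.3]) if i % 2 else np.array([0.25, 0.35, 0.4])
            cpts[m] = w.reshape(1, 3)
    return make_bn(cards, parents, cpts)


def simulate_cohort(spec: CohortSpec, seed: int) -> tuple:
    """Simulate an annotated cohort; returns (CellMatrix, metadata frame).

    Per patient and day, latent discrete states are ancestrally sampled
    from the regime's ground-truth network, mapped to log-normal intensity
    means, and location effects are added on the intensity scale in units
    of the marker's cross-cohort SD.
    """
    net = spec.latent_bn if spec.latent_bn is not None else _default_latent_bn(spec.markers)
    rng = np.random.default_rng(seed)

    regime_nets = {}
    for regime in REGIMES:
        g = net
        for edge, rg, present in spec.edge_effects:
            if rg == regime and not present:
                g = marginalize_edge(g, edge)
        regime_nets[regime] = g

    # nominal intensity SD for shift units (lognormal moments at middle state)
    mu0 = spec.base_log_location
    nominal_sd = float(np.sqrt((np.exp(spec.log_scale ** 2) - 1)
                               * np.exp(2 * mu0 + spec.log_scale ** 2)))

    frames, anns, meta = [], [], []
    responders = set(range(spec.n_responders))
    for p in range(spec.n_patients):
        is_resp = p in responders
        tsize = float(rng.uniform(-65, -30)) if is_resp else float(rng.uniform(-20, 25))
        pid = f"P{p + 1:02d}"
        for day in spec.days:
            regime = f"day{day}_{'R' if is_resp else 'NR'}"
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            latent = sample_bn(regime_nets[regime], spec.cells_per_patient, sub_seed)
            logs = (mu0
                    + (latent.labels[list(spec.markers)].to_numpy() - 1) * spec.state_step
                    + rng.normal(0.0, spec.log_scale,
                                 size=(spec.cells_per_patient, len(spec.markers))))
            intensities = np.exp(logs)
            for marker, rg, shift in spec.location_effects:
                if rg == regime:
                    intensities[:, spec.markers.index(marker)] += shift * nominal_sd
            frames.append(pd.DataFrame(intensities, columns=list(spec.markers)))
            anns.append(pd.DataFrame({
                "patient_id": [pid] * spec.cells_per_patient,
                "day": [day] * spec.cells_per_patient,
                "response": [is_resp] * spec.cells_per_patient,
                "tsize": [tsize] * spec.cells_per_patient,
            }))
            meta.append((pid, day, is_resp, tsize, regime))
    cells = CellMatrix(pd.concat(frames, ignore_index=True),
                       pd.concat(anns, ignore_index=True))
    metadata = pd.DataFrame(meta, columns=["patient_id", "day", "response",
                                           "tsize", "regime"])
    return cells, metadata
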