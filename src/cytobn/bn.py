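"""Discrete Bayesian-network learning: BDeu scoring, sparse-candidate
pruning, hill-climbing search with random restarts, and edge strengths.

The model is a DAG over discrete variables with one conditional probability
table (CPT) per node.  Structure quality is the Bayesian-Dirichlet
equivalent-uniform (BDeu) log marginal likelihood, which decomposes into
per-family terms

    score(child | parents) =
        sum_j [ lnG(a_j) - lnG(a_j + N_j) ]
      + sum_jk [ lnG(a_jk + N_jk) - lnG(a_jk) ]

with r child states, q joint parent configurations, N_jk the count of child
state k under parent configuration j, a_j = ess/q and a_jk = ess/(q r).
BDeu is score-equivalent: Markov-equivalent DAGs receive identical scores.

The search is the hybrid "sparse candidates" + search-and-score scheme:
each node's admissible parents are restricted to the k variables with
highest pairwise mutual information, and greedy add/delete/reverse moves
run to a local optimum from several random acyclic starting graphs; the
best-scoring network over restarts is returned.  Everything is
deterministic given the seed.

Edge strength is the log marginal-likelihood ratio between the network
with and without the edge — local to the child's family by score
decomposability, and comparable only within a single network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .discretize import DiscretizedMatrix, discretize_matrix
from .io import CellMatrix

__all__ = ["BayesianNetwork", "SearchConfig", "family_score",
           "sparse_candidates", "hill_climb", "learn_network",
           "edge_strength", "pairwise_mutual_information"]

SCORE_EPS = 1e-9  # minimum improvement for a move to count


@dataclass(frozen=True)
class SearchConfig:
    """Structure-search settings.

    k_candidates : sparse-candidate pool size per node.
    restarts     : number of random-restart searches (the first restart
                   always begins from the empty graph).
    seed         : RNG seed; the whole search is deterministic given it.
    ess          : equivalent sample size of the BDeu Dirichlet prior.
    max_parents  : parent-set size cap (keeps q = prod of parent
                   cardinalities tractable at 8 bins).
    """

    k_candidates: int = 8
    restarts: int = 20
    seed: int = 0
    ess: float = 1.0
    max_parents: int = 4

    def __post_init__(self) -> None:
        if self.max_parents < 1 or self.k_candidates < self.max_parents:
            raise ValueError("need k_candidates >= max_parents >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.ess <= 0:
            raise ValueError("ess must be > 0")


@dataclass
class BayesianNetwork:
    """Learned DAG with CPTs, family scores and edge strengths.

    ``cpts[node]`` has shape (q, r): one row per joint parent configuration
    (row-major in the order of ``parents[node]``), each row a distribution
    over the node's states.  ``total_score`` is the sum of family scores.
    """

    nodes: list
    cardinalities: dict
    parents: dict
    cpts: dict
    family_scores: dict
    edge_strengths: dict = field(default_factory=dict)

    @property
    def total_score(self) -> float:
        return float(sum(self.family_scores.values()))

    def edges(self) -> list:
        return [(u, v) for v in self.nodes for u in self.parents[v]]

    def children(self, node) -> list:
        return [v for v in self.nodes if node in self.parents[v]]

    def skeleton(self) -> set:
        return {frozenset((u, v)) for u, v in self.edges()}

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges():
            g.add_edge(u, v, strength=self.edge_strengths.get((u, v)))
        return g

    def to_json(self) -> str:
        return json.dumps({
            "nodes": list(self.nodes),
            "cardinalities": {n: int(c) for n, c in self.cardinalities.items()},
            "parents": {n: list(p) for n, p in self.parents.items()},
            "total_score": self.total_score,
            "edge_strengths": {f"{u}->{v}": s for (u, v), s in self.edge_strengths.items()},
            "cpts": {n: np.asarray(t).tolist() for n, t in self.cpts.items()},
        }, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _encode(data: np.ndarray, cards: np.ndarray, idxs) -> tuple:
    """Row-major mixed-radix code of the given columns; returns (code, q)."""
    q = 1
    code = np.zeros(data.shape[0], dtype=np.int64)
    for i in idxs:
        code = code * cards[i] + data[:, i]
        q *= int(cards[i])
    return code, q


def _family_counts(data, cards, child, parent_idxs):
    r = int(cards[child])
    code, q = _encode(data, cards, parent_idxs)
    counts = np.bincount(code * r + data[:, child], minlength=q * r)
    return counts.reshape(q, r), q, r


def _family_score_arr(data, cards, child, parent_idxs, ess) -> float:
    njk, q, r = _family_counts(data, cards, child, parent_idxs)
    nj = njk.sum(axis=1)
    aj = ess / q
    ajk = ess / (q * r)
    seen = nj > 0  # unseen parent configurations contribute zero
    score = float(np.sum(gammaln(aj) - gammaln(aj + nj[seen])))
    sub = njk[seen]
    score += float(np.sum(gammaln(ajk + sub[sub > 0]) - gammaln(ajk)))
    return score


def family_score(data: DiscretizedMatrix, child, parents, ess: float = 1.0) -> float:
    """BDeu log marginal likelihood of one family (child given parent set)."""
    parents = list(parents)
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    if len(data.labels) == 0:
        raise ValueError("empty data")
    names = data.variables
    for v in [child, *parents]:
        if v not in names:
            raise ValueError(f"unknown variable {v!r}")
    arr = data.labels.to_numpy(dtype=np.int64)
    cards = np.array([data.cardinality(v) for v in names], dtype=np.int64)
    idx = {n: i for i, n in enumerate(names)}
    return _family_score_arr(arr, cards, idx[child], [idx[p] for p in parents], ess)


# ---------------------------------------------------------------------------
# Sparse candidates
# ---------------------------------------------------------------------------

def pairwise_mutual_information(data: DiscretizedMatrix) -> pd.DataFrame:
    """Plug-in mutual information (nats) between every pair of variables."""
    names = data.variables
    arr = data.labels.to_numpy(dtype=np.int64)
    cards = np.array([data.cardinality(v) for v in names], dtype=np.int64)
    n = arr.shape[0]
    p = len(names)
    mi = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            joint = np.bincount(arr[:, i] * cards[j] + arr[:, j],
                                minlength=cards[i] * cards[j]).reshape(cards[i], cards[j])
            pij = joint / n
            pi = pij.sum(axis=1, keepdims=True)
            pj = pij.sum(axis=0, keepdims=True)
            nz = pij > 0
            mi[i, j] = mi[j, i] = float(np.sum(pij[nz] * np.log(pij[nz] / (pi @ pj)[nz])))
    return pd.DataFrame(mi, index=names, columns=names)


def sparse_candidates(data: DiscretizedMatrix, k_candidates: int,
                      forced=()) -> dict:
    """Per-node candidate parent pools: the k variables of highest pairwise
    mutual information with the node.

    ``forced`` variables (e.g. contrast indicators) are always included in
    every other node's pool regardless of their MI rank, on top of the k
    MI-selected candidates.  MI ties break by variable order in the data.
    """
    names = data.variables
    if k_candidates >= len(names):
        raise ValueError("k_candidates must be < number of variables")
    mi = pairwise_mutual_information(data).to_numpy()
    order = {n: i for i, n in enumerate(names)}
    pools = {}
    for i, v in enumerate(names):
        others = [u for u in names if u != v]
        # stable sort: descending MI, then original column order
        ranked = sorted(others, key=lambda u: (-mi[i, order[u]], order[u]))
        pool = ranked[:k_candidates]
        for f in forced:
            if f != v and f not in pool:
                pool.append(f)
        pools[v] = pool
    return pools


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------

class _Searcher:
    """Greedy add/delete/reverse search over one dataset; caches family scores."""

    def __init__(self, arr, cards, names, candidates, config, unbounded=()):
        self.arr = arr
        self.cards = cards
        self.names = names
        self.idx = {n: i for i, n in enumerate(names)}
        self.cand = {self.idx[v]: sorted(self.idx[u] for u in candidates[v])
                     for v in names}
        self.cfg = config
        self.p = len(names)
        self.unbounded = {self.idx[v] for v in unbounded}
        self._cache = {}

    def _cap(self, v) -> int:
        return self.p if v in self.unbounded else self.cfg.max_parents

    def score_family(self, child, parent_set) -> float:
        key = (child, parent_set)
        if key not in self._cache:
            self._cache[key] = _family_score_arr(
                self.arr, self.cards, child, sorted(parent_set), self.cfg.ess)
        return self._cache[key]

    @staticmethod
    def _creates_cycle(parents, u, v) -> bool:
        """Would adding u -> v create a cycle (is v an ancestor of u)?"""
        stack = [u]
        seen = set()
        while stack:
            x = stack.pop()
            if x == v:
                return True
            for pa in parents[x]:
                if pa not in seen:
                    seen.add(pa)
                    stack.append(pa)
        return False

    def total(self, parents) -> float:
        return sum(self.score_family(v, parents[v]) for v in range(self.p))

    def _moves(self, parents):
        """Yield (delta, move) for every admissible single-edge move."""
        fam = {v: self.score_family(v, parents[v]) for v in range(self.p)}
        for v in range(self.p):
            for u in self.cand[v]:
                if u in parents[v]:
                    continue
                if len(parents[v]) >= self._cap(v):
                    continue
                if self._creates_cycle(parents, u, v):
                    continue
                delta = self.score_family(v, parents[v] | {u}) - fam[v]
                yield delta, ("add", u, v)
        for v in range(self.p):
            for u in sorted(parents[v]):
                delta = self.score_family(v, parents[v] - {u}) - fam[v]
                yield delta, ("del", u, v)
                # reverse u -> v into v -> u
                if v in self.cand[u] and len(parents[u]) < self._cap(u):
                    without = dict(parents)
                    without[v] = parents[v] - {u}
                    if not self._creates_cycle(without, v, u):
                        d = (self.score_family(v, parents[v] - {u}) - fam[v]
                             + self.score_family(u, parents[u] | {v}) - fam[u])
                        yield d, ("rev", u, v)

    def climb(self, parents) -> dict:
        parents = {v: frozenset(ps) for v, ps in parents.items()}
        while True:
            best_delta, best_move = SCORE_EPS, None
            for delta, move in self._moves(parents):
                if delta > best_delta:
                    best_delta, best_move = delta, move
            if best_move is None:
                return parents
            kind, u, v = best_move
            if kind == "add":
                parents[v] = parents[v] | {u}
            elif kind == "del":
                parents[v] = parents[v] - {u}
            else:
                parents[v] = parents[v] - {u}
                parents[u] = parents[u] | {v}

    def random_start(self, rng) -> dict:
        """Random acyclic graph with edges inside the candidate pools."""
        order = rng.permutation(self.p)
        pos = np.empty(self.p, dtype=int)
        pos[order] = np.arange(self.p)
        parents = {v: set() for v in range(self.p)}
        for v in range(self.p):
            allowed = [u for u in self.cand[v] if pos[u] < pos[v]]
            if not allowed:
                continue
            m = int(rng.integers(0, min(self.cfg.max_parents, len(allowed)) + 1))
            if m:
                chosen = rng.choice(len(allowed), size=m, replace=False)
                parents[v] = {allowed[c] for c in chosen}
        return parents


def hill_climb(data: DiscretizedMatrix, candidates: dict,
               config: SearchConfig, unbounded_parents=()) -> BayesianNetwork:
    """Best network over `config.restarts` greedy searches.

    The first restart starts from the empty graph; the rest from random
    acyclic graphs drawn inside the candidate pools.  Ties between moves
    break on enumeration order (nodes in data order), so the result is
    reproducible bit-for-bit given the seed.
    """
    names = data.variables
    arr = data.labels.to_numpy(dtype=np.int64)
    cards = np.array([data.cardinality(v) for v in names], dtype=np.int64)
    s = _Searcher(arr, cards, names, candidates, config,
                  unbounded=unbounded_parents)
    rng = np.random.default_rng(config.seed)

    best_parents, best_score = None, -np.inf
    for restart in range(config.restarts):
        start = ({v: set() for v in range(s.p)} if restart == 0
                 else s.random_start(rng))
        parents = s.climb(start)
        score = s.total(parents)
        if score > best_score + SCORE_EPS:
            best_parents, best_score = parents, score
    return _finalize(s, best_parents, names, cards, config)


def _finalize(s: _Searcher, parents_idx, names, cards, config) -> BayesianNetwork:
    parents = {names[v]: tuple(names[u] for u in sorted(ps))
               for v, ps in parents_idx.items()}
    fam = {names[v]: s.score_family(v, frozenset(ps))
           for v, ps in parents_idx.items()}
    cpts = {}
    for v, ps in parents_idx.items():
        njk, q, r = _family_counts(s.arr, s.cards, v, sorted(ps))
        ajk = config.ess / (q * r)
        cpts[names[v]] = (njk + ajk) / (njk.sum(axis=1, keepdims=True) + config.ess / q)
    net = BayesianNetwork(
        nodes=list(names),
        cardinalities={names[i]: int(cards[i]) for i in range(len(names))},
        parents=parents,
        cpts=cpts,
        family_scores=fam,
    )
    strengths = {}
    for v, ps in parents_idx.items():
        for u in ps:
            strengths[(names[u], names[v])] = (
                fam[names[v]] - s.score_family(v, frozenset(ps) - {u}))
    net.edge_strengths = strengths
    return net


def edge_strength(net: BayesianNetwork, data: DiscretizedMatrix, edge,
                  ess: float = 1.0) -> float:
    """Log marginal-likelihood ratio for one edge: family score with the
    parent minus family score without it.  Local to the child's family."""
    u, v = edge
    if u not in net.parents.get(v, ()):
        raise ValueError(f"edge {u!r}->{v!r} not present in network")
    with_p = list(net.parents[v])
    without = [p for p in with_p if p != u]
    return family_score(data, v, with_p, ess) - family_score(data, v, without, ess)


# ---------------------------------------------------------------------------
# End-to-end learning
# ---------------------------------------------------------------------------

def learn_network(cells: CellMatrix, k_bins: int, config: SearchConfig,
                  extra_discrete_vars: pd.DataFrame | None = None,
                  forced_candidates=()) -> tuple:
    """Discretize markers, prune candidates, search: the full BN stage.

    ``extra_discrete_vars`` are already-categorical columns (binary response
    label, contrast indicators, a pre-binned tumor-size variable) appended
    to the discretized markers; their integer codes are used as-is.
    Returns ``(network, discretized)`` so downstream stages (edge strengths
    on held structure, configuration tables) reuse the same binning.
    """
    disc = discretize_matrix(cells, k_bins)
    labels = disc.labels
    if extra_discrete_vars is not None:
        extra = extra_discrete_vars.reset_index(drop=True)
        for col in extra.columns:
            codes = pd.Categorical(extra[col]).codes.astype(np.int64)
            if (codes < 0).any():
                raise ValueError(f"missing values in extra variable {col!r}")
            labels[col] = codes
        disc = DiscretizedMatrix(labels, disc.edge_map, disc.annotations)
    n_vars = len(disc.variables)
    k_cand = min(config.k_candidates, n_vars - 1)
    cands = sparse_candidates(disc, k_cand, forced=forced_candidates)
    net = hill_climb(disc, cands, config, unbounded_parents=forced_candidates)
    return net, disc
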