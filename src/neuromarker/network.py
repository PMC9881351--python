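"""Protein-protein interaction network analysis: score-filtered graph
construction, Molecular Complex Detection (MCODE) clustering, five hub
centralities (MCC, Degree, DMNC, MNC, clustering coefficient), and top-k
consensus hub calling.

The module score convention is density x V with density = E/(V(V-1)),
i.e. score = E/(V-1); this is the convention under which a 14-node,
60-edge module scores 60/13 = 4.615.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "McodeParams",
    "ModuleResult",
    "CentralityRanking",
    "build_graph",
    "module_score",
    "mcode_cluster",
    "centrality",
    "CENTRALITY_METHODS",
    "hub_consensus",
]

_CLIQUE_NODE_GUARD = 5000


def build_graph(
    edges: pd.DataFrame, min_score: float = 0.4
) -> nx.Graph:
    """Build a simple weighted graph from an edge list, keeping score > min_score.

    ``edges`` needs columns ``node_a, node_b, combined_score``. STRING-style
    integer scores on the 0-1000 scale are auto-rescaled to [0, 1]. The score
    filter is strict (a 0.4 edge is dropped); duplicate edges keep the maximum
    score; self-loops are dropped; nodes are only those incident to a kept
    edge, so isolated nodes never appear.
    """
    required = {"node_a", "node_b", "combined_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    scores = pd.to_numeric(edges["combined_score"], errors="raise").astype(float)
    if scores.max() > 1.0:  # STRING 0-1000 dialect
        scores = scores / 1000.0
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("combined scores must lie in [0, 1] after rescaling")
    g = nx.Graph()
    for a, b, s in zip(edges["node_a"], edges["node_b"], scores):
        if a == b:
            continue
        if s > min_score:
            if g.has_edge(a, b):
                g[a][b]["combined_score"] = max(g[a][b]["combined_score"], s)
            else:
                g.add_edge(a, b, combined_score=float(s))
    return g


def module_score(n_nodes: int, n_edges: int) -> float:
    """MCODE module score: density x V with density = E/(V(V-1)) = E/(V-1)."""
    if n_nodes < 2:
        return 0.0
    return n_edges / (n_nodes - 1)


@dataclass
class McodeParams:
    """MCODE filter parameters (node score cutoff 0.2, degree cutoff 2,
    k-core 2, max depth 100 are the conventional defaults)."""

    node_score_cutoff: float = 0.2
    degree_cutoff: int = 2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.node_score_cutoff < 0 or self.degree_cutoff < 0:
            raise ValueError("cutoffs must be >= 0")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")


@dataclass
class ModuleResult:
    members: frozenset[str]
    n_nodes: int
    n_edges: int
    score: float


def _mcode_weights(g: nx.Graph, degree_cutoff: int) -> dict:
    """Vertex weighting: highest k-core number of the closed neighborhood
    times the density of that k-core subgraph."""
    weights = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph(list(g.neighbors(v)) + [v])
        cores = nx.core_number(nbhd)
        kmax = max(cores.values())
        core_sub = nbhd.subgraph([u for u, c in cores.items() if c >= kmax])
        nv, ne = core_sub.number_of_nodes(), core_sub.number_of_edges()
        density = 2.0 * ne / (nv * (nv - 1)) if nv > 1 else 0.0
        weights[v] = kmax * density
    return weights


def mcode_cluster(g: nx.Graph, params: McodeParams | None = None) -> list[ModuleResult]:
    """Find locally dense modules by seeded greedy expansion over MCODE weights.

    Seeds are taken in decreasing weight order (ties by node ID) among
    unvisited nodes; expansion includes unvisited neighbors whose weight is at
    least seed_weight x (1 - node_score_cutoff), breadth-first to max_depth.
    Complexes are kept only if they contain a k-core of order ``k_core``;
    haircut iteratively trims singly-connected nodes. Modules with fewer than
    3 nodes or score <= 0 are discarded. Result sorted by score descending.
    """
    params = params or McodeParams()
    if g.number_of_nodes() == 0:
        return []
    weights = _mcode_weights(g, params.degree_cutoff)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    modules: list[ModuleResult] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w in visited or w in members:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        visited.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        sub = g.subgraph(members).copy()
        core = nx.k_core(sub, params.k_core)
        if core.number_of_nodes() == 0:
            continue
        if params.haircut:
            while True:
                trim = [v for v in sub.nodes if sub.degree(v) < 2]
                if not trim:
                    break
                sub.remove_nodes_from(trim)
        if params.fluff:
            # add neighbors whose neighborhood density is above the cutoff
            extra = set()
            for v in list(sub.nodes):
                for w in g.neighbors(v):
                    if w in sub or w in extra:
                        continue
                    nb = g.subgraph(list(g.neighbors(w)) + [w])
                    nv, ne = nb.number_of_nodes(), nb.number_of_edges()
                    dens = 2.0 * ne / (nv * (nv - 1)) if nv > 1 else 0.0
                    if dens > params.node_score_cutoff:
                        extra.add(w)
            sub = g.subgraph(set(sub.nodes) | extra).copy()
        nv, ne = sub.number_of_nodes(), sub.number_of_edges()
        score = module_score(nv, ne)
        if nv >= 3 and score > 0:
            modules.append(
                ModuleResult(frozenset(sub.nodes), nv, ne, score)
            )
    modules.sort(key=lambda m: (-m.score, -m.n_nodes, sorted(m.members)))
    return modules


# ---------------------------------------------------------------------------
# centralities


def _maximal_cliques(g: nx.Graph) -> list[frozenset]:
    if g.number_of_nodes() > _CLIQUE_NODE_GUARD:
        raise ValueError(
            f"graph has > {_CLIQUE_NODE_GUARD} nodes; maximal-clique centralities "
            "are exponential in the worst case — subset the graph first"
        )
    return [frozenset(c) for c in nx.find_cliques(g)]


def _mcc(g: nx.Graph) -> dict:
    """Maximal clique centrality: sum of (|C|-1)! over maximal cliques
    containing the node. A node in no triangle only belongs to maximal
    2-cliques, so its MCC equals its degree."""
    scores = {v: 0.0 for v in g.nodes}
    for clique in _maximal_cliques(g):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def _mnc_component(g: nx.Graph, v) -> nx.Graph:
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return g.subgraph([])
    sub = g.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
    return sub.subgraph(comp)


def _mnc(g: nx.Graph) -> dict:
    return {v: float(_mnc_component(g, v).number_of_nodes()) for v in g.nodes}


def _dmnc(g: nx.Graph, eps: float = 1.7) -> dict:
    """Density of the maximum neighborhood component: E / V**eps (eps = 1.7)."""
    out = {}
    for v in g.nodes:
        comp = _mnc_component(g, v)
        nv, ne = comp.number_of_nodes(), comp.number_of_edges()
        out[v] = ne / nv**eps if nv > 0 else 0.0
    return out


CENTRALITY_METHODS = {
    "MCC": _mcc,
    "Degree": lambda g: {v: float(d) for v, d in g.degree()},
    "DMNC": _dmnc,
    "MNC": _mnc,
    "ClusteringCoefficient": nx.clustering,
}


@dataclass
class CentralityRanking:
    method: str
    scores: dict = field(default_factory=dict)
    top_k: list = field(default_factory=list)


def centrality(g: nx.Graph, method: str, k: int = 14) -> CentralityRanking:
    """Rank all nodes by one centrality; top_k keeps every node tied with the
    k-th score (inclusive ties), ordered by score descending then node ID."""
    if method not in CENTRALITY_METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid: {sorted(CENTRALITY_METHODS)}"
        )
    scores = {v: float(s) for v, s in CENTRALITY_METHODS[method](g).items()}
    ranked = sorted(scores, key=lambda v: (-scores[v], str(v)))
    if len(ranked) <= k:
        top = ranked
    else:
        kth = scores[ranked[k - 1]]
        top = [v for v in ranked if scores[v] >= kth]
    return CentralityRanking(method=method, scores=scores, top_k=top)


def hub_consensus(
    rankings: list[CentralityRanking], tissue_specific: set | None = None
) -> tuple[set, set]:
    """Intersect all top-k lists into hub genes; optionally intersect those
    with a tissue-specific gene set (e.g. nervous-system-specific genes)."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings for a consensus")
    hubs = set.intersection(*(set(r.top_k) for r in rankings))
    system_hubs = hubs & set(tissue_specific) if tissue_specific is not None else set()
    return hubs, system_hubs
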