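"""Network parameters: clustering, path length, small-world index, modularity.

All quantities follow their textbook definitions so they can be verified by
exhaustive enumeration on small graphs:

* CC (unweighted): mean Watts-Strogatz local clustering; nodes of degree < 2
  contribute 0.
* CC (weighted): mean Barrat local weighted clustering,
  c_i = 1 / (s_i (k_i - 1)) * sum_{(j,h)} (w_ij + w_ih) / 2 over closed
  triangles at i; edges with non-positive weight carry no clustering mass
  and are ignored.
* ASPL: mean shortest-path length over all unordered node pairs, in hops
  (every edge length 1) or along the distance transform 1 - r.
* Small-world index: S = (CC / CCran) / (ASPL / ASPLran), small-world iff
  S > 1 against a size-matched random baseline.
* Modularity: Q = sum_c [ e_c / m - (d_c / 2m)^2 ] with edge weights
  (e_c intra-community weight, d_c community strength, m total weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms import community as nxcommunity

from .fluency import LexicalNetwork, ValidationError


class UndefinedMetricError(ValidationError):
    """Raised when a metric is undefined for the given graph (too small)."""


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, LexicalNetwork) else network


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering_coefficient(network, mode: str = "unweighted") -> float:
    """Mean local clustering coefficient, in [0, 1]."""
    G = _as_graph(network)
    if G.number_of_nodes() < 3:
        raise UndefinedMetricError("clustering undefined for fewer than 3 nodes")
    if mode == "unweighted":
        return float(nx.average_clustering(G, count_zeros=True))
    if mode == "weighted":
        return float(np.mean([_barrat_local(G, u) for u in G.nodes]))
    raise ValidationError("mode must be unweighted|weighted")


def _barrat_local(G: nx.Graph, u) -> float:
    nbrs = [
        v for v in G.neighbors(u) if v != u and G[u][v].get("weight", 1.0) > 0
    ]
    k = len(nbrs)
    if k < 2:
        return 0.0
    s = sum(G[u][v]["weight"] for v in nbrs)
    acc = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            j, h = nbrs[a], nbrs[b]
            if G.has_edge(j, h) and G[j][h].get("weight", 1.0) > 0:
                # (w_uj + w_uh)/2 summed over ordered pairs = unhalved sum
                # over unordered pairs; reduces to Watts-Strogatz on unit weights
                acc += G[u][j]["weight"] + G[u][h]["weight"]
    return acc / (s * (k - 1))


# ---------------------------------------------------------------------------
# path length
# ---------------------------------------------------------------------------

def average_shortest_path_length(network, mode: str = "hops") -> float:
    """Mean shortest-path length over unordered node pairs.

    ``hops`` treats every edge as length 1; ``weighted-distance`` runs
    Dijkstra on the distance transform 1 - r (similarity networks) or on the
    weights directly when the network already carries distances.  On a
    disconnected graph the mean is taken over the largest connected
    component, with a warning.
    """
    if mode not in ("hops", "weighted-distance"):
        raise ValidationError("mode must be hops|weighted-distance")
    G = _as_graph(network)
    if G.number_of_nodes() < 2:
        raise UndefinedMetricError("ASPL undefined for fewer than 2 nodes")
    if not nx.is_connected(G):
        warnings.warn("graph disconnected; ASPL computed on the largest component")
        comp = max(nx.connected_components(G), key=len)
        if len(comp) < 2:
            raise UndefinedMetricError("largest component is a singleton")
        G = G.subgraph(comp)
    if mode == "hops":
        return float(nx.average_shortest_path_length(G))
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    similarity = (
        network.weight_interpretation == "similarity"
        if isinstance(network, LexicalNetwork)
        else True
    )
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0)
        dist = 1.0 - w if similarity else w
        if dist < 0:
            raise ValidationError("negative distance; check weight interpretation")
        H.add_edge(u, v, dist=dist)
    return float(nx.average_shortest_path_length(H, weight="dist"))


# ---------------------------------------------------------------------------
# small-world index
# ---------------------------------------------------------------------------

def small_world_index(cc: float, ccran: float, aspl: float, asplran: float) -> float:
    """S = (CC / CCran) / (ASPL / ASPLran); S > 1 indicates small-world
    organisation relative to the random baseline."""
    for name, v in (("cc", cc), ("ccran", ccran), ("aspl", aspl), ("asplran", asplran)):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name} must be finite and > 0, got {v}")
    return (cc / ccran) / (aspl / asplran)


# ---------------------------------------------------------------------------
# communities / modularity
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Node -> community-id map together with its recomputed modularity."""

    assignment: dict
    q: float
    method: str

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[set]:
        groups: dict = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]


def modularity(network, assignment: dict, weighted: bool = True) -> float:
    """Q = sum_c [ e_c/m - (d_c/2m)^2 ], computed from the definition."""
    G = _as_graph(network)
    m = 0.0
    e: dict = {}
    d: dict = {}
    for u, v, data in G.edges(data=True):
        w = data.get("weight", 1.0) if weighted else 1.0
        m += w
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + w
        d[cu] = d.get(cu, 0.0) + w
        d[cv] = d.get(cv, 0.0) + w
    if m == 0:
        return 0.0
    comms = set(assignment.values())
    return float(
        sum(e.get(c, 0.0) / m - (d.get(c, 0.0) / (2 * m)) ** 2 for c in comms)
    )


def _partition_to_assignment(parts) -> dict:
    assignment = {}
    # stable community ids: order communities by their smallest node label
    ordered = sorted(parts, key=lambda p: sorted(map(str, p))[0])
    for cid, nodes in enumerate(ordered):
        for node in nodes:
            assignment[node] = cid
    return assignment


def detect_communities(
    network, method: str = "louvain", weighted: bool = True, seed: int = 0
) -> CommunityPartition:
    """Partition the graph into communities maximizing modularity.

    ``louvain`` (default, deterministic given seed) and ``greedy`` (CNM,
    deterministic) are heuristics; ``exact`` enumerates all set partitions
    (guarded to <= 12 nodes).  An edgeless graph yields singleton
    communities with q = 0.  The reported q is always recomputed from the
    returned assignment via :func:`modularity`.
    """
    G = _as_graph(network)
    weight_key = "weight" if weighted else None
    if G.number_of_edges() == 0:
        assignment = {u: i for i, u in enumerate(G.nodes)}
        return CommunityPartition(assignment, 0.0, method="singletons")
    if method == "louvain":
        parts = nxcommunity.louvain_communities(G, weight=weight_key, seed=seed)
    elif method == "greedy":
        parts = nxcommunity.greedy_modularity_communities(G, weight=weight_key)
    elif method == "exact":
        if G.number_of_nodes() > 12:
            raise ValidationError("exact search limited to 12 nodes")
        parts = _exact_best_partition(G, weighted=weighted)
    else:
        raise ValidationError("method must be louvain|greedy|exact")
    assignment = _partition_to_assignment([set(p) for p in parts])
    q = modularity(G, assignment, weighted=weighted)
    return CommunityPartition(assignment, q, method=method)


def _exact_best_partition(G: nx.Graph, weighted: bool) -> list[set]:
    from sympy.utilities.iterables import multiset_partitions

    nodes = list(G.nodes)
    best_q, best = -np.inf, [set(nodes)]
    for parts in multiset_partitions(nodes):
        assignment = {u: i for i, p in enumerate(parts) for u in p}
        q = modularity(G, assignment, weighted=weighted)
        if q > best_q:
            best_q, best = q, [set(p) for p in parts]
    return best


# ---------------------------------------------------------------------------
# summary container
# ---------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    """The reported parameter set: n, CC, ASPL, S, Q plus the null baselines
    (CCran, ASPLran) used to form S and the modes they were computed under."""

    n: int
    cc: float
    aspl: float
    s: float
    q: float
    ccran: float
    asplran: float
    cc_mode: str = "unweighted"
    aspl_mode: str = "hops"
    community_method: str = "louvain"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "cc": self.cc,
            "aspl": self.aspl,
            "s": self.s,
            "q": self.q,
            "ccran": self.ccran,
            "asplran": self.asplran,
            "modes": {
                "cc": self.cc_mode,
                "aspl": self.aspl_mode,
                "community": self.community_method,
            },
            "seed": self.seed,
        }


def summarize_network(
    network,
    ccran: float,
    asplran: float,
    cc_mode: str = "unweighted",
    aspl_mode: str = "hops",
    community_method: str = "louvain",
    weighted_communities: bool = True,
    seed: int = 0,
) -> NetworkMetrics:
    """Compute the full parameter set against a supplied null baseline."""
    G = _as_graph(network)
    cc = clustering_coefficient(network, mode=cc_mode)
    aspl = average_shortest_path_length(network, mode=aspl_mode)
    part = detect_communities(
        network, method=community_method, weighted=weighted_communities, seed=seed
    )
    s = small_world_index(cc, ccran, aspl, asplran)
    return NetworkMetrics(
        n=G.number_of_nodes(),
        cc=cc,
        aspl=aspl,
        s=s,
        q=part.q,
        ccran=ccran,
        asplran=asplran,
        cc_mode=cc_mode,
        aspl_mode=aspl_mode,
        community_method=community_method,
        seed=seed,
    )
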