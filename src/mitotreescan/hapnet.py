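"""Parsimony haplotype network construction and branch enumeration.

Nodes are observed haplotypes; each edge segment corresponds to one
mutational step, so an edge between haplotypes at Hamming distance *d*
is subdivided by *d - 1* latent (unobserved, degree-2) placeholder
nodes.  The network is the union of all minimum spanning trees of the
complete Hamming-distance graph over haplotypes: where the MST is
unique this is a tree, and equally parsimonious alternative connections
appear as reticulation loops.  Each loop resolution (a minimum spanning
tree contained in the network) is analysed separately downstream.

Cutting a branch (an observed-node-to-observed-node edge) bipartitions
the haplotypes into two allelic classes; the side away from the root is
the *clade* defined by that branch.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import CapacityError, ConsistencyError, DegenerateInputError
from .mtvar import HaplotypeTable, Variant


def hamming_distance(set_a: frozenset, set_b: frozenset) -> int:
    """Size of the symmetric difference of two variant sets."""
    return len(set_a ^ set_b)


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    variants: frozenset[Variant]

    @property
    def length(self) -> int:
        return len(self.variants)

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.node_a, self.node_b)))  # type: ignore[return-value]

    @property
    def n_latent(self) -> int:
        """Number of degree-2 placeholder nodes subdividing this edge."""
        return self.length - 1


@dataclass
class HaplotypeNetwork:
    """Union-of-MSTs haplotype network (minimum spanning network)."""

    node_counts: dict[str, int]
    node_variants: dict[str, frozenset[Variant]]
    edges: list[NetworkEdge]
    mst_weight: int

    @property
    def observed_nodes(self) -> list[str]:
        return sorted(self.node_counts)

    @property
    def n_loops(self) -> int:
        """Dimension of the cycle space (number of independent loops)."""
        return len(self.edges) - len(self.node_counts) + 1

    @property
    def loops(self) -> list[list[tuple[str, str]]]:
        """A cycle basis, each cycle as a list of (node, node) edges."""
        g = self.to_networkx(expand_latent=False)
        cycles = nx.cycle_basis(g)
        out = []
        for cyc in cycles:
            out.append([tuple(sorted((cyc[i], cyc[(i + 1) % len(cyc)])))
                        for i in range(len(cyc))])
        return out

    def to_networkx(self, expand_latent: bool = True) -> nx.Graph:
        g = nx.Graph()
        for n in self.observed_nodes:
            g.add_node(n, count=self.node_counts[n], observed=True)
        latent_i = 0
        for e in self.edges:
            labels = ";".join(sorted(v.label for v in e.variants))
            if not expand_latent or e.length <= 1:
                g.add_edge(e.node_a, e.node_b, weight=e.length, variants=labels)
            else:
                chain = [e.node_a]
                for _ in range(e.n_latent):
                    latent_i += 1
                    lid = f"LAT{latent_i:04d}"
                    g.add_node(lid, count=0, observed=False)
                    chain.append(lid)
                chain.append(e.node_b)
                for a, b in zip(chain, chain[1:]):
                    g.add_edge(a, b, weight=1, variants=labels)
        return g


def build_network(haplotypes: HaplotypeTable) -> HaplotypeNetwork:
    """Union of all minimum spanning trees of the Hamming-distance graph.

    An edge belongs to some MST iff its endpoints are not yet connected by
    strictly lighter edges (Kruskal cycle property applied per weight
    class), so ties are retained rather than broken arbitrarily.
    """
    if haplotypes.n_haplotypes < 2:
        raise DegenerateInputError(
            f"need at least 2 haplotypes, got {haplotypes.n_haplotypes}")
    ids = [h.haplotype_id for h in haplotypes.haplotypes]
    vsets = {h.haplotype_id: h.variants for h in haplotypes.haplotypes}
    counts = {h.haplotype_id: h.n_members for h in haplotypes.haplotypes}

    all_edges = sorted(
        ((hamming_distance(vsets[a], vsets[b]), a, b)
         for a, b in itertools.combinations(sorted(ids), 2)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    uf = nx.utils.UnionFind(ids)
    kept: list[NetworkEdge] = []
    mst_weight = 0
    n_joined = 0
    for w, group in itertools.groupby(all_edges, key=lambda t: t[0]):
        group = list(group)
        in_some_mst = [(a, b) for _, a, b in group if uf[a] != uf[b]]
        for a, b in in_some_mst:
            kept.append(NetworkEdge(a, b, vsets[a] ^ vsets[b]))
            if uf[a] != uf[b]:
                mst_weight += w
                n_joined += 1
            uf.union(a, b)
        if n_joined == len(ids) - 1:
            break
    return HaplotypeNetwork(counts, vsets, kept, mst_weight)


# ---------------------------------------------------------------------------
# Loop resolutions
# ---------------------------------------------------------------------------

@dataclass
class SpanningTree:
    """One loop resolution: a minimum spanning tree inside the network."""

    resolution_id: int
    node_counts: dict[str, int]
    node_variants: dict[str, frozenset[Variant]]
    edges: list[NetworkEdge]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n, c in self.node_counts.items():
            g.add_node(n, count=c, observed=True)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, weight=e.length)
        return g

    @property
    def weight(self) -> int:
        return sum(e.length for e in self.edges)


def _count_spanning_trees(g: nx.MultiGraph) -> int:
    """Matrix-tree count of spanning trees of a small (multi)graph."""
    nodes = sorted(g.nodes)
    if len(nodes) == 1:
        return 1
    idx = {n: i for i, n in enumerate(nodes)}
    lap = np.zeros((len(nodes), len(nodes)))
    for a, b in g.edges():
        i, j = idx[a], idx[b]
        lap[i, i] += 1
        lap[j, j] += 1
        lap[i, j] -= 1
        lap[j, i] -= 1
    minor = lap[1:, 1:]
    return int(round(np.linalg.det(minor)))


def _piece_spanning_trees(edges: list[tuple[str, str, NetworkEdge]],
                          nodes: set[str], cap: int) -> list[tuple[NetworkEdge, ...]]:
    """All spanning trees of one contracted tie-cluster, as edge tuples."""
    need = len(nodes) - 1
    out: list[tuple[NetworkEdge, ...]] = []
    for combo in itertools.combinations(range(len(edges)), need):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((edges[i][0], edges[i][1]) for i in combo)
        if g.number_of_edges() == need and nx.is_connected(g):
            out.append(tuple(edges[i][2] for i in combo))
            if len(out) > cap:
                break
    return out


def enumerate_loop_resolutions(
    net: HaplotypeNetwork, max_resolutions: int = 64
) -> list[SpanningTree]:
    """All minimum spanning trees contained in the network.

    Each resolution removes one edge per independent loop such that the
    remainder is a connected tree of minimum total weight.  A loop-free
    network yields a single resolution identical to the input.

    MSTs factor over the network's weight classes: within each class, the
    kept edges form tie-clusters on the components assembled from lighter
    edges, and any combination of one spanning tree per cluster is a
    minimum spanning tree.  The number of resolutions is counted exactly
    (matrix-tree theorem) before enumeration so oversize ambiguity fails
    fast with the count in the error.
    """
    if net.n_loops == 0:
        return [SpanningTree(0, dict(net.node_counts),
                             dict(net.node_variants), list(net.edges))]

    ids = sorted(net.node_counts)
    uf = nx.utils.UnionFind(ids)
    forced: list[NetworkEdge] = []
    clusters: list[tuple[list[tuple[str, str, NetworkEdge]], set[str]]] = []

    ordered = sorted(net.edges, key=lambda e: (e.length, e.key))
    total = 1
    for _, group in itertools.groupby(ordered, key=lambda e: e.length):
        group = list(group)
        contracted = nx.MultiGraph()
        for e in group:
            contracted.add_edge(uf[e.node_a], uf[e.node_b], edge=e)
        for comp in nx.connected_components(contracted):
            sub = contracted.subgraph(comp)
            piece = [(a, b, d["edge"]) for a, b, d in sub.edges(data=True)]
            if sub.number_of_edges() == len(comp) - 1:
                forced.extend(e for _, _, e in piece)
            else:
                total *= _count_spanning_trees(nx.MultiGraph(sub))
                clusters.append((piece, set(comp)))
        for e in group:
            uf.union(e.node_a, e.node_b)
    if total > max_resolutions:
        raise CapacityError(
            f"{total} loop resolutions exceed the cap of {max_resolutions}")

    choice_sets = [_piece_spanning_trees(piece, nodes, max_resolutions)
                   for piece, nodes in clusters]
    resolutions: list[SpanningTree] = []
    for combo in itertools.product(*choice_sets):
        kept = forced + [e for alt in combo for e in alt]
        kept.sort(key=lambda e: e.key)
        resolutions.append(SpanningTree(len(resolutions), dict(net.node_counts),
                                        dict(net.node_variants), kept))
    return resolutions


# ---------------------------------------------------------------------------
# Branch enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """A tree edge between observed haplotypes and its induced bipartition.

    ``side_a`` is the clade (the side away from the root); ``side_b`` the
    remainder.  ``signature`` identifies the bipartition independently of
    rooting and of the resolution it came from.
    """

    branch_id: int
    resolution_id: int
    variants: frozenset[Variant]
    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ConsistencyError("branch bipartition has an empty side")
        if self.side_a & self.side_b:
            raise ConsistencyError("branch sides overlap")
        if len(self.variants) < 1:
            raise ConsistencyError("branch must carry at least one variant")

    @property
    def signature(self) -> frozenset[str]:
        """Canonical side: the smaller one (ties: lexicographically first)."""
        if (len(self.side_a), tuple(sorted(self.side_a))) <= (
                len(self.side_b), tuple(sorted(self.side_b))):
            return self.side_a
        return self.side_b

    @property
    def variant_labels(self) -> str:
        return ";".join(sorted(v.label for v in self.variants))


def network_root(node_counts: dict[str, int]) -> str:
    """Deterministic root: largest membership, ties broken lexicographically."""
    return min(node_counts, key=lambda n: (-node_counts[n], n))


def enumerate_branches(tree: SpanningTree) -> list[Branch]:
    """One branch per observed-to-observed edge, numbered in BFS order.

    The tree is rooted at the most frequent haplotype; each branch's
    ``side_a`` is the set of haplotypes on the far side of the cut (the
    clade it defines).
    """
    g = tree.to_networkx()
    n_nodes = g.number_of_nodes()
    if g.number_of_edges() != n_nodes - 1 or not nx.is_connected(g):
        raise ConsistencyError("branch enumeration requires a loop-free tree")
    root = network_root(tree.node_counts)
    edge_lookup = {e.key: e for e in tree.edges}
    all_nodes = frozenset(tree.node_counts)

    branches: list[Branch] = []
    parent: dict[str, str] = {}
    order: list[tuple[str, str]] = []
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in sorted(g.neighbors(u)):
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append((u, v))
                queue.append(v)

    # subtree sets bottom-up
    subtree: dict[str, set[str]] = {n: {n} for n in g.nodes}
    for u, v in reversed(order):
        subtree[u] |= subtree[v]

    for bid, (u, v) in enumerate(order, start=1):
        side_a = frozenset(subtree[v])
        branches.append(Branch(
            branch_id=bid,
            resolution_id=tree.resolution_id,
            variants=edge_lookup[tuple(sorted((u, v)))].variants,
            side_a=side_a,
            side_b=all_nodes - side_a,
        ))
    return branches


def branch_table(branches: list[Branch]) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "branch_id": [b.branch_id for b in branches],
            "resolution_id": [b.resolution_id for b in branches],
            "variants": [b.variant_labels for b in branches],
            "clade_haplotypes": [";".join(sorted(b.side_a)) for b in branches],
            "clade_size": [len(b.side_a) for b in branches],
        }
    )
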