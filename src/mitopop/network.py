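"""Median-joining haplotype networks and rho-statistic coalescence dating.

Haplotypes are points in a finite state space with one column per occupied
(position, insert_index) site; distances count differing columns. The
median-joining construction unites all minimum spanning trees (with an
optional epsilon relaxation) and augments them with majority-consensus
median vectors — inferred unsampled intermediates — until no new median
shortens the network, then discards medians that end up as mere pass-through
nodes. Coalescence ages come from the rho statistic (mean mutational
distance to a designated root) scaled by the molecular clock, with the
Saillard standard error.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .haplotyping import DEFAULT_EXCLUSIONS, ExclusionRules, dedup_by_site
from .model import (
    Motif,
    PhyloTree,
    RateConfig,
    ReferenceSegment,
    SampleRecord,
    Variant,
    VariantKind,
)


def hamming_motif_distance(a: Motif, b: Motif) -> int:
    """Number of (position, insert_index) sites at which two motifs differ.

    Sites occupied in only one motif count as one difference (variant vs
    reference state); sites occupied in both count when their states differ.
    """
    sa, sb = a.site_states(), b.site_states()
    d = 0
    for site in sa.keys() | sb.keys():
        if sa.get(site) != sb.get(site):
            d += 1
    return d


# -- internal state-vector encoding -----------------------------------------


class _Space:
    """Columnar encoding of motifs over the union of occupied sites."""

    def __init__(self, motifs: Iterable[Motif]) -> None:
        motifs = list(motifs)
        sites: set[tuple[int, int]] = set()
        for m in motifs:
            sites.update(m.site_states())
        self.sites = sorted(sites)
        self.site_index = {s: i for i, s in enumerate(self.sites)}
        # state code 0 = reference; variant states numbered per column
        self.codes: list[dict[tuple[VariantKind, str], int]] = [
            {} for _ in self.sites
        ]
        self.decode: list[dict[int, tuple[VariantKind, str]]] = [
            {} for _ in self.sites
        ]
        for m in motifs:
            self.encode(m)

    def encode(self, motif: Motif) -> tuple[int, ...]:
        vec = [0] * len(self.sites)
        for site, ks in motif.site_states().items():
            i = self.site_index[site]
            col = self.codes[i]
            if ks not in col:
                code = len(col) + 1
                col[ks] = code
                self.decode[i][code] = ks
            vec[i] = col[ks]
        return tuple(vec)

    def to_motif(self, vec: Sequence[int]) -> Motif:
        variants = []
        for i, code in enumerate(vec):
            if code:
                kind, state = self.decode[i][code]
                pos, idx = self.sites[i]
                variants.append(Variant(pos, idx, kind, state))
        return Motif(variants)


def _distance_matrix(vectors: list[tuple[int, ...]]) -> np.ndarray:
    arr = np.asarray(vectors, dtype=np.int16)
    if arr.ndim == 1:
        arr = arr.reshape(len(vectors), 0)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def _msn_edges(dist: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A pair (u, v) is linked iff d(u, v) <= merge_level(u, v) + epsilon, where
    merge_level is the distance threshold at which u and v first fall into
    one connected component when links are admitted in ascending order. With
    epsilon = 0 this is exactly the union of all minimum spanning trees.
    """
    n = len(dist)
    if n <= 1:
        return []
    merge_level = np.full((n, n), -1, dtype=np.int64)
    comp = list(range(n))
    levels = np.unique(dist[np.triu_indices(n, k=1)])
    for level in levels:
        pairs = np.argwhere(np.triu(dist == level, k=1))
        for u, v in pairs:
            ru, rv = comp[u], comp[v]
            if ru != rv:
                for i in range(n):
                    if comp[i] == rv:
                        comp[i] = ru
        newly = (merge_level < 0) & np.equal.outer(comp, comp)
        merge_level[newly] = level
        if len(set(comp)) == 1 and epsilon == 0:
            break
    edges = []
    for u in range(n):
        for v in range(u + 1, n):
            if merge_level[u, v] >= 0 and dist[u, v] <= merge_level[u, v] + epsilon:
                edges.append((u, v, int(dist[u, v])))
    return edges


def _median(u: Sequence[int], v: Sequence[int], w: Sequence[int]) -> tuple[int, ...]:
    """Per-column majority state of three vectors; all-distinct ties keep the
    center node's state (u), a pinned deterministic convention."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b)
        else:
            out.append(a)  # a == b, a == c, or three distinct -> center wins
    return tuple(out)


class HaplotypeNetwork:
    """Sampled and median haplotype nodes with mutation-step edge lengths."""

    def __init__(self, graph: nx.Graph, epsilon: int = 0) -> None:
        self.graph = graph
        self.epsilon = epsilon

    @property
    def total_length(self) -> int:
        return sum(l for _, _, l in self.graph.edges(data="length"))

    def sampled_nodes(self) -> list[str]:
        return [k for k, s in self.graph.nodes(data="sampled") if s]

    def median_nodes(self) -> list[str]:
        return [k for k, s in self.graph.nodes(data="sampled") if not s]

    def node_motif(self, key: str) -> Motif:
        return self.graph.nodes[key]["motif"]

    def __contains__(self, motif: Motif) -> bool:
        return str(motif) in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def median_joining(
    haplotypes: Sequence[tuple[Motif, int]],
    epsilon: int = 0,
    anchors: Sequence[Motif] = (),
) -> HaplotypeNetwork:
    """Build the median-joining network of the given haplotypes.

    Repeats: (1) form the epsilon-relaxed minimum spanning network over the
    current node set; (2) for every node and pair of its network neighbours,
    compute the majority-consensus median vector; (3) add the medians not
    yet present; until no new median appears. Finally, unsampled medians of
    degree <= 2 are deleted (they lie on paths the remaining links already
    realize) and the network is rebuilt. Nodes are processed in lexicographic
    motif order, making the construction deterministic. ``anchors`` are extra
    motifs (e.g. an ancestral root) forced to survive as unsampled nodes.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    mult: dict[Motif, int] = {}
    for motif, m in haplotypes:
        if m < 1:
            raise ValueError("multiplicities must be positive")
        mult[motif] = mult.get(motif, 0) + m
    anchor_set = {a for a in anchors if a not in mult}
    space = _Space(list(mult) + list(anchor_set))

    sampled_vecs = {space.encode(m) for m in mult}
    anchor_vecs = {space.encode(m) for m in anchor_set}
    protected = sampled_vecs | anchor_vecs
    nodes: list[tuple[int, ...]] = sorted(
        protected, key=lambda v: str(space.to_motif(v))
    )
    known = set(nodes)

    while True:
        dist = _distance_matrix(nodes)
        edges = _msn_edges(dist, epsilon)
        adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
        for u, v, _ in edges:
            adj[u].append(v)
            adj[v].append(u)
        arr = np.asarray(nodes, dtype=np.int16)
        if arr.ndim == 1:
            arr = arr.reshape(len(nodes), 0)
        found_new = False
        for u in range(len(nodes)):
            nbrs = sorted(adj[u])
            if len(nbrs) < 2:
                continue
            A = arr[nbrs]  # (m, C)
            B, C = A[:, None, :], A[None, :, :]
            meds = np.where(B == C, B, arr[u])  # (m, m, C)
            iu = np.triu_indices(len(nbrs), k=1)
            for med in map(tuple, np.unique(meds[iu], axis=0).tolist()):
                if med not in known:
                    known.add(med)
                    found_new = True
        if not found_new:
            break
        nodes = sorted(known, key=lambda v: str(space.to_motif(v)))

    # prune pass-through medians
    while True:
        dist = _distance_matrix(nodes)
        edges = _msn_edges(dist, epsilon)
        degree = [0] * len(nodes)
        for u, v, _ in edges:
            degree[u] += 1
            degree[v] += 1
        removable = [
            i
            for i, vec in enumerate(nodes)
            if vec not in protected and degree[i] <= 2
        ]
        if not removable or len(nodes) == 1:
            break
        drop = set(removable)
        nodes = [vec for i, vec in enumerate(nodes) if i not in drop]

    dist = _distance_matrix(nodes)
    edges = _msn_edges(dist, epsilon)
    graph = nx.Graph()
    for vec in nodes:
        motif = space.to_motif(vec)
        graph.add_node(
            str(motif),
            motif=motif,
            sampled=vec in sampled_vecs,
            multiplicity=mult.get(motif, 0),
        )
    for u, v, l in edges:
        graph.add_edge(
            str(space.to_motif(nodes[u])), str(space.to_motif(nodes[v])), length=l
        )
    return HaplotypeNetwork(graph, epsilon=epsilon)


def extract_rooted_tree(
    net: HaplotypeNetwork,
    root: Motif,
    attach_if_absent: bool = True,
) -> nx.DiGraph:
    """Shortest-path tree of the network from the designated ancestral node.

    Reticulations resolve toward the lexicographically smaller parent. If
    the root motif is not a network node it may be attached to its nearest
    node by one extra link (``attach_if_absent``); a root farther than one
    mutation from the network is rejected.
    """
    graph = net.graph.copy()
    root_key = str(root)
    if root_key not in graph:
        if not attach_if_absent:
            raise ValueError(f"root {root_key!r} is not a network node")
        candidates = sorted(
            (hamming_motif_distance(root, attrs["motif"]), key)
            for key, attrs in graph.nodes(data=True)
        )
        d, nearest = candidates[0]
        if d > 1:
            raise ValueError(
                f"root {root_key!r} is {d} mutations from the network; "
                "not placeable"
            )
        graph.add_node(root_key, motif=root, sampled=False, multiplicity=0)
        graph.add_edge(root_key, nearest, length=d)

    # Dijkstra with deterministic parent choice
    dist: dict[str, float] = {root_key: 0}
    parent: dict[str, Optional[str]] = {root_key: None}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0, root_key)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in graph.neighbors(u):
            nd = d + graph.edges[u, v]["length"]
            if v not in dist or nd < dist[v] or (nd == dist[v] and u < parent[v]):
                if v not in done:
                    dist[v] = nd
                    parent[v] = u
                    heapq.heappush(heap, (nd, v))
    missing = set(graph.nodes) - done
    if missing:
        raise ValueError(f"nodes unreachable from root: {sorted(missing)}")

    tree = nx.DiGraph()
    for key, attrs in graph.nodes(data=True):
        tree.add_node(key, **attrs)
    for child, par in parent.items():
        if par is not None:
            tree.add_edge(par, child, length=graph.edges[par, child]["length"])
    return tree


@dataclass
class RhoResult:
    """Rho-statistic age estimate for a rooted genealogy."""

    rho: float
    sigma: float
    n: int
    age_years: Optional[float] = None
    age_se_years: Optional[float] = None
    low_information: bool = False


def rho_statistic(
    tree: nx.DiGraph,
    rate: Optional[RateConfig] = None,
) -> RhoResult:
    """Mean mutational distance to the root, with the Saillard error.

    rho = (1/n) sum over sampled sequences of the path length to the root
    (multiplicities weighted); sigma^2 = (1/n^2) sum over links of
    l_link * n_link^2 with n_link the number of sampled sequences below the
    link. With a clock, age = rho * years_per_substitution.
    """
    roots = [k for k in tree if tree.in_degree(k) == 0]
    if len(roots) != 1:
        raise ValueError(f"rooted tree must have one root, found {len(roots)}")
    root = roots[0]
    order = list(nx.topological_sort(tree))
    depth: dict[str, int] = {root: 0}
    for u in order:
        for v in tree.successors(u):
            depth[v] = depth[u] + tree.edges[u, v]["length"]
    weights = {k: tree.nodes[k].get("multiplicity", 0) if
               tree.nodes[k].get("sampled") else 0 for k in tree}
    n = sum(weights.values())
    if n < 1:
        raise ValueError("no sampled sequences in the tree")

    rho = Fraction(sum(weights[k] * depth[k] for k in tree), n)

    below: dict[str, int] = {}
    for u in reversed(order):
        below[u] = weights[u] + sum(below[v] for v in tree.successors(u))
    var = Fraction(
        sum(tree.edges[u, v]["length"] * below[v] ** 2 for u, v in tree.edges), n**2
    )
    sigma = float(np.sqrt(float(var)))
    result = RhoResult(rho=float(rho), sigma=sigma, n=n)
    if rate is not None:
        result.age_years = float(rho) * rate.years_per_substitution
        result.age_se_years = sigma * rate.years_per_substitution
    return result


def date_clade(
    samples: Sequence[SampleRecord],
    haplogroup: str,
    tree_fixture: PhyloTree,
    rate: RateConfig = RateConfig(),
    segment: Optional[ReferenceSegment] = None,
    epsilon: int = 0,
    exclusions: ExclusionRules = DEFAULT_EXCLUSIONS,
) -> RhoResult:
    """Coalescence age of one haplogroup clade from sampled motifs.

    Applies the dating-scope relatedness rule (one sample per site), builds
    a median-joining network over the clade members plus the haplogroup's
    ancestral motif, roots the network at that motif and evaluates the rho
    statistic under the clock. With fewer than two distinct haplotypes the
    estimate is still returned but flagged low-information.
    """
    if haplogroup not in tree_fixture:
        raise ValueError(f"haplogroup {haplogroup!r} not in the tree fixture")
    clade = set(tree_fixture.descendants(haplogroup))
    members = [
        s
        for s in samples
        if s.haplogroup is not None
        and (s.haplogroup in clade)
        and s.motif is not None
    ]
    if not members:
        raise ValueError(f"no samples with motifs in clade {haplogroup!r}")
    members = dedup_by_site(members, scope="dating")

    root = tree_fixture.cumulative_motif(haplogroup)
    if segment is not None:
        root = root.restrict(segment.start, segment.end)
    haps: list[tuple[Motif, int]] = []
    for s in members:
        kept, _ = exclusions.split(s.motif)
        if segment is not None:
            kept = kept.restrict(segment.start, segment.end)
        haps.append((kept, s.multiplicity))

    net = median_joining(haps, epsilon=epsilon, anchors=[root])
    genealogy = extract_rooted_tree(net, root, attach_if_absent=True)
    result = rho_statistic(genealogy, rate=rate)
    if len({m for m, _ in haps}) < 2:
        result.low_information = True
    return result


def mst_total_length(motifs: Sequence[Motif]) -> int:
    """Total length of a minimum spanning tree over the given haplotypes."""
    space = _Space(motifs)
    vecs = sorted({space.encode(m) for m in motifs})
    if len(vecs) <= 1:
        return 0
    dist = _distance_matrix(vecs)
    g = nx.Graph()
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            g.add_edge(i, j, weight=int(dist[i, j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )
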