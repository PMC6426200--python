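"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own code paths: exact rational
hypergeometric enumeration for the Fisher test, explicit 0/1 pairwise-
distance sums for AMOVA, and exhaustive Steiner-point enumeration over the
binary hypercube for haplotype networks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx


def fisher_two_tailed_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed Fisher p as an exact rational, by full enumeration."""
    n_present, n_east, N = a + b, a + c, a + b + c + d
    if n_present in (0, N) or n_east in (0, N):
        return Fraction(1)
    denom = comb(N, n_east)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(n_present, k) * comb(N - n_present, n_east - k), denom)

    p_obs = pmf(a)
    lo, hi = max(0, n_present + n_east - N), min(n_present, n_east)
    return sum(
        (pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs), Fraction(0)
    )


def amova_phist_pairwise(counts_1, counts_2) -> float:
    """Phi_ST by summing explicit 0/1 distances over individual pairs."""
    pops = []
    for counts in (counts_1, counts_2):
        individuals = []
        for cat, k in enumerate(counts):
            individuals.extend([cat] * int(k))
        pops.append(individuals)
    everyone = pops[0] + pops[1]
    N = len(everyone)

    def ssd(group):
        n = len(group)
        total = sum(
            1 for i in range(n) for j in range(i + 1, n) if group[i] != group[j]
        )
        return total / n

    ssd_w = ssd(pops[0]) + ssd(pops[1])
    ssd_t = ssd(everyone)
    ssd_a = ssd_t - ssd_w
    n1, n2 = len(pops[0]), len(pops[1])
    sigma_w = ssd_w / (N - 2) if N > 2 else 0.0
    n_c = N - (n1**2 + n2**2) / N
    sigma_a = (ssd_a - sigma_w) / n_c if n_c > 0 else 0.0
    denom = sigma_a + sigma_w
    if denom <= 0:
        return 0.0
    return min(1.0, max(0.0, sigma_a / denom))


# -- Steiner-network oracle over the binary hypercube ------------------------


def hamming(a, b) -> int:
    return sum(x != y for x, y in zip(a, b))


def mst_length(vectors) -> int:
    """Prim MST total length over Hamming distances."""
    n = len(vectors)
    if n <= 1:
        return 0
    INF = 10**9
    in_tree = [False] * n
    dist = [INF] * n
    dist[0] = 0
    total = 0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=lambda i: dist[i])
        in_tree[u] = True
        total += dist[u]
        for v in range(n):
            if not in_tree[v]:
                d = hamming(vectors[u], vectors[v])
                if d < dist[v]:
                    dist[v] = d
    return total


def union_of_msts(vectors) -> set[tuple[int, int]]:
    """Edge set of the union of all MSTs (merge-level construction)."""
    n = len(vectors)
    comp = list(range(n))
    merge: dict[tuple[int, int], int] = {}
    dist = [[hamming(a, b) for b in vectors] for a in vectors]
    levels = sorted({dist[i][j] for i in range(n) for j in range(i + 1, n)})
    for level in levels:
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i][j] == level and comp[i] != comp[j]:
                    old = comp[j]
                    for k in range(n):
                        if comp[k] == old:
                            comp[k] = comp[i]
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in merge and comp[i] == comp[j]:
                    merge[(i, j)] = level
    return {(i, j) for (i, j), lvl in merge.items() if dist[i][j] <= lvl}


def optimal_steiner(terminals, k: int) -> tuple[int, frozenset]:
    """Exhaustive optimum over Steiner-point subsets of the k-hypercube.

    Returns (optimal Steiner tree length, union of node sets over all
    optimal solutions whose Steiner points are genuine junctions).
    """
    T = [tuple(t) for t in terminals]
    candidates = [
        v for v in itertools.product((0, 1), repeat=k) if v not in set(T)
    ]
    best = mst_length(T)
    optimal_subsets: list[tuple] = [()]
    for j in range(1, max(0, len(T) - 2) + 1):
        for S in itertools.combinations(candidates, j):
            L = mst_length(T + list(S))
            if L < best:
                best = L
                optimal_subsets = [S]
            elif L == best:
                optimal_subsets.append(S)
    nodes = set(T)
    for S in optimal_subsets:
        vectors = T + list(S)
        if mst_length(vectors) != best:
            continue
        edges = union_of_msts(vectors)
        degree: dict[int, int] = {}
        for i, j in edges:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        # pass-through Steiner points belong to a smaller, also-optimal subset
        if any(degree.get(len(T) + a, 0) <= 2 for a in range(len(S))):
            continue
        nodes.update(S)
    return best, frozenset(nodes)


def network_steiner_length(net) -> int:
    """Minimum spanning-subgraph length of a haplotype network.

    The shortest connected subgraph of the network that spans all sampled
    nodes, found by enumerating median-node subsets (small networks only).
    """
    g = net.graph
    sampled = [n for n, s in g.nodes(data="sampled") if s]
    medians = [n for n, s in g.nodes(data="sampled") if not s]
    best = None
    for j in range(len(medians) + 1):
        for S in itertools.combinations(medians, j):
            sub = g.subgraph(sampled + list(S))
            if len(sub) and not nx.is_connected(sub):
                continue
            tree = nx.minimum_spanning_tree(sub, weight="length")
            if tree.number_of_nodes() < len(sub):
                continue
            L = sum(d["length"] for _, _, d in tree.edges(data=True))
            if best is None or L < best:
                best = L
    return best
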