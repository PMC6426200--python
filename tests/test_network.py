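"""Median-joining networks, rooted-tree extraction and rho dating."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import motif_from_bits, network_bits
from mitopop import (
    RateConfig,
    date_clade,
    extract_rooted_tree,
    hamming_motif_distance,
    median_joining,
    rho_statistic,
)
from mitopop.model import Motif, SampleRecord
from mitopop.network import mst_total_length
from oracles import network_steiner_length, optimal_steiner

POSITIONS = [16001 + i for i in range(6)]


class TestHammingDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("16223T", "16223T", 0),
            ("16223T", "", 1),
            ("16223T 16311C", "16311C 16362C", 2),
            ("16093C", "16093T", 1),  # same site, different state
        ],
    )
    def test_examples(self, a, b, d):
        assert hamming_motif_distance(Motif.parse(a), Motif.parse(b)) == d
        assert hamming_motif_distance(Motif.parse(b), Motif.parse(a)) == d


class TestMedianJoining:
    def test_additive_chain_has_no_medians(self):
        haps = [
            (Motif(), 1),
            (Motif.parse("16126C"), 1),
            (Motif.parse("16126C 16189C"), 1),
        ]
        net = median_joining(haps)
        assert len(net) == 3
        assert net.median_nodes() == []
        assert net.total_length == 2

    def test_three_singletons_get_central_median(self):
        haps = [(Motif.parse(t), 1) for t in ("16111T", "16222T", "16333T")]
        net = median_joining(haps)
        assert len(net) == 4
        assert net.median_nodes() == [""]  # the empty (ancestral) motif
        assert net.total_length == 3

    def test_single_haplotype(self):
        net = median_joining([(Motif.parse("16223T"), 3)])
        assert len(net) == 1 and net.total_length == 0
        assert net.graph.nodes["16223T"]["multiplicity"] == 3

    def test_duplicate_motifs_merge_multiplicity(self):
        net = median_joining([(Motif.parse("16223T"), 1), (Motif.parse("16223T"), 2)])
        assert net.graph.nodes["16223T"]["multiplicity"] == 3

    def test_sampled_nodes_never_deleted(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            bits = {tuple(rng.integers(0, 2, size=5)) for _ in range(5)}
            haps = [(motif_from_bits(b, POSITIONS), 1) for b in bits]
            net = median_joining(haps)
            sampled = network_bits(net, POSITIONS[:5]) & bits
            assert sampled == bits

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            median_joining([(Motif(), 1)], epsilon=-1)

    def test_reticulation_retains_most_parsimonious_tree(self):
        # 4 terminals whose MJ network is cyclic; the shortest spanning
        # subgraph inside it must still realize the optimal Steiner length
        terms = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 1, 1)]
        net = median_joining([(motif_from_bits(t, POSITIONS), 1) for t in terms])
        L, nodes = optimal_steiner(terms, 3)
        assert network_steiner_length(net) == L
        assert network_bits(net, POSITIONS[:3]) == set(nodes)

    def test_small_inputs_match_steiner_oracle(self):
        vectors = list(itertools.product((0, 1), repeat=3))
        rng = np.random.default_rng(0)
        for _ in range(30):
            terms = [
                tuple(v)
                for v in rng.permutation(vectors)[: rng.integers(2, 6)]
            ]
            net = median_joining(
                [(motif_from_bits(t, POSITIONS), 1) for t in terms]
            )
            L, nodes = optimal_steiner(terms, 3)
            assert network_steiner_length(net) == L
            assert network_bits(net, POSITIONS[:3]) == set(nodes)
            assert network_steiner_length(net) <= mst_total_length(
                [motif_from_bits(t, POSITIONS) for t in terms]
            )


class TestRootedTree:
    def test_tree_shaped_network_unchanged(self):
        haps = [
            (Motif(), 1),
            (Motif.parse("16126C"), 1),
            (Motif.parse("16126C 16189C"), 1),
        ]
        net = median_joining(haps)
        tree = extract_rooted_tree(net, Motif())
        assert set(tree.edges) == {("", "16126C"), ("16126C", "16126C 16189C")}

    def test_four_cycle_resolved_by_lexicographic_tie_break(self):
        haps = [
            (Motif(), 1),
            (Motif.parse("16111T"), 1),
            (Motif.parse("16222T"), 1),
            (Motif.parse("16111T 16222T"), 1),
        ]
        net = median_joining(haps)
        assert net.graph.number_of_edges() == 4  # the reticulation square
        tree = extract_rooted_tree(net, Motif())
        # both spanning trees give equal root-leaf distances; parent of the
        # double mutant is the lexicographically smaller single mutant
        assert tree.has_edge("16111T", "16111T 16222T")
        depths = {n: 0 for n in tree}
        for u, v in nx.bfs_edges(tree, ""):
            depths[v] = depths[u] + tree.edges[u, v]["length"]
        assert depths["16111T 16222T"] == 2

    def test_root_only_node(self):
        net = median_joining([(Motif(), 1)])
        tree = extract_rooted_tree(net, Motif())
        assert list(tree.nodes) == [""]

    def test_absent_root_attached_within_one_mutation(self):
        net = median_joining([(Motif.parse("16223T"), 1)])
        tree = extract_rooted_tree(net, Motif())
        assert tree.has_edge("", "16223T")

    def test_distant_root_rejected(self):
        net = median_joining([(Motif.parse("16223T 16311C 16362C"), 1)])
        with pytest.raises(ValueError, match="not placeable"):
            extract_rooted_tree(net, Motif())


class TestRhoStatistic:
    def test_star_closed_form(self):
        haps = [
            (Motif.parse(f"{16011 + 20 * i}T {16012 + 20 * i}T"), 1)
            for i in range(4)
        ]
        net = median_joining(haps, anchors=[Motif()])
        tree = extract_rooted_tree(net, Motif())
        r = rho_statistic(tree, rate=RateConfig())
        assert r.rho == 2.0
        assert r.sigma == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert r.age_years == pytest.approx(2 * 3624.0)

    def test_all_samples_at_root(self):
        net = median_joining([(Motif(), 5)])
        r = rho_statistic(extract_rooted_tree(net, Motif()))
        assert r.rho == 0.0 and r.sigma == 0.0

    def test_unit_rho_maps_to_clock_rate(self):
        net = median_joining([(Motif.parse("16223T"), 1)], anchors=[Motif()])
        r = rho_statistic(extract_rooted_tree(net, Motif()), rate=RateConfig())
        assert r.rho == 1.0 and r.age_years == 3624.0

    def test_multiplicity_weighting(self):
        haps = [(Motif(), 3), (Motif.parse("16223T"), 1)]
        net = median_joining(haps)
        r = rho_statistic(extract_rooted_tree(net, Motif()))
        assert r.rho == pytest.approx(0.25)


class TestDateClade:
    def _samples(self, tree, segment, motifs, site=None):
        root = tree.cumulative_motif("U6b1a")
        out = []
        for i, extra in enumerate(motifs):
            motif = root.union(Motif.parse(extra)) if extra else root
            out.append(
                SampleRecord(
                    f"s{i}",
                    "GOM",
                    "ancient",
                    site=site or f"site{i}",
                    haplogroup="U6b1a",
                    motif=motif,
                )
            )
        return out

    def test_single_haplotype_flagged_low_information(self, tree, segment):
        samples = self._samples(tree, segment, [None])
        r = date_clade(samples, "U6b1a", tree, segment=segment)
        assert r.rho == 0.0 and r.low_information

    def test_site_duplicates_do_not_change_estimate(self, tree, segment):
        distinct = self._samples(tree, segment, [None, "16051G"])
        with_dupes = distinct + [
            SampleRecord(
                "zz",
                "GOM",
                "ancient",
                site=distinct[1].site,  # same site, will be deduplicated
                haplogroup="U6b1a",
                motif=distinct[1].motif,
            )
        ]
        a = date_clade(distinct, "U6b1a", tree, segment=segment)
        b = date_clade(with_dupes, "U6b1a", tree, segment=segment)
        assert (a.rho, a.sigma, a.n) == (b.rho, b.sigma, b.n)

    def test_descendant_haplogroups_included(self, tree, segment):
        samples = self._samples(tree, segment, [None, "16051G"])
        samples.append(
            SampleRecord(
                "sub",
                "GOM",
                "ancient",
                site="deep",
                haplogroup="U6b1a1",
                motif=tree.cumulative_motif("U6b1a1"),
            )
        )
        r = date_clade(samples, "U6b1a", tree, segment=segment)
        assert r.n == 3

    def test_unknown_clade_rejected(self, tree, segment):
        with pytest.raises(ValueError):
            date_clade([], "Q99", tree, segment=segment)
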