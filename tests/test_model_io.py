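"""Domain types, variant notation and file round trips."""

import json

import pandas as pd
import pytest

from mitopop import io as mio
from mitopop.model import (
    FrequencyTable,
    Motif,
    PhyloTree,
    ReferenceSegment,
    SampleRecord,
    TreeNode,
    Variant,
    VariantKind,
    compose_motifs,
    parse_variant_token,
)


class TestVariantNotation:
    @pytest.mark.parametrize(
        "token,canonical",
        [
            ("16223T", "16223T"),
            ("16223t", "16223T"),
            ("309iC", "309.1C"),
            ("309.1C", "309.1C"),
            ("309.2A", "309.2A"),
            ("16166d", "16166d"),
            ("@16189", "@16189"),
        ],
    )
    def test_canonical_round_trip(self, token, canonical):
        variants = parse_variant_token(token)
        assert len(variants) == 1
        assert str(variants[0]) == canonical
        assert parse_variant_token(canonical) == variants

    def test_multibase_insertion_expands(self):
        variants = parse_variant_token("309iCC")
        assert [str(v) for v in variants] == ["309.1C", "309.2C"]

    @pytest.mark.parametrize("bad", ["", "16223", "X16223", "16999999T", "0T"])
    def test_rejects_malformed_tokens(self, bad):
        with pytest.raises(ValueError):
            parse_variant_token(bad)

    def test_position_bound_honours_reference_length(self):
        parse_variant_token("16569T")
        with pytest.raises(ValueError, match="16999"):
            parse_variant_token("16999T")


class TestMotif:
    def test_order_invariant_and_hashable(self):
        a = Motif.parse("16311C 16223T")
        b = Motif.parse("16223T 16311C")
        assert a == b and hash(a) == hash(b)
        assert str(a) == "16223T 16311C"

    def test_back_mutation_composition_removes_ancestral_variant(self):
        base = Motif.parse("16172C 16311C")
        derived = compose_motifs(base, parse_variant_token("@16311"))
        assert derived == Motif.parse("16172C")

    def test_conflicting_duplicate_rejected(self):
        with pytest.raises(ValueError):
            Motif(
                [
                    Variant(16223, 0, VariantKind.SUBSTITUTION, "T"),
                    Variant(16223, 0, VariantKind.SUBSTITUTION, "C"),
                ]
            )


class TestFasta:
    def test_reads_identity_case(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        assert mio.read_fasta(p) == [("a", "ACGT")]

    def test_normalizes_case_and_uracil(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgu\n")
        assert mio.read_fasta(p) == [("a", "ACGT")]

    def test_duplicate_id_names_offender(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="'a'"):
            mio.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            mio.read_fasta(p)

    def test_non_iupac_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">bad\nAC9T\n")
        with pytest.raises(ValueError, match="'bad'"):
            mio.read_fasta(p)

    def test_write_read_round_trip(self, tmp_path):
        records = [("s1", "ACGT" * 30), ("s2", "TTTT")]
        p = tmp_path / "out.fasta"
        mio.write_fasta(records, p)
        assert mio.read_fasta(p) == records


class TestSampleTable:
    def test_parses_motif_and_fields(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "sample_id\tisland\tperiod\tsite\thaplogroup\tmotif\n"
            "s1\tGCA\tancient\tGuayadeque\tU6b1a\t16163G 16172C\n"
        )
        (rec,) = mio.read_sample_table(p)
        assert rec.island == "GCA" and rec.haplogroup == "U6b1a"
        assert len(rec.motif) == 2

    def test_out_of_range_motif_names_row(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "sample_id\tisland\tperiod\tmotif\ns1\tGCA\tancient\t16999T\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            mio.read_sample_table(p)

    def test_empty_motif_cell_gives_empty_motif(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tisland\tperiod\tmotif\ns1\tHIE\tancient\t\n")
        (rec,) = mio.read_sample_table(p)
        assert rec.motif == Motif()

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tperiod\ns1\tancient\n")
        with pytest.raises(ValueError, match="island"):
            mio.read_sample_table(p)

    def test_unknown_island_mapped_to_other(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tisland\tperiod\ns1\tATLANTIS\tancient\n")
        assert mio.read_sample_table(p)[0].island == "other"

    def test_round_trip(self, tmp_path):
        samples = [
            SampleRecord("s1", "GOM", "ancient", site="x",
                         haplogroup="U6b1a", motif=Motif.parse("16163G")),
            SampleRecord("s2", "TFE", "modern"),
        ]
        p = tmp_path / "s.tsv"
        mio.write_sample_table(samples, p)
        back = mio.read_sample_table(p)
        assert [s.sample_id for s in back] == ["s1", "s2"]
        assert back[0].motif == samples[0].motif


class TestFrequencyTableIO:
    def test_tsv_round_trip_preserves_layout(self, tmp_path, table1):
        p = tmp_path / "t.tsv"
        mio.write_frequency_table(table1, p)
        back = mio.read_frequency_table(p)
        assert back == table1
        assert back.populations == table1.populations

    def test_table1_population_totals(self, table1):
        assert list(table1.n_g) == [70, 35, 53, 57, 87, 20]
        assert table1.total == 322

    def test_pooling_merges_rows(self, table1):
        pooled = table1.pooled(["GCA", "LAN&FUE"], "EAST")
        assert pooled.n_g["EAST"] == 107
        assert pooled.total == 322


class TestPhyloTreeIO:
    def test_round_trip(self, tmp_path, tree):
        p = tmp_path / "tree.json"
        mio.write_phylotree(tree, p)
        back = mio.read_phylotree(p)
        assert set(back.nodes) == set(tree.nodes)
        for label in tree:
            assert back.cumulative_motif(label) == tree.cumulative_motif(label)

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree({"a": TreeNode(None, ()), "b": TreeNode(None, ())})

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree(
                {
                    "r": TreeNode(None, ()),
                    "a": TreeNode("b", ()),
                    "b": TreeNode("a", ()),
                }
            )


class TestNetworkIO:
    @pytest.mark.parametrize("fmt", ["json", "gml"])
    def test_single_node_round_trip(self, tmp_path, fmt):
        from mitopop import median_joining

        net = median_joining([(Motif.parse("16223T"), 2)])
        p = tmp_path / f"net.{fmt}"
        mio.write_network(net, p, format=fmt)
        back = mio.read_network(p, format=fmt)
        assert set(back.graph.nodes) == {"16223T"}
        assert back.graph.nodes["16223T"]["multiplicity"] == 2

    @pytest.mark.parametrize("fmt", ["json", "gml"])
    def test_chain_and_median_flag_round_trip(self, tmp_path, fmt):
        from mitopop import median_joining

        haps = [(Motif(), 1), (Motif.parse("16126C"), 1),
                (Motif.parse("16126C 16189C"), 1)]
        net = median_joining(haps)
        assert net.graph.number_of_edges() == 2
        star = median_joining(
            [(Motif.parse(t), 1) for t in ("16111T", "16222T", "16333T")]
        )
        for src in (net, star):
            p = tmp_path / f"n.{fmt}"
            mio.write_network(src, p, format=fmt)
            back = mio.read_network(p, format=fmt)
            assert set(back.graph.nodes) == set(src.graph.nodes)
            assert set(back.median_nodes()) == set(src.median_nodes())
            for u, v, d in src.graph.edges(data=True):
                assert back.graph.edges[u, v]["length"] == d["length"]

    def test_unknown_format_rejected(self, tmp_path):
        from mitopop import median_joining

        net = median_joining([(Motif(), 1)])
        with pytest.raises(ValueError):
            mio.write_network(net, tmp_path / "x", format="xml")


def test_reference_segment_validation():
    seg = ReferenceSegment("w", "ACGT", 16000, 16003)
    assert seg.base_at(16001) == "C"
    with pytest.raises(ValueError):
        ReferenceSegment("w", "ACGT", 16000, 16010)
    with pytest.raises(ValueError):
        seg.base_at(15999)
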