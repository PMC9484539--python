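import numpy as np
import networkx as nx
import pandas as pd
import pytest

from cernakit.cerna_net import CeRNAEdge
from cernakit.circ_annot import CircJunction
from cernakit.io_formats import (
    GeneModel,
    ParseError,
    read_counts,
    read_fasta,
    read_gmt,
    read_gtf,
    read_junctions,
    read_network_tsv,
    read_signatures,
    read_survival,
    read_target_table,
    merge_target_tables,
    write_counts,
    write_fasta,
    write_gtf,
    write_junctions,
    write_network,
    write_signatures,
)
from cernakit.matrix import ExpressionMatrix, ValidationError
from cernakit.ntp import TemplateSignature


class TestExpressionMatrix:
    def test_duplicate_feature_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"],
                          columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="duplicate feature"):
            ExpressionMatrix(df)

    def test_negative_count_located(self):
        df = pd.DataFrame([[1, -2]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="s2"):
            ExpressionMatrix(df)

    def test_missing_sample_metadata_rejected(self):
        df = pd.DataFrame([[1, 2]], index=["a"], columns=["s1", "s2"])
        meta = pd.DataFrame({"condition": ["tumor"]}, index=["s1"])
        with pytest.raises(ValidationError, match="s2"):
            ExpressionMatrix(df, sample_meta=meta)

    def test_biotype_subsetting(self):
        df = pd.DataFrame([[1], [2], [3]], index=["a", "b", "c"],
                          columns=["s"])
        fm = pd.DataFrame({"biotype": ["mRNA", "lncRNA", "mRNA"]},
                          index=df.index)
        m = ExpressionMatrix(df, fm)
        assert list(m.biotype("mRNA").feature_ids) == ["a", "c"]


class TestCountsIO:
    def test_round_trip(self, tmp_path, matrix_factory):
        m = matrix_factory([[1, 2], [3, 4]])
        path = tmp_path / "counts.tsv"
        write_counts(m, str(path))
        back = read_counts(str(path))
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)

    def test_shape(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("feature_id\ts1\ts2\nf1\t1\t2\nf2\t3\t4\n")
        assert read_counts(str(path)).values.shape == (2, 2)

    def test_duplicate_feature_id_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("feature_id\ts1\nf1\t1\nf1\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_counts(str(path))

    def test_negative_cell_rejected_with_coordinates(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("feature_id\ts1\ts2\nf1\t1\t-2\n")
        with pytest.raises(ValidationError, match="f1.*s2"):
            read_counts(str(path))

    def test_missing_sample_in_metadata_named(self, tmp_path):
        counts = tmp_path / "c.tsv"
        counts.write_text("feature_id\ts1\ts2\nf1\t1\t2\n")
        meta = tmp_path / "m.tsv"
        meta.write_text("sample\tcondition\ns1\ttumor\n")
        with pytest.raises(ValidationError, match="s2"):
            read_counts(str(counts), str(meta))

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("feature_id\ts1\nf1\tNAN?\n")
        with pytest.raises(ValidationError):
            read_counts(str(path))


class TestGTF:
    def test_single_exon_gene(self, tmp_path):
        path = tmp_path / "g.gtf"
        path.write_text(
            'chr1\tx\texon\t10\t50\t.\t+\t.\tgene_id "G1"; gene_type "lncRNA";\n'
        )
        genes = read_gtf(str(path))
        assert len(genes) == 1
        assert genes[0].exons == [(10, 50)]
        assert genes[0].biotype == "lncRNA"

    def test_three_exon_fixture(self, tmp_path):
        g = GeneModel("G3", "chr2", "-", [(10, 20), (40, 60), (90, 95)])
        path = tmp_path / "g.gtf"
        write_gtf([g], str(path))
        back = read_gtf(str(path))
        assert len(back[0].exons) == 3
        assert back[0].exons == g.exons

    def test_missing_gene_id_names_line(self, tmp_path):
        path = tmp_path / "g.gtf"
        path.write_text(
            'chr1\tx\texon\t10\t50\t.\t+\t.\tgene_id "G1";\n'
            "chr1\tx\texon\t60\t70\t.\t+\t.\tfoo bar;\n"
        )
        with pytest.raises(ParseError, match=":2"):
            read_gtf(str(path))

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            GeneModel("G", "chr1", "+", [(10, 50), (40, 60)])

    def test_introns_between_exons(self):
        g = GeneModel("G", "chr1", "+", [(10, 20), (40, 60)])
        assert g.introns == [(21, 39)]


class TestJunctions:
    def test_round_trip_converts_coordinates_once(self, tmp_path):
        j = CircJunction("c1", "chr1", 101, 200, "+", 7)
        path = tmp_path / "j.tsv"
        write_junctions([j], str(path))
        line = path.read_text().strip().split("\t")
        assert line[1] == "100" and line[2] == "200"  # 0-based half-open
        back = read_junctions(str(path))[0]
        assert (back.start, back.end, back.strand, back.read_support) == (
            101, 200, "+", 7
        )

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "j.tsv"
        path.write_text("chr1\t0\t100\n")
        with pytest.raises(ParseError, match=":1"):
            read_junctions(str(path))


class TestFasta:
    def test_round_trip_uppercases(self, tmp_path):
        path = tmp_path / "s.fa"
        write_fasta({"a": "ACGU", "b": "GGCC"}, str(path))
        assert read_fasta(str(path)) == {"a": "ACGU", "b": "GGCC"}


class TestTargetTables:
    def test_validated_dialect(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("miRNA\tTarget Gene\nmir1\tGENE1\nmir1\tGENE1\n")
        df = read_target_table(str(path))
        assert len(df) == 1
        assert df.iloc[0]["evidence"] == "validated"

    def test_predicted_dialect(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("miR Family\tGene Symbol\nmir1\tGENE1\n")
        df = read_target_table(str(path))
        assert df.iloc[0]["evidence"] == "predicted"

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ParseError, match="dialect"):
            read_target_table(str(path))

    def test_merge_keeps_provenance(self, tmp_path):
        p1 = tmp_path / "v.tsv"
        p1.write_text("miRNA\tTarget Gene\nmir1\tGENE1\n")
        p2 = tmp_path / "p.tsv"
        p2.write_text("miR Family\tGene Symbol\nmir1\tGENE1\n")
        merged = merge_target_tables(
            [read_target_table(str(p1)), read_target_table(str(p2))]
        )
        assert len(merged) == 2
        assert set(merged["evidence"]) == {"validated", "predicted"}


class TestSignaturesAndGMT:
    def test_signature_round_trip(self, tmp_path):
        templates = [
            TemplateSignature("S1", [("g1", 1), ("g2", -1)]),
            TemplateSignature("S2", [("g3", 1), ("g4", 1)]),
        ]
        path = tmp_path / "sig.tsv"
        write_signatures(templates, str(path))
        back = read_signatures(str(path))
        assert [(t.class_label, t.genes) for t in back] == [
            (t.class_label, t.genes) for t in templates
        ]

    def test_gmt_parse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = read_gmt(str(path))
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g4"]}

    def test_survival_table_validation(self, tmp_path):
        path = tmp_path / "surv.tsv"
        path.write_text("sample\ttime\tevent\ns1\t0\t1\n")
        with pytest.raises(ValidationError, match="non-positive"):
            read_survival(str(path))


class TestNetworkSerialisation:
    def _edge(self):
        return CeRNAEdge(
            cerna_id="lncA", cerna_class="lncRNA", mrna_id="geneB",
            shared_mirnas=[f"m{i}" for i in range(5)],
            k=5, K=6, n=7, N=100, p_hyper=1e-8, pcc=0.8,
        )

    def test_empty_edge_set_header_only(self, tmp_path):
        path = tmp_path / "net.tsv"
        write_network([], str(path))
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("cerna_id")

    def test_shared_mirnas_semicolon_joined(self, tmp_path):
        path = tmp_path / "net.tsv"
        write_network([self._edge()], str(path))
        df = read_network_tsv(str(path))
        assert len(df) == 1
        assert df.iloc[0]["shared_mirnas"] == [f"m{i}" for i in range(5)]

    def test_graphml_node_count_is_distinct_molecules(self, tmp_path):
        path = tmp_path / "net.graphml"
        edge2 = self._edge()
        edge2.mrna_id = "geneC"
        write_network([self._edge(), edge2], str(path), format="graphml")
        g = nx.read_graphml(str(path))
        assert g.number_of_nodes() == 3
        assert g.nodes["lncA"]["node_class"] == "lncRNA"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_network([], str(tmp_path / "x"), format="xlsx")

    def test_edge_invariants_enforced(self):
        with pytest.raises(ValidationError):
            CeRNAEdge("a", "lncRNA", "b", ["m1"], k=2, K=3, n=3, N=10,
                      p_hyper=0.1, pcc=0.5)
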