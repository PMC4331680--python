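"""Overlay loading, inter/intra miRNA classification and TMMN assembly."""

import pytest

from regmotifs import (build_network, build_tmmn, classify_mirna_regulation,
                       find_all_motifs, load_overlays, merge_cms, trace_paths)
from regmotifs.motifs import BIFAN, FBL, FFL
from regmotifs.tmmn import (LAYER_GENE, LAYER_MIRNA, LAYER_TF, OverlayTables,
                            normalize_mirna, write_sif)
from tests.test_cms import bifan, fbl, ffl


def make_overlays(mirna_targets=(), tf_mirna=(), roles=()):
    t = OverlayTables()
    for m, g in mirna_targets:
        t.add_mirna_target(m, g)
    for tf, m in tf_mirna:
        t.add_tf_mirna(tf, m)
    for g, r in roles:
        t.add_gene_role(g, r)
    return t


class TestOverlayTables:
    def test_load_deduplicates_and_normalises(self, tmp_path):
        (tmp_path / "mt.tsv").write_text(
            "hsa-miR-1\tgene1\nmiR-1\tGENE1\nmiR-2\tGENE2\n", encoding="utf-8")
        (tmp_path / "tm.tsv").write_text("TP53\thsa-miR-1\n", encoding="utf-8")
        (tmp_path / "gr.tsv").write_text(
            "GENE1\tOCG\ngene1\tTSG\n", encoding="utf-8")
        tables = load_overlays(tmp_path / "mt.tsv", tmp_path / "tm.tsv",
                               tmp_path / "gr.tsv")
        assert tables.mirna_targets == {("mir-1", "GENE1"), ("mir-2", "GENE2")}
        assert tables.tf_mirna == {("TP53", "mir-1")}
        # OCG outranks TSG, with a warning
        assert tables.gene_roles["GENE1"] == "OCG"
        assert any("conflicting roles" in w for w in tables.warnings)

    def test_empty_files_give_empty_tables(self, tmp_path):
        for name in ("a", "b", "c"):
            (tmp_path / name).write_text("", encoding="utf-8")
        tables = load_overlays(tmp_path / "a", tmp_path / "b", tmp_path / "c")
        assert not tables.mirna_targets and not tables.tf_mirna

    def test_malformed_line_reports_position(self, tmp_path):
        (tmp_path / "mt.tsv").write_text("ok\tG1\nbroken-line\n",
                                         encoding="utf-8")
        (tmp_path / "e").write_text("", encoding="utf-8")
        with pytest.raises(ValueError, match="mt.tsv:2"):
            load_overlays(tmp_path / "mt.tsv", tmp_path / "e", tmp_path / "e")

    def test_mirna_prefix_stripped_for_matching_only(self):
        assert normalize_mirna("hsa-miR-15a") == normalize_mirna("MIR-15A")
        tables = make_overlays([("hsa-miR-15a", "G1")])
        assert tables.mirna_display["mir-15a"] == "hsa-miR-15a"


class TestClassification:
    def test_inter_motif_two_bifans(self):
        insts = [bifan("A", "B", "C", "D"), bifan("E", "F", "G", "H")]
        tables = make_overlays([("miR-1", "C"), ("miR-1", "G")])
        summary = classify_mirna_regulation(insts, tables)
        assert summary.inter[BIFAN] == 1 and summary.intra[BIFAN] == 0
        assert summary.as_strings()[BIFAN] == "1/0"

    def test_intra_motif_both_regulators(self):
        insts = [bifan("A", "B", "C", "D")]
        tables = make_overlays([("miR-1", "A"), ("miR-1", "B")])
        summary = classify_mirna_regulation(insts, tables)
        assert summary.inter[BIFAN] == 0 and summary.intra[BIFAN] == 1

    def test_single_gene_hit_counts_neither(self):
        insts = [ffl("A", "B", "C")]
        tables = make_overlays([("miR-1", "A")])
        summary = classify_mirna_regulation(insts, tables)
        assert summary.inter[FFL] == 0 and summary.intra[FFL] == 0
        assert summary.total_mirnas == 1

    def test_fbl_intra_and_mirna_can_be_both(self):
        insts = [fbl("A", "B"), fbl("C", "D")]
        tables = make_overlays([("miR-1", "A"), ("miR-1", "B"),
                                ("miR-1", "C")])
        summary = classify_mirna_regulation(insts, tables)
        assert summary.inter[FBL] == 1 and summary.intra[FBL] == 1

    def test_one_to_many_many_to_one_many_to_many(self):
        insts = [ffl("A", "B", "C"), ffl("D", "E", "F")]
        one_to_many = make_overlays([("miR-1", "A"), ("miR-1", "D")])
        many_to_one = make_overlays([("miR-1", "A"), ("miR-2", "B")])
        many_to_many = make_overlays([("miR-1", "A"), ("miR-1", "D"),
                                      ("miR-2", "B"), ("miR-2", "E")])
        assert classify_mirna_regulation(insts, one_to_many).inter[FFL] == 1
        assert classify_mirna_regulation(insts, many_to_one).inter[FFL] == 0
        assert classify_mirna_regulation(insts, many_to_many).inter[FFL] == 2


class TestBuildTmmn:
    @pytest.fixture
    def ffl_with_overlay(self, ffl_net):
        tables = make_overlays(
            mirna_targets=[("miR-X", "AKT3"), ("miR-OUT", "NOTINNET")],
            tf_mirna=[("TFY", "miR-X"), ("TFZ", "miR-OUT")],
            roles=[("AKT3", "OCG")])
        inv = find_all_motifs(ffl_net)
        return build_tmmn(ffl_net, inv.instances, tables)

    def test_three_layers_assembled(self, ffl_with_overlay):
        g = ffl_with_overlay
        layers = {n: d["layer"] for n, d in g.nodes(data=True)}
        assert layers == {"PI3K": LAYER_GENE, "PDPK1": LAYER_GENE,
                          "AKT3": LAYER_GENE, "miR-X": LAYER_MIRNA,
                          "TFY": LAYER_TF}
        assert g.nodes["AKT3"]["role"] == "OCG"
        assert g.has_edge("TFY", "miR-X") and g.has_edge("miR-X", "AKT3")

    def test_layer_discipline_no_upward_edges(self, ffl_with_overlay):
        rank = {LAYER_TF: 0, LAYER_MIRNA: 1, LAYER_GENE: 2}
        for u, v in ffl_with_overlay.edges:
            ru = rank[ffl_with_overlay.nodes[u]["layer"]]
            rv = rank[ffl_with_overlay.nodes[v]["layer"]]
            assert ru <= rv

    def test_empty_overlays_give_motif_gene_graph(self, ffl_net):
        inv = find_all_motifs(ffl_net)
        g = build_tmmn(ffl_net, inv.instances, make_overlays())
        assert set(g.nodes) == {"PI3K", "PDPK1", "AKT3"}
        assert g.number_of_edges() == 3

    def test_monotone_in_overlays(self, ffl_net):
        inv = find_all_motifs(ffl_net)
        small = make_overlays([("miR-1", "AKT3")])
        big = make_overlays([("miR-1", "AKT3"), ("miR-2", "PI3K")])
        g_small = build_tmmn(ffl_net, inv.instances, small)
        g_big = build_tmmn(ffl_net, inv.instances, big)
        assert set(g_small.nodes) <= set(g_big.nodes)
        assert set(g_small.edges) <= set(g_big.edges)

    def test_accepts_cms_structures(self, ffl_net):
        structures = merge_cms(find_all_motifs(ffl_net).instances)
        g = build_tmmn(ffl_net, structures, make_overlays())
        assert set(g.nodes) == {"PI3K", "PDPK1", "AKT3"}

    def test_sif_export(self, tmp_path, ffl_with_overlay):
        write_sif(ffl_with_overlay, tmp_path / "g.sif", tmp_path / "g.tsv")
        sif = (tmp_path / "g.sif").read_text(encoding="utf-8")
        assert "TFY\ttf-mirna\tmiR-X" in sif
        attrs = (tmp_path / "g.tsv").read_text(encoding="utf-8")
        assert "AKT3\tgene\tgene\tOCG" in attrs


class TestTracePaths:
    @pytest.fixture
    def pathway_graph(self):
        net = build_network("nsclc-frag", [
            ("TGFA", "EGFR", 1), ("EGFR", "PIK3CA", 1), ("PIK3CA", "AKT", 1),
            ("EGFR", "AKT", 1), ("TGFA", "PIK3CA", 1),
        ])
        from regmotifs import MotifSearchConfig
        inv = find_all_motifs(net, MotifSearchConfig(sim_min_targets=2))
        return build_tmmn(net, inv.instances, make_overlays())

    def test_receptor_to_kinase_paths(self, pathway_graph):
        paths = trace_paths(pathway_graph, "TGFA", "AKT")
        assert ["TGFA", "EGFR", "PIK3CA", "AKT"] in paths
        assert ["TGFA", "EGFR", "AKT"] in paths

    def test_source_equals_sink(self, pathway_graph):
        assert trace_paths(pathway_graph, "EGFR", "EGFR") == [["EGFR"]]

    def test_disconnected_and_unknown(self, pathway_graph):
        assert trace_paths(pathway_graph, "AKT", "TGFA") == []
        with pytest.raises(KeyError):
            trace_paths(pathway_graph, "TGFA", "NOPE")
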