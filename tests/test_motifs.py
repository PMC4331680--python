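"""Motif finders: worked pathway examples, definitional edge cases,
oracle equivalence and monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmotifs import (BIFAN, FFL, MotifSearchConfig, build_network,
                       classify_ffl, find_all_motifs, find_arl, find_bifan,
                       find_fbl, find_ffl, find_sim)
from regmotifs.motifs import AMBIGUOUS, COHERENT, INCOHERENT, MotifInstance
from regmotifs.synthetic import brute_force_enumerate, random_signed_digraph


class TestArl:
    def test_self_edge_found(self):
        net = build_network("x", [("A", "A", 1), ("A", "B", 1)])
        assert [i.nodes for i in find_arl(net)] == [("A",)]

    def test_no_self_edges_empty(self):
        net = build_network("x", [("A", "B", 1)])
        assert find_arl(net) == []

    def test_planted_self_edges_in_random_graph(self):
        net = random_signed_digraph(20, 0.1, seed=3)
        planted = ["G002", "G005", "G008", "G011", "G014"]
        for n in planted:
            net.add_edge(n, n, 1)
        assert [i.nodes[0] for i in find_arl(net)] == planted


class TestFbl:
    def test_mutual_pair_found(self):
        net = build_network("x", [("A", "B", 1), ("B", "A", -1)])
        assert [i.nodes for i in find_fbl(net)] == [("A", "B")]

    def test_one_way_edge_is_not_fbl(self):
        assert find_fbl(build_network("x", [("A", "B", 1)])) == []


class TestFfl:
    def test_named_pathway_triad_is_coherent(self, ffl_net):
        (inst,) = find_ffl(ffl_net)
        assert inst.nodes == ("PI3K", "PDPK1", "AKT3")
        assert inst.coherence == COHERENT

    def test_directed_three_cycle_has_no_ffl(self):
        net = build_network("cycle", [("A", "B", 1), ("B", "C", 1),
                                      ("C", "A", 1)])
        assert find_ffl(net) == []
        assert brute_force_enumerate(net, FFL) == []

    def test_role_reassignments_are_distinct_instances(self):
        # x->y, y->z, x->z plus z->y gives a second triad (x, z, y)
        net = build_network("x", [("X", "Y", 1), ("Y", "Z", 1),
                                  ("X", "Z", 1), ("Z", "Y", 1)])
        assert {i.nodes for i in find_ffl(net)} == {("X", "Y", "Z"),
                                                    ("X", "Z", "Y")}

    def test_bidirectional_style_requires_full_triangle(self):
        cfg = MotifSearchConfig(ffl_style="bidirectional")
        tri = [(u, v, 1) for u in "ABC" for v in "ABC" if u != v]
        full = build_network("full", tri)
        assert len(find_ffl(full, cfg)) == 1
        canonical = build_network("canon", [("A", "B", 1), ("B", "C", 1),
                                            ("A", "C", 1)])
        assert find_ffl(canonical, cfg) == []


class TestClassifyFfl:
    @pytest.mark.parametrize("signs,expected", [
        ((1, 1, 1), COHERENT),
        ((1, -1, 1), INCOHERENT),   # direct +1 vs path product -1
        ((-1, -1, 1), COHERENT),    # two repressions compose to activation
        ((1, 1, 0), AMBIGUOUS),
        ((0, 1, 1), AMBIGUOUS),
    ])
    def test_sign_product_rule(self, signs, expected):
        s_xy, s_yz, s_xz = signs
        inst = MotifInstance(FFL, ("X", "Y", "Z"), (
            (("X", "Y"), s_xy), (("Y", "Z"), s_yz), (("X", "Z"), s_xz)))
        assert classify_ffl(inst) == expected

    def test_non_ffl_rejected(self):
        inst = MotifInstance("FBL", ("A", "B"),
                             ((("A", "B"), 1), (("B", "A"), 1)))
        with pytest.raises(ValueError):
            classify_ffl(inst)

    def test_conflicting_parallel_signs_are_ambiguous(self, ffl_net):
        ffl_net.add_edge("PI3K", "AKT3", -1)  # now both +1 and -1
        (inst,) = find_ffl(ffl_net)
        assert inst.coherence == AMBIGUOUS


class TestBifan:
    def test_named_pathway_bifan(self, bifan_net):
        (inst,) = find_bifan(bifan_net)
        assert inst.nodes == ("EGF", "TGFA", "EGFR", "ERBB2")

    def test_connected_regulators_exclude_bifan(self, bifan_net):
        bifan_net.add_edge("EGF", "TGFA", 1)
        assert find_bifan(bifan_net) == []

    @pytest.mark.parametrize("r,t", [(2, 2), (3, 3), (4, 2), (6, 6)])
    def test_complete_bipartite_count_law(self, r, t):
        from math import comb
        edges = [(f"R{i}", f"T{j}", 1) for i in range(r) for j in range(t)]
        net = build_network("kb", edges)
        assert len(find_bifan(net)) == comb(r, 2) * comb(t, 2)

    def test_target_edge_exclusion_flag(self, bifan_net):
        bifan_net.add_edge("EGFR", "ERBB2", 1)
        assert len(find_bifan(bifan_net)) == 1
        cfg = MotifSearchConfig(bifan_exclude_target_edges=True)
        assert find_bifan(bifan_net, cfg) == []


class TestSim:
    def test_star_at_threshold(self):
        net = build_network("x", [("A", t, 1) for t in "BCD"])
        assert [i.nodes for i in find_sim(net, 3)] == [("A", "B", "C", "D")]

    def test_below_threshold_empty(self):
        net = build_network("x", [("A", "B", 1), ("A", "C", 1)])
        assert find_sim(net, 3) == []

    def test_masters_match_out_degree_count(self):
        net = random_signed_digraph(20, 0.15, seed=11)
        masters = {i.nodes[0] for i in find_sim(net, 3)}
        expected = {n for n in net.node_ids
                    if len(net.successors(n) - {n}) >= 3}
        assert masters == expected

    def test_self_edge_not_a_target_and_bad_threshold(self):
        net = build_network("x", [("A", "A", 1), ("A", "B", 1), ("A", "C", 1)])
        assert find_sim(net, 3) == []
        with pytest.raises(ValueError):
            find_sim(net, 1)


class TestFindAll:
    def test_empty_network_all_zero(self):
        inv = find_all_motifs(build_network("e", []))
        assert inv.summary_row() == (0, 0, 0, 0, 0)

    def test_bifan_fixture_with_threshold_two(self, bifan_net):
        inv = find_all_motifs(bifan_net, MotifSearchConfig(sim_min_targets=2))
        assert inv.summary_row() == (0, 0, 0, 1, 2)

    def test_determinism(self):
        net = random_signed_digraph(12, 0.2, seed=5)
        a = find_all_motifs(net).instances
        b = find_all_motifs(net).instances
        assert a == b

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), p=st.sampled_from([0.05, 0.2, 0.4]))
    def test_oracle_equivalence_small_graphs(self, seed, p):
        net = random_signed_digraph(9, p, seed=seed, self_loops=True)
        cfg = MotifSearchConfig(sim_min_targets=2)
        inv = find_all_motifs(net, cfg)
        for mtype in ("ARL", "FBL", "FFL", "BIFAN", "SIM"):
            assert inv.of_type(mtype) == brute_force_enumerate(net, mtype, cfg)

    def test_adding_edge_monotone_for_all_but_bifan(self):
        net = random_signed_digraph(10, 0.15, seed=9, self_loops=True)
        before = find_all_motifs(net)
        net.add_edge("G000", "G007", 1)
        after = find_all_motifs(net)
        for mtype in ("ARL", "FBL", "FFL"):
            assert set(before.of_type(mtype)) <= set(after.of_type(mtype))
        # SIM masters never disappear (their maximal target set may grow)
        sim_before = {i.nodes[0] for i in before.of_type("SIM")}
        sim_after = {i.nodes[0] for i in after.of_type("SIM")}
        assert sim_before <= sim_after
        # bi-fan instances may only disappear by connecting a regulator pair
        lost = set(before.of_type(BIFAN)) - set(after.of_type(BIFAN))
        for inst in lost:
            assert {"G000", "G007"} <= {inst.nodes[0], inst.nodes[1]}
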