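"""Database merging, distinct-study evidence filtering and complex collapse."""

import networkx as nx
import pytest

from bcrnet.interactome import (
    InteractionRecord,
    collapse_complex,
    filter_min_evidence,
    map_orthologs,
    merge_databases,
    read_edge_list,
    read_interactions,
    write_edge_list,
)
from bcrnet.synthetic import gen_interactome, records_from_frame


def rec(a, b, pubs, db="db1"):
    return InteractionRecord(a, b, frozenset(pubs), db)


class TestReadInteractions:
    def test_parses_well_formed_rows(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text(
            "LYN\tSYK\tp1|p2\tdbA\n"
            "LYN\tBCR\tp3\tdbB\n"
            "SYK\tBLNK\tp4\tdbA\n"
        )
        records = read_interactions(path)
        assert len(records) == 3
        assert records[0].publications == {"p1", "p2"}

    def test_skips_row_with_empty_publications(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\tp1\tdb\nC\tD\t\tdb\n")
        assert len(read_interactions(path)) == 1

    def test_self_interaction_retained_at_parse_stage(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tA\tp1\tdb\n")
        records = read_interactions(path)
        assert len(records) == 1  # dropped later, at network build

    def test_all_malformed_raises(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\nC\n")
        with pytest.raises(ValueError, match="malformed"):
            read_interactions(path)


class TestMapOrthologs:
    MAP = {"MouseLyn": "LYN", "MouseSyk": "SYK"}

    def test_remaps_both_sides(self):
        out = map_orthologs([rec("MouseLyn", "MouseSyk", {"p1"})], self.MAP)
        assert (out[0].id_a, out[0].id_b) == ("LYN", "SYK")

    def test_drops_records_with_unmapped_side(self):
        out = map_orthologs([rec("MouseLyn", "Unknown", {"p1"})], self.MAP)
        assert out == []

    def test_identity_mapping_is_noop(self):
        records = [rec("A", "B", {"p1"})]
        out = map_orthologs(records, {"A": "A", "B": "B"})
        assert out == records

    def test_empty_mapping_raises(self):
        with pytest.raises(ValueError):
            map_orthologs([rec("A", "B", {"p1"})], {})


class TestMergeDatabases:
    def test_shared_publication_deduplicated_across_databases(self):
        net = merge_databases(
            [[rec("A", "B", {"p1"}, "db1")], [rec("B", "A", {"p1"}, "db2")]]
        )
        assert net.number_of_edges() == 1
        assert net.edges["A", "B"]["evidence"] == 1
        assert net.edges["A", "B"]["sources"] == {"db1", "db2"}

    def test_distinct_publications_accumulate(self):
        net = merge_databases([[rec("A", "B", {"p1"}), rec("A", "B", {"p2"})]])
        assert net.edges["A", "B"]["evidence"] == 2

    def test_self_loops_removed(self):
        net = merge_databases([[rec("A", "A", {"p1"})]])
        assert net.number_of_edges() == 0

    def test_merge_order_invariance(self):
        tables = [
            [rec("A", "B", {"p1"}, "db1"), rec("B", "C", {"p2"}, "db1")],
            [rec("C", "B", {"p2", "p3"}, "db2")],
            [rec("A", "C", {"p4"}, "db3")],
        ]
        forward = merge_databases(tables)
        backward = merge_databases(tables[::-1])
        assert nx.utils.graphs_equal(forward, backward)


class TestFilterMinEvidence:
    def test_threshold_boundary(self):
        net = merge_databases([[rec("A", "B", {"p1"}), rec("C", "D", {"p2", "p3"})]])
        filtered = filter_min_evidence(net, 2)
        assert not filtered.has_edge("A", "B")
        assert filtered.has_edge("C", "D")

    def test_min_one_study_keeps_everything(self):
        net = merge_databases([[rec("A", "B", {"p1"}), rec("B", "C", {"p2"})]])
        assert nx.utils.graphs_equal(filter_min_evidence(net, 1), net)

    def test_survivor_count_matches_brute_force(self):
        evidences = (1, 1, 2, 3, 2)
        pubs = [{f"p{i}_{j}" for j in range(e)} for i, e in enumerate(evidences)]
        pairs = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A")]
        net = merge_databases([[rec(a, b, p) for (a, b), p in zip(pairs, pubs)]])
        expected = sum(1 for e in evidences if e >= 2)  # brute-force count
        assert filter_min_evidence(net, 2).number_of_edges() == expected == 3

    def test_idempotence(self):
        net = merge_databases(
            [[rec("A", "B", {"p1"}), rec("B", "C", {"p1", "p2", "p3"})]]
        )
        once = filter_min_evidence(net, 2)
        twice = filter_min_evidence(once, 2)
        assert nx.utils.graphs_equal(once, twice)

    def test_isolated_nodes_pruned(self):
        net = merge_databases([[rec("A", "B", {"p1"}), rec("C", "D", {"p2", "p3"})]])
        assert set(filter_min_evidence(net, 2).nodes) == {"C", "D"}


class TestCollapseComplex:
    def test_member_edges_merge_onto_complex_node(self):
        net = merge_databases(
            [[rec("CD79A", "X", {"p1", "p2"}), rec("CD79B", "X", {"p3"})]]
        )
        out = collapse_complex(net, {"CD79A", "CD79B"}, "BCR")
        assert out.has_edge("BCR", "X")
        assert out.number_of_edges() == 1
        # conservative evidence: max of merged, not sum
        assert out.edges["BCR", "X"]["evidence"] == 2

    def test_internal_edge_removed(self):
        net = merge_databases([[rec("CD79A", "CD79B", {"p1"}), rec("CD79A", "X", {"p2"})]])
        out = collapse_complex(net, {"CD79A", "CD79B"}, "BCR")
        assert [set(e) for e in out.edges] == [{"BCR", "X"}]

    def test_single_member_collapse_is_rename(self):
        net = merge_databases([[rec("CD79A", "X", {"p1"})]])
        out = collapse_complex(net, {"CD79A"}, "BCR")
        assert set(out.nodes) == {"BCR", "X"}
        assert out.edges["BCR", "X"]["evidence"] == 1

    def test_missing_member_raises(self):
        net = merge_databases([[rec("A", "B", {"p1"})]])
        with pytest.raises(ValueError, match="not in network"):
            collapse_complex(net, {"A", "Z"}, "BCR")


class TestSyntheticInteractome:
    def test_planted_path_survives_two_study_filter(self):
        frame, truth = gen_interactome(
            10, 15, frac_multi_study=0.5, planted_paths=[["A", "B", "C"]], seed=1
        )
        net = merge_databases([records_from_frame(frame)])
        assert net.number_of_edges() == 15
        filtered = filter_min_evidence(net, 2)
        for u, v in zip(["A", "B"], ["B", "C"]):
            assert filtered.has_edge(u, v)

    def test_empty_generation_is_valid(self):
        frame, _ = gen_interactome(5, 0, planted_paths=[], seed=1)
        assert len(frame) == 0

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        a, _ = gen_interactome(50, 200, seed=42)
        b, _ = gen_interactome(50, 200, seed=42)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(pa, sep="\t", index=False)
        b.to_csv(pb, sep="\t", index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_multi_study_fraction_is_exact_on_non_planted_edges(self):
        frame, _ = gen_interactome(
            30, 100, frac_multi_study=0.25, planted_paths=[["A", "B"]], seed=9
        )
        net = merge_databases([records_from_frame(frame)])
        non_planted = [
            d["evidence"] for u, v, d in net.edges(data=True)
            if {u, v} != {"A", "B"}
        ]
        assert sum(1 for e in non_planted if e >= 2) == round(0.25 * 99)

    def test_records_span_multiple_databases(self):
        frame, _ = gen_interactome(20, 30, seed=3)
        assert frame.source_db.nunique() >= 2

    def test_record_publication_counts_in_range(self):
        frame, _ = gen_interactome(20, 30, seed=3)
        counts = frame.publications.map(lambda s: len(s.split("|")))
        assert counts.between(1, 5).all()

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            gen_interactome(4, 10, seed=0)


def test_edge_list_round_trip(tmp_path):
    frame, _ = gen_interactome(15, 25, seed=6)
    net = merge_databases([records_from_frame(frame)])
    path = tmp_path / "edges.tsv"
    write_edge_list(net, path)
    recovered = read_edge_list(path)
    assert {frozenset(e) for e in recovered.edges} == {frozenset(e) for e in net.edges}
    for u, v in recovered.edges:
        assert recovered.edges[u, v]["evidence"] == net.edges[u, v]["evidence"]
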