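"""Network loading, filtering, symmetrization, cleaning and union."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trigat import (
    GeneNetwork,
    IntegratedNetwork,
    clean_network,
    filter_by_confidence,
    load_edge_list,
    symmetrize_undirected,
    union_networks,
)


def write(tmp_path, text, name="net.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadEdgeList:
    def test_plain_three_row_list(self, tmp_path):
        net = load_edge_list(write(tmp_path, "A\tB\nB\tC\nC\tA\n"), directed=True)
        assert net.edges == [("A", "B"), ("B", "C"), ("C", "A")]
        assert net.directed and net.scores is None

    def test_score_column(self, tmp_path):
        net = load_edge_list(write(tmp_path, "A\tB\t0.9\n"),
                             dialect={"score": 2}, directed=True)
        assert net.scores == [0.9]

    def test_empty_file_warns_and_yields_no_edges(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            net = load_edge_list(write(tmp_path, ""), directed=False)
        assert net.edges == []

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_edge_list(tmp_path / "absent.tsv")

    def test_single_column_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="2 columns"):
            load_edge_list(write(tmp_path, "A\nB\n"))

    def test_ids_case_normalized(self, tmp_path):
        net = load_edge_list(write(tmp_path, "tp53\t Myc \n"), directed=True)
        assert net.edges == [("TP53", "MYC")]


class TestFilterByConfidence:
    def test_numeric_strictly_greater(self):
        net = GeneNetwork("cpdb", [("A", "B"), ("B", "C"), ("C", "D")], True,
                          scores=[0.4, 0.6, 0.85])
        out = filter_by_confidence(net, 0.5, "numeric")
        assert out.edges == [("B", "C"), ("C", "D")]
        assert out.scores == [0.6, 0.85]

    def test_threshold_value_itself_is_dropped(self):
        net = GeneNetwork("n", [("A", "B")], True, scores=[0.5])
        assert filter_by_confidence(net, 0.5, "numeric").edges == []

    def test_categorical_retained_set(self):
        net = GeneNetwork("regnet", [("A", "B"), ("B", "C"), ("C", "D")], True,
                          scores=["high", "middle", "low"])
        out = filter_by_confidence(net, {"high", "middle"}, "categorical")
        assert out.edges == [("A", "B"), ("B", "C")]

    def test_empty_network_passthrough(self):
        out = filter_by_confidence(GeneNetwork("n", [], True, scores=[]), 0.5, "numeric")
        assert out.edges == []

    def test_scoreless_network_rejected(self):
        with pytest.raises(ValueError, match="without scores"):
            filter_by_confidence(GeneNetwork("n", [("A", "B")], True), 0.5, "numeric")


class TestSymmetrize:
    def test_single_pair_doubles(self):
        out = symmetrize_undirected(GeneNetwork("ppi", [("A", "B")], False))
        assert out.edges == [("A", "B"), ("B", "A")] and out.directed

    def test_redundant_record_then_clean(self):
        out = symmetrize_undirected(
            GeneNetwork("ppi", [("A", "B"), ("B", "A")], False))
        assert len(out.edges) == 4
        assert sorted(clean_network(out).edges) == [("A", "B"), ("B", "A")]

    def test_empty(self):
        out = symmetrize_undirected(GeneNetwork("ppi", [], False))
        assert out.edges == [] and out.directed

    def test_directed_input_noop_with_warning(self):
        net = GeneNetwork("grn", [("A", "B")], True)
        with pytest.warns(UserWarning):
            assert symmetrize_undirected(net) is net


class TestCleanNetwork:
    def test_removes_duplicates_and_self_loops(self):
        net = GeneNetwork("n", [("A", "B"), ("A", "B"), ("A", "A")], True)
        assert clean_network(net).edges == [("A", "B")]

    def test_reverse_pairs_are_distinct(self):
        net = GeneNetwork("n", [("A", "B"), ("B", "A")], True)
        assert clean_network(net).edges == [("A", "B"), ("B", "A")]

    def test_idempotent(self):
        net = clean_network(GeneNetwork("n", [("A", "B"), ("B", "C"), ("A", "B")], True))
        assert clean_network(net).edges == net.edges

    def test_first_score_kept_for_duplicates(self):
        net = GeneNetwork("n", [("A", "B"), ("A", "B")], True, scores=[0.9, 0.1])
        assert clean_network(net).scores == [0.9]


class TestUnion:
    def test_membership_rule(self):
        db1 = GeneNetwork("db1", [("A", "B")], True)
        db2 = GeneNetwork("db2", [("A", "B"), ("B", "C")], True)
        net = union_networks([db1, db2])
        assert net.edges == [("A", "B"), ("B", "C")]
        assert net.edge_features.tolist() == [[1, 1], [0, 1]]
        assert net.database_names == ["db1", "db2"]

    def test_single_net_all_ones(self):
        net = union_networks([GeneNetwork("db", [("A", "B"), ("B", "C")], True)])
        assert (net.edge_features == 1).all()

    def test_disjoint_union_counts(self):
        db1 = GeneNetwork("a", [("A", "B")], True)
        db2 = GeneNetwork("b", [("C", "D"), ("D", "E")], True)
        net = union_networks([db1, db2])
        assert net.n_edges == 3
        assert net.edge_features.sum(axis=0).tolist() == [1, 2]

    def test_uncleaned_rejected(self):
        with pytest.raises(ValueError, match="clean"):
            union_networks([GeneNetwork("bad", [("A", "A")], True)])
        with pytest.raises(ValueError, match="undirected"):
            union_networks([GeneNetwork("ppi", [("A", "B")], False)])

    def test_no_networks_rejected(self):
        with pytest.raises(ValueError):
            union_networks([])


@st.composite
def random_networks(draw):
    genes = [f"G{i}" for i in range(draw(st.integers(3, 8)))]
    nets = []
    for k in range(draw(st.integers(1, 4))):
        pairs = draw(st.lists(
            st.tuples(st.sampled_from(genes), st.sampled_from(genes)),
            min_size=0, max_size=15))
        nets.append(clean_network(GeneNetwork(f"db{k}", pairs, True)))
    return nets


class TestUnionProperties:
    @settings(max_examples=50, deadline=None)
    @given(random_networks())
    def test_feature_column_sums_equal_cleaned_edge_counts(self, nets):
        net = union_networks(nets)
        sums = net.edge_features.sum(axis=0)
        for k, db in enumerate(nets):
            assert sums[k] == db.n_edges
        # total membership equals total per-database edges
        assert net.edge_features.sum() == sum(db.n_edges for db in nets)

    @settings(max_examples=30, deadline=None)
    @given(random_networks())
    def test_edge_set_order_insensitive(self, nets):
        forward = union_networks(nets)
        backward = union_networks(nets[::-1])
        assert forward.edges == backward.edges
        assert np.array_equal(forward.edge_features, backward.edge_features[:, ::-1])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("ABCDE"), st.sampled_from("ABCDE")),
                    min_size=0, max_size=12))
    def test_symmetrize_doubles_irredundant_input(self, pairs):
        # restrict to inputs with no self pairs and no reverse duplicates
        seen, filtered = set(), []
        for u, v in pairs:
            if u != v and (u, v) not in seen and (v, u) not in seen:
                seen.add((u, v))
                filtered.append((u, v))
        net = GeneNetwork("ppi", filtered, False)
        assert symmetrize_undirected(net).n_edges == 2 * len(filtered)


def test_integrated_network_roundtrip(tmp_path):
    db1 = GeneNetwork("db1", [("A", "B"), ("B", "C")], True)
    db2 = GeneNetwork("db2", [("B", "C")], True)
    net = union_networks([db1, db2])
    net.save(tmp_path)
    back = IntegratedNetwork.load(tmp_path)
    assert back.edges == net.edges
    assert np.array_equal(back.edge_features, net.edge_features)
    assert back.database_names == net.database_names
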