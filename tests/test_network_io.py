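import numpy as np
import pandas as pd
import pytest

from ecoweb.network_io import (
    BipartiteNetwork,
    DirectedNetwork,
    NetworkFormatError,
    binary_fraction,
    foodweb_to_bipartite,
    jaccard_index,
    read_edge_list,
    read_incidence_matrix,
    read_site_table,
    write_incidence_matrix,
    write_site_table,
)
from ecoweb.synthetic_data import SyntheticTruth, gen_site_table

from conftest import random_directed


class TestIncidenceMatrix:
    def test_round_trip_identity(self, tmp_path, staircase):
        path = tmp_path / "net.csv"
        write_incidence_matrix(staircase, path)
        back = read_incidence_matrix(path)
        assert back.plant_labels == staircase.plant_labels
        assert back.animal_labels == staircase.animal_labels
        np.testing.assert_array_equal(back.incidence, staircase.incidence)

    def test_counts_binarized(self, tmp_path):
        pd.DataFrame([[0, 2], [5, 0]], index=["p1", "p2"], columns=["a1", "a2"]).to_csv(
            tmp_path / "w.csv"
        )
        net = read_incidence_matrix(tmp_path / "w.csv")
        np.testing.assert_array_equal(net.incidence, [[0, 1], [1, 0]])

    def test_binarization_idempotent(self, tmp_path, staircase):
        path = tmp_path / "net.csv"
        write_incidence_matrix(staircase, path)
        once = read_incidence_matrix(path)
        write_incidence_matrix(once, path)
        twice = read_incidence_matrix(path)
        np.testing.assert_array_equal(once.incidence, twice.incidence)

    def test_all_zero_row_dropped_with_warning(self, tmp_path, caplog):
        pd.DataFrame(
            [[1, 1], [0, 0], [0, 1]], index=["p1", "p2", "p3"], columns=["a1", "a2"]
        ).to_csv(tmp_path / "z.csv")
        with caplog.at_level("WARNING"):
            net = read_incidence_matrix(tmp_path / "z.csv")
        assert net.n_plants == 2
        assert net.plant_labels == ("p1", "p3")
        assert any("all-zero" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize(
        "mat,err",
        [
            ([[0, 0], [0, 0]], "all-zero"),
            ([[1, -1], [1, 0]], "nonnegative"),
        ],
    )
    def test_invalid_matrices_rejected(self, tmp_path, mat, err):
        pd.DataFrame(mat, index=["p1", "p2"], columns=["a1", "a2"]).to_csv(tmp_path / "bad.csv")
        with pytest.raises(NetworkFormatError, match=err):
            read_incidence_matrix(tmp_path / "bad.csv")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NetworkFormatError, match="duplicate"):
            BipartiteNetwork(("p", "p"), ("a", "b"), [[1, 0], [0, 1]])


class TestEdgeList:
    def test_one_way_pairs(self, tmp_path):
        (tmp_path / "e.csv").write_text("A,B\nC,D\n")
        net = read_edge_list(tmp_path / "e.csv")
        assert net.n_nodes == 4
        assert net.n_edges == 2
        assert net.adjacency[0, 1] == 1 and net.adjacency[2, 3] == 1

    def test_mutual_edge_sets_both_entries(self, tmp_path):
        (tmp_path / "e.csv").write_text("source,target\nA,B\nB,A\n")
        net = read_edge_list(tmp_path / "e.csv")
        assert net.adjacency[0, 1] == 1 and net.adjacency[1, 0] == 1
        assert int(net.edge_triples()["mutual"].sum()) == 2

    def test_duplicates_collapse(self, tmp_path):
        (tmp_path / "e.csv").write_text("A,B\nA,B\nB,C\n")
        assert read_edge_list(tmp_path / "e.csv").n_edges == 2

    def test_self_pair_rejected(self, tmp_path):
        (tmp_path / "e.csv").write_text("A,A\n")
        with pytest.raises(NetworkFormatError, match="self-pair"):
            read_edge_list(tmp_path / "e.csv")


class TestFoodwebToBipartite:
    def test_chain(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 2] = 1
        bip = foodweb_to_bipartite(DirectedNetwork(("A", "B", "C"), adj))
        assert bip.plant_labels == ("A", "B")
        assert bip.animal_labels == ("B", "C")
        np.testing.assert_array_equal(bip.incidence, [[1, 0], [0, 1]])

    def test_mutual_edge_species_on_both_sides(self):
        adj = np.array([[0, 1], [1, 0]])
        bip = foodweb_to_bipartite(DirectedNetwork(("A", "B"), adj))
        assert bip.plant_labels == ("A", "B") == bip.animal_labels
        np.testing.assert_array_equal(bip.incidence, [[0, 1], [1, 0]])

    def test_link_conservation_and_degree_recount(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            net = random_directed(rng, 6)
            bip = foodweb_to_bipartite(net)
            assert bip.n_links == net.n_edges
            out_deg = net.out_degrees
            kept = [i for i, lab in enumerate(net.node_labels) if out_deg[i] > 0]
            np.testing.assert_array_equal(bip.plant_degrees, out_deg[kept])


class TestSiteTable:
    def test_round_trip(self, tmp_path):
        records, _ = gen_site_table(5, SyntheticTruth(seed=3))
        write_site_table(records, tmp_path / "sites.csv")
        back = read_site_table(tmp_path / "sites.csv")
        assert len(back) == 5
        for a, b in zip(records, back):
            assert a.network_id == b.network_id
            assert a.human_impact == pytest.approx(b.human_impact)
            assert a.T_velocity == pytest.approx(b.T_velocity)
            assert a.mainland_island == b.mainland_island

    def test_invalid_human_impact_names_row(self, tmp_path):
        records, _ = gen_site_table(3, SyntheticTruth(seed=3))
        records[1].human_impact = 137.0
        write_site_table(records, tmp_path / "bad.csv")
        with pytest.raises(NetworkFormatError, match="row 1.*human_impact"):
            read_site_table(tmp_path / "bad.csv")

    def test_missing_column_rejected(self, tmp_path):
        records, _ = gen_site_table(3, SyntheticTruth(seed=3))
        write_site_table(records, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv").drop(columns=["human_impact"])
        df.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(NetworkFormatError, match="human_impact"):
            read_site_table(tmp_path / "t.csv")

    def test_n_species_derived_from_plants_plus_animals(self, tmp_path):
        records, _ = gen_site_table(3, SyntheticTruth(seed=3))
        write_site_table(records, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv").drop(columns=["n_species"])
        df["n_plants"] = [10, 12, 8]
        df["n_animals"] = [20, 5, 7]
        df.to_csv(tmp_path / "t.csv", index=False)
        back = read_site_table(tmp_path / "t.csv")
        assert [r.n_species for r in back] == [30, 17, 15]


def test_dataset_summary_arithmetic():
    assert jaccard_index(1, 2) == 0.5
    assert binary_fraction(1, 4) == 25.0
    with pytest.raises(ValueError):
        jaccard_index(3, 2)
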