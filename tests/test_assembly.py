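import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.assembly import (
    _beta_mntd_matrix,
    _community_arrays,
    assembly_distance_matrix,
    beta_mntd,
    beta_nti,
    classify,
)
from ecoassembly.containers import CountTable, FormatError
from ecoassembly.io import patristic_distances, read_distance_matrix, write_distance_matrix


def table_of(rows: dict, taxa: list[str]) -> CountTable:
    return CountTable(pd.DataFrame.from_dict(rows, orient="index",
                                             dtype=int)[taxa])


class TestBetaMNTD:
    def test_identical_communities_zero(self, demo_tree):
        table = table_of({"s1": {"A": 3, "B": 1, "C": 2},
                          "s2": {"A": 3, "B": 1, "C": 2}}, ["A", "B", "C"])
        assert beta_mntd(table, demo_tree, ("s1", "s2")) == pytest.approx(0.0)

    def test_two_singleton_communities(self, demo_tree):
        """k={A}, m={B}: both directions see d(A,B)=2, so βMNTD = 2.0."""
        table = table_of({"s1": {"A": 5, "B": 0, "C": 0},
                          "s2": {"A": 0, "B": 7, "C": 0}}, ["A", "B", "C"])
        assert beta_mntd(table, demo_tree, ("s1", "s2")) == pytest.approx(2.0)

    def test_weighted_three_taxon_example(self, demo_tree):
        """k={A:3,B:1} vs m={C}: ½[(0.75·4 + 0.25·4) + 1.0·4] = 4.0."""
        table = table_of({"s1": {"A": 3, "B": 1, "C": 0},
                          "s2": {"A": 0, "B": 0, "C": 9}}, ["A", "B", "C"])
        assert beta_mntd(table, demo_tree, ("s1", "s2"),
                         weighted=True) == pytest.approx(4.0)

    def test_unweighted_flag(self, demo_tree):
        # unweighted uses 1/richness weights; same value here by symmetry
        table = table_of({"s1": {"A": 3, "B": 1, "C": 0},
                          "s2": {"A": 0, "B": 0, "C": 9}}, ["A", "B", "C"])
        assert beta_mntd(table, demo_tree, ("s1", "s2"),
                         weighted=False) == pytest.approx(4.0)

    def test_empty_sample_errors(self, demo_tree):
        table = table_of({"s1": {"A": 1, "B": 0, "C": 0},
                          "s2": {"A": 0, "B": 0, "C": 0}}, ["A", "B", "C"])
        with pytest.raises(FormatError, match="s2"):
            beta_mntd(table, demo_tree, ("s1", "s2"))

    def test_taxon_missing_from_tree(self, demo_tree):
        table = table_of({"s1": {"A": 1, "Z": 1}, "s2": {"A": 1, "Z": 0}},
                         ["A", "Z"])
        with pytest.raises(KeyError, match="Z"):
            beta_mntd(table, demo_tree, ("s1", "s2"))


class TestClassification:
    @pytest.mark.parametrize("z,expected", [
        (-2.5, "homogeneous_selection"),
        (2.5, "variable_selection"),
        (0.0, "stochastic"),
        (-2.0, "stochastic"),
        (2.0, "stochastic"),
        (float("nan"), "undefined"),
    ])
    def test_two_sigma_rule(self, z, expected):
        assert classify(z) == expected


class TestBetaNTI:
    def test_exhaustive_permutation_oracle(self):
        """Monte-Carlo null matches exhaustive enumeration of all tip
        permutations on a 4-taxon, 3-sample instance (within 3 MC SE)."""
        tree = ea.simulate_tree(4, seed=2)
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(0, 20, size=(3, 4)) + [1, 0, 0, 0],
                              index=["s1", "s2", "s3"], columns=taxa)
        counts.iloc[1, 0] = 0
        table = CountTable(counts)

        dist = patristic_distances(tree, taxa).values
        present, weights = _community_arrays(table, taxa, weighted=True)
        iu = np.triu_indices(3, k=1)
        exact = np.array([
            _beta_mntd_matrix(dist, present, weights, np.array(perm))[iu]
            for perm in itertools.permutations(range(4))
        ])
        exact_mean, exact_sd = exact.mean(axis=0), exact.std(axis=0, ddof=1)

        res = beta_nti(table, tree, n_rand=1000, seed=9)
        frame = res.to_frame()
        mc_se = exact_sd / np.sqrt(1000)
        for k, row in frame.iterrows():
            assert abs(row["null_mean"] - exact_mean[k]) <= 3 * mc_se[k] + 1e-12
            assert abs(row["null_sd"] - exact_sd[k]) <= 3 * exact_sd[k] / np.sqrt(500)

    def test_label_invariance(self, demo_tree):
        """Consistently renaming taxa in table and tree changes nothing."""
        table = table_of({"s1": {"A": 4, "B": 1, "C": 0},
                          "s2": {"A": 0, "B": 2, "C": 6}}, ["A", "B", "C"])
        res1 = beta_nti(table, demo_tree, n_rand=200, seed=3)
        renamed = dendropy.Tree.get(data="((X:1,Y:1):1,Z:2);", schema="newick")
        table2 = CountTable(table.counts.rename(columns={"A": "X", "B": "Y",
                                                         "C": "Z"}))
        res2 = beta_nti(table2, renamed, n_rand=200, seed=3)
        assert np.allclose(res1.to_frame()["beta_nti"],
                           res2.to_frame()["beta_nti"], equal_nan=True)

    def test_branch_scaling_covariance(self):
        """Branch lengths ×c scale βMNTD by c and leave βNTI unchanged."""
        tree = ea.simulate_tree(12, seed=4)
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        rng = np.random.default_rng(1)
        table = CountTable(pd.DataFrame(rng.integers(0, 10, size=(4, 12)),
                                        index=list("wxyz"), columns=taxa))
        res1 = beta_nti(table, tree, n_rand=300, seed=2)
        scaled = tree.clone(depth=1)
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 3.0
        res2 = beta_nti(table, scaled, n_rand=300, seed=2)
        f1, f2 = res1.to_frame(), res2.to_frame()
        assert np.allclose(f2["beta_mntd_obs"], 3.0 * f1["beta_mntd_obs"])
        assert np.allclose(f2["beta_nti"], f1["beta_nti"], atol=1e-9,
                           equal_nan=True)

    def test_two_taxa_undefined(self):
        """With 2 taxa every tip permutation is equivalent: zero null spread
        is flagged as undefined, not clamped to ±inf."""
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        table = table_of({"s1": {"A": 5, "B": 0}, "s2": {"A": 0, "B": 5}},
                         ["A", "B"])
        res = beta_nti(table, tree, n_rand=100, seed=0)
        assert np.isnan(res.results[0].beta_nti)
        assert res.results[0].assembly_class == "undefined"

    def test_n_rand_floor(self, demo_tree, small_table):
        with pytest.raises(ValueError):
            beta_nti(small_table, demo_tree, n_rand=50)


class TestAssemblyDistanceMatrix:
    def test_construction_and_round_trip(self, tmp_path):
        tree = ea.simulate_tree(10, seed=1)
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 15, size=(3, 10)) * (rng.random((3, 10)) < 0.5)
        counts[:, 0] += 1  # keep every sample nonempty
        table = CountTable(pd.DataFrame(counts, index=["s1", "s2", "s3"],
                                        columns=taxa))
        res = beta_nti(table, tree, n_rand=200, seed=6)
        dm = assembly_distance_matrix(res)
        assert dm.labels == ["s1", "s2", "s3"]
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        path = tmp_path / "nti.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path, signed=True)
        assert np.allclose(back.values, dm.values, atol=1e-12)

    def test_undefined_pair_fails_export(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        table = table_of({"s1": {"A": 5, "B": 0}, "s2": {"A": 0, "B": 5}},
                         ["A", "B"])
        res = beta_nti(table, tree, n_rand=100, seed=0)
        with pytest.raises(FormatError, match="undefined"):
            assembly_distance_matrix(res)
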