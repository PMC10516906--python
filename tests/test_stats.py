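import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from ecoassembly.containers import DistanceMatrix, FormatError, GeneTable
from ecoassembly.stats import (
    anova_tukey,
    mantel,
    permutation_slope_test,
    rpkm,
    wilcoxon_screen,
    zscore,
)
from ecoassembly.synth import simulate_feature_table


def random_dm(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(labels or [f"s{i}" for i in range(n)],
                          squareform(pdist(pts)))


class TestMantel:
    def test_perfect_association(self):
        dm_x = random_dm(8, 1)
        dm_y = DistanceMatrix(dm_x.labels, 2.0 * dm_x.values)
        res = mantel(dm_x, dm_y, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_alignment_by_label(self):
        """dm_y given in scrambled label order must be realigned, not
        compared positionally."""
        dm_x = random_dm(8, 2)
        order = list(reversed(dm_x.labels))
        dm_y = DistanceMatrix(
            order,
            (2.0 * dm_x.reorder(order).values),
        )
        res = mantel(dm_x, dm_y, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        dm_x, dm_y = random_dm(7, 3), random_dm(7, 4)
        r1 = mantel(dm_x, dm_y, n_perm=99, seed=5).r
        new = [f"q{i}" for i in range(7)]
        r2 = mantel(DistanceMatrix(new, dm_x.values),
                    DistanceMatrix(new, dm_y.values), n_perm=99, seed=5).r
        assert r1 == pytest.approx(r2)

    def test_errors(self):
        dm_x = random_dm(6, 1)
        with pytest.raises(FormatError):
            mantel(dm_x, random_dm(6, 2, labels=[f"z{i}" for i in range(6)]))
        flat = DistanceMatrix(dm_x.labels,
                              np.ones((6, 6)) - np.eye(6))
        with pytest.raises(FormatError, match="constant"):
            mantel(dm_x, flat)


class TestWilcoxonScreen:
    def _screen(self, table, groups, **kw):
        return wilcoxon_screen(table, groups, treatment_group="trt",
                               reference_group="ref", **kw)

    def test_complete_separation_exact_p(self):
        """All treatment values below all reference values at 5 vs 5:
        one-sided exact p = 1/C(10,5) = 1/252."""
        values = np.concatenate([np.arange(1, 6), np.arange(10, 15)])
        table = pd.DataFrame({"f1": values},
                             index=[f"x{i}" for i in range(10)])
        groups = pd.Series(["trt"] * 5 + ["ref"] * 5, index=table.index)
        res = self._screen(table, groups, alternative="decrease")
        assert res.loc["f1", "p_raw"] == pytest.approx(1 / 252)
        assert res.loc["f1", "direction"] == "decreased"

    def test_identical_groups_not_significant(self):
        table = pd.DataFrame({"f1": [1.0, 2, 3, 1, 2, 3]},
                             index=[f"x{i}" for i in range(6)])
        groups = pd.Series(["trt"] * 3 + ["ref"] * 3, index=table.index)
        res = self._screen(table, groups)
        assert not res.loc["f1", "significant"]

    def test_constant_feature_flagged(self):
        table = pd.DataFrame({"f1": [2.0] * 8, "f2": range(8)},
                             index=[f"x{i}" for i in range(8)])
        groups = pd.Series(["trt"] * 4 + ["ref"] * 4, index=table.index)
        res = self._screen(table, groups)
        assert res.loc["f1", "constant"]
        assert res.loc["f1", "p_raw"] == 1.0

    def test_bh_monotone_and_order_invariant(self):
        table, groups, _ = simulate_feature_table(
            40, {"ref": 6, "trt": 6}, effect_size=1.5, seed=3,
            reference_group="ref")
        res = self._screen(table, groups)
        by_raw = res.sort_values("p_raw")
        assert (by_raw["p_adjusted"].diff().dropna() >= -1e-12).all()
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()
        shuffled = table[list(reversed(table.columns))]
        res2 = self._screen(shuffled, groups)
        assert np.allclose(res2.loc[res.index, "p_adjusted"],
                           res["p_adjusted"])


class TestAnovaTukey:
    def test_separated_groups_distinct_letters(self, rng):
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(10, 1, 8)])
        groups = np.array(["a"] * 8 + ["b"] * 8)
        res = anova_tukey(values, groups)
        assert set(res.letters["a"]).isdisjoint(res.letters["b"])

    def test_null_shares_letters_mostly(self):
        """Under a common distribution all groups share a letter in ≥90%
        of simulated runs (Tukey family-wise error control)."""
        share = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=20)
            groups = np.repeat(list("abcd"), 5)
            res = anova_tukey(values, groups)
            common = set.intersection(*(set(v) for v in res.letters.values()))
            share += bool(common)
        assert share >= 0.9 * n_runs

    def test_f_near_one_under_null(self):
        """E[F] ≈ 1 for a balanced null design (mean over 500 sims)."""
        fs = []
        for seed in range(500):
            rng = np.random.default_rng(10_000 + seed)
            values = rng.normal(size=24)
            fs.append(anova_tukey(values, np.repeat(list("abc"), 8)).f_statistic)
        assert 0.8 <= np.mean(fs) <= 1.2

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestZscore:
    def test_hand_example(self):
        out = zscore(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(out.to_numpy(), [-1.0, 0.0, 1.0])

    def test_normalisation_contract(self, rng):
        table = pd.DataFrame(rng.normal(5, 3, size=(20, 8)),
                             columns=[f"enz{i}" for i in range(8)])
        out = zscore(table)
        assert np.allclose(out.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_feature_named(self):
        table = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore(table)


class TestRpkm:
    def _genes(self, counts, lengths, totals):
        return GeneTable(
            counts=pd.DataFrame(counts, index=["g1"], columns=["s1"]),
            gene_lengths=pd.Series(lengths, index=["g1"]),
            total_mapped=pd.Series(totals, index=["s1"]),
        )

    def test_hand_example(self):
        out = rpkm(self._genes([[10]], [1000.0], [1e6]))
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count(self):
        assert rpkm(self._genes([[0]], [500.0], [1e6])).loc["g1", "s1"] == 0

    def test_doubling_totals_halves(self):
        a = rpkm(self._genes([[10]], [1000.0], [1e6]))
        b = rpkm(self._genes([[10]], [1000.0], [2e6]))
        assert b.loc["g1", "s1"] == pytest.approx(a.loc["g1", "s1"] / 2)

    def test_zero_total_errors(self):
        genes = GeneTable(
            counts=pd.DataFrame([[0]], index=["g1"], columns=["s1"]),
            gene_lengths=pd.Series([100.0], index=["g1"]),
            total_mapped=pd.Series([0.0], index=["s1"]),
        )
        with pytest.raises(FormatError):
            rpkm(genes)


class TestPermutationSlope:
    def test_exact_linear(self):
        x = np.arange(10, dtype=float)
        res = permutation_slope_test(x, 3.0 * x, n_perm=999, seed=0)
        assert res.slope == pytest.approx(3.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_floor(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = permutation_slope_test(x, y, n_perm=199, seed=1)
        assert res.p_value >= 1 / 200

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            permutation_slope_test(np.ones(6), np.arange(6.0))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=6), st.data())
def test_compact_letter_display_properties(n_groups, data):
    """Letter displays are faithful: every significantly different pair has
    disjoint letters; every non-different pair shares at least one."""
    from ecoassembly.stats import _compact_letter_display

    groups = [f"g{i}" for i in range(n_groups)]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    differs = {
        frozenset(p)
        for p in pairs
        if data.draw(st.booleans(), label=str(p))
    }
    letters = _compact_letter_display(groups, differs)
    for a, b in pairs:
        shared = set(letters[a]) & set(letters[b])
        if frozenset((a, b)) in differs:
            assert not shared, (letters, differs)
        else:
            assert shared, (letters, differs)
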