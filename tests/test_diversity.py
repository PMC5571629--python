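import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from focaltax import diversity as div
from focaltax.tables import CountTable


def make_table(rows, samples, taxa):
    return CountTable(pd.DataFrame(rows, index=samples, columns=taxa))


def unifrac_star_oracle(tips_a, tips_b, branch_lengths):
    """Brute-force unweighted UniFrac on a star tree: every tip is its own
    branch; unique length over observed length."""
    a, b = set(tips_a), set(tips_b)
    unique = sum(branch_lengths[t] for t in a ^ b)
    observed = sum(branch_lengths[t] for t in a | b)
    return unique / observed


class TestRarefy:
    def test_full_depth_unchanged(self):
        row = np.array([5, 3, 2])
        assert div.rarefy(row, 10, seed=0).tolist() == [5, 3, 2]

    def test_single_taxon(self):
        assert div.rarefy(np.array([0, 50, 0]), 20, seed=1).tolist() == [0, 20, 0]

    def test_depth_preserved_exactly(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 100, 20)
        out = div.rarefy(row, 200, seed=2)
        assert out.sum() == 200
        assert (out <= row).all()

    def test_two_equal_taxa_split_binomial(self):
        row = np.array([50_000, 50_000])
        draws = [div.rarefy(row, 10_000, seed=s)[0] for s in range(30)]
        # hypergeometric mean 5000, sd ~ 47; all draws within 5 sd
        assert all(abs(d - 5000) < 5 * 50 for d in draws)

    def test_depth_exceeding_total_raises(self):
        with pytest.raises(ValueError):
            div.rarefy(np.array([1, 1]), 3)


class TestAlpha:
    def test_chao1_formula(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
        row = [1, 1, 1, 1, 2, 2, 3, 3, 3, 3]
        table = make_table([row], ["s"], [f"t{i}" for i in range(10)])
        assert div.alpha_diversity(table, "chao1")["value"].iloc[0] == 14.0

    def test_chao1_bias_corrected_when_no_doubletons(self):
        row = [1, 1, 3, 3]  # F1=2, F2=0 -> 4 + 2*1/2 = 5
        table = make_table([row], ["s"], list("abcd"))
        assert div.alpha_diversity(table, "chao1")["value"].iloc[0] == 5.0

    def test_shannon_bits(self):
        table = make_table([[5, 5, 5, 5]], ["s"], list("abcd"))
        assert div.alpha_diversity(table, "shannon")["value"].iloc[0] == 2.0

    def test_faith_pd_star_tree(self, star_tree):
        table = make_table([[1, 1, 1, 0, 0]], ["s"],
                           ["t1", "t2", "t3", "t4", "t5"])
        val = div.alpha_diversity(table, "faith_pd", tree=star_tree)["value"].iloc[0]
        assert val == 3.0

    def test_shallow_sample_flagged_not_raised(self):
        table = make_table([[5, 5], [100, 100]], ["lo", "hi"], ["a", "b"])
        res = div.alpha_diversity(table, "observed_otus", rarefaction_depth=50)
        assert res.loc["lo", "excluded"] and np.isnan(res.loc["lo", "value"])
        assert not res.loc["hi", "excluded"]

    def test_missing_tree_tip_raises(self, star_tree):
        table = make_table([[1, 1]], ["s"], ["t1", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            div.alpha_diversity(table, "faith_pd", tree=star_tree)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=15))
    def test_chao1_at_least_observed(self, row):
        row = np.asarray(row)
        if row.sum() == 0:
            return
        s_obs = (row > 0).sum()
        assert div._chao1(row) >= s_obs
        if (row == 1).sum() == 0:
            assert div._chao1(row) == s_obs


class TestAlphaCompare:
    def test_permutation_p_floor(self):
        rng = np.random.default_rng(0)
        values = pd.Series(np.concatenate([rng.normal(0, 1, 50),
                                           rng.normal(8, 1, 50)]),
                           index=[f"s{i}" for i in range(100)])
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=values.index)
        res = div.alpha_compare(values, groups, n_perm=999, seed=1)
        assert np.isclose(res["p_perm"].iloc[0], 1 / 1000)

    def test_small_group_skipped(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        groups = pd.Series(["a", "a", "a", "b"], index=values.index)
        res = div.alpha_compare(values, groups)
        assert res["skipped"].iloc[0]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=values.index)
        r1 = div.alpha_compare(values, groups, seed=5)
        r2 = div.alpha_compare(values, groups, seed=5)
        assert r1["p_perm"].tolist() == r2["p_perm"].tolist()


class TestBeta:
    def test_unifrac_disjoint_star(self, star_tree):
        table = make_table([[1, 1, 0, 0, 0], [0, 0, 1, 1, 0]], ["A", "B"],
                           ["t1", "t2", "t3", "t4", "t5"])
        d = div.beta_distance(table, "unweighted_unifrac", tree=star_tree)
        assert np.isclose(d.data[0, 1], 1.0)

    def test_unifrac_overlap_matches_branch_oracle(self, star_tree):
        table = make_table([[1, 1, 0, 0, 0], [0, 1, 1, 0, 0]], ["A", "B"],
                           ["t1", "t2", "t3", "t4", "t5"])
        d = div.beta_distance(table, "unweighted_unifrac", tree=star_tree)
        lengths = {f"t{i}": 1.0 for i in range(1, 6)}
        oracle = unifrac_star_oracle({"t1", "t2"}, {"t2", "t3"}, lengths)
        assert np.isclose(d.data[0, 1], oracle)
        assert np.isclose(oracle, 2 / 3)

    def test_unifrac_weighted_star_oracle(self):
        tree = "(t1:2,t2:1,t3:5);"
        table = make_table([[1, 1, 0], [0, 1, 1]], ["A", "B"], ["t1", "t2", "t3"])
        d = div.beta_distance(table, "unweighted_unifrac", tree=tree)
        oracle = unifrac_star_oracle({"t1", "t2"}, {"t2", "t3"},
                                     {"t1": 2, "t2": 1, "t3": 5})
        assert np.isclose(d.data[0, 1], oracle)

    def test_bray_curtis_formula(self):
        table = make_table([[1, 1, 0], [0, 1, 1]], ["A", "B"], list("xyz"))
        d = div.beta_distance(table, "bray_curtis")
        assert np.isclose(d.data[0, 1], 0.5)

    def test_identical_samples_zero_distance(self, star_tree):
        table = make_table([[3, 2, 0, 0, 0], [3, 2, 0, 0, 0]], ["A", "B"],
                           ["t1", "t2", "t3", "t4", "t5"])
        for metric, kw in (("bray_curtis", {}),
                           ("unweighted_unifrac", {"tree": star_tree})):
            d = div.beta_distance(table, metric, **kw)
            assert np.isclose(d.data[0, 1], 0.0)
            assert np.allclose(d.data, d.data.T)

    def test_all_zero_sample_rejected(self):
        table = make_table([[1, 1], [0, 0]], ["A", "B"], ["x", "y"])
        with pytest.raises(ValueError):
            div.beta_distance(table, "bray_curtis")


class TestPcoa:
    def test_three_equidistant_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = div.pcoa(div.DistanceMatrix(list("abc"), D))
        ev = res["eigenvalues"]
        assert np.isclose(ev[0], ev[1])
        assert ev[0] > 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        D = squareform(pdist(pts))
        res = div.pcoa(div.DistanceMatrix([f"p{i}" for i in range(8)], D))
        coords = res["coordinates"].to_numpy()[:, :2]
        from scipy.spatial import procrustes
        _, _, err = procrustes(pts, coords)
        assert err < 1e-8

    def test_duplicate_samples_identical_coordinates(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = div.pcoa(div.DistanceMatrix(list("abc"), D))
        c = res["coordinates"].to_numpy()
        assert np.allclose(c[0], c[1])

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            div.DistanceMatrix(list("ab"), D)


class TestPermanova:
    def _clusters(self, sep, n=8, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 0.1, (n, 2)),
                         rng.normal(sep, 0.1, (n, 2))])
        ids = [f"s{i}" for i in range(2 * n)]
        D = squareform(pdist(pts))
        groups = pd.Series(["a"] * n + ["b"] * n, index=ids)
        return div.DistanceMatrix(ids, D), groups

    def test_separated_clusters_minimal_p(self):
        dm, groups = self._clusters(10.0)
        res = div.permanova(dm, groups, n_perm=1000, seed=0)
        assert np.isclose(res["p_value"], 1 / 1001)

    def test_statistic_matches_skbio(self):
        dm, groups = self._clusters(1.0, seed=2)
        res = div.permanova(dm, groups, n_perm=99, seed=0)
        import skbio
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, dm.ids), groups.loc[dm.ids].to_numpy(),
            permutations=0)
        assert np.isclose(res["pseudo_F"], ref["test statistic"])

    def test_seed_reproducible(self):
        dm, groups = self._clusters(0.5, seed=3)
        p1 = div.permanova(dm, groups, n_perm=200, seed=9)["p_value"]
        p2 = div.permanova(dm, groups, n_perm=200, seed=9)["p_value"]
        assert p1 == p2

    def test_single_group_rejected(self):
        dm, groups = self._clusters(1.0)
        with pytest.raises(ValueError):
            div.permanova(dm, pd.Series("a", index=groups.index))


class TestGroupDistances:
    def test_duplicated_separated_groups(self):
        # two groups of duplicated points: intra 0, inter > 0
        D = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                D[i, j] = D[j, i] = 5.0
        dm = div.DistanceMatrix(list("wxyz"), D)
        groups = pd.Series(["a", "a", "b", "b"], index=dm.ids)
        res = div.group_distance_compare(dm, groups)
        s = res["summary"].set_index("set")
        assert s.loc["a", "mean"] == 0.0
        assert s.loc["b", "mean"] == 0.0
        assert s.loc["a|b", "mean"] == 5.0

    def test_pair_counts_match_hand_enumeration(self):
        # 4 samples, groups (a,a,a,b): intra-a 3 pairs, intra-b 0, inter 3
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4, 2))
        dm = div.DistanceMatrix(list("wxyz"), squareform(pdist(pts)))
        groups = pd.Series(["a", "a", "a", "b"], index=dm.ids)
        res = div.group_distance_compare(dm, groups)
        s = res["summary"].set_index("set")
        assert s.loc["a", "n_pairs"] == 3
        assert s.loc["b", "n_pairs"] == 0
        assert s.loc["a|b", "n_pairs"] == 3
        assert "b" in res["flagged"]

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        dm = div.DistanceMatrix([f"s{i}" for i in range(10)],
                                squareform(pdist(pts)))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.ids)
        r1 = div.group_distance_compare(dm, groups, bootstrap_k=20, seed=4)
        r2 = div.group_distance_compare(dm, groups, bootstrap_k=20, seed=4)
        for g in ("a", "b"):
            assert np.array_equal(r1["bootstrap_intragroup_means"][g],
                                  r2["bootstrap_intragroup_means"][g],
                                  equal_nan=True)
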