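import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from focaltax import screening as scr
from focaltax.tables import CountTable


def make_table(rows, samples, taxa):
    return CountTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestFilterAndDedup:
    def _fixture(self):
        # 6 samples / 3 subjects with hand-chosen depths
        table = make_table(
            [[999, 0], [1000, 0], [10_000, 0], [500, 500], [2000, 0], [50, 0]],
            [f"s{i}" for i in range(6)], ["a", "b"],
        )
        meta = pd.DataFrame({
            "subject_id": ["u1", "u1", "u2", "u2", "u3", "u3"],
            "collection_order": [1, 2, 1, 2, 2, 1],
            "body_site": ["feces"] * 5 + ["skin"],
        }, index=[f"s{i}" for i in range(6)])
        return table, meta

    def test_depth_boundary_inclusive(self):
        table, meta = self._fixture()
        res = scr.filter_and_dedup(table, meta, min_depth=1000, site="feces")
        # hand count: s0 (999) and s5 (50) fail depth -> 4; all 4 are feces;
        # u2 keeps only its first specimen -> 3
        assert res.retention == {"initial": 6, "depth": 4, "site": 4, "dedup": 3}

    def test_earliest_specimen_kept(self):
        table, meta = self._fixture()
        res = scr.filter_and_dedup(table, meta, min_depth=100, site="feces")
        kept = set(res.table.samples)
        # u1: s0 (order 1); u2: s2; u3: only s4 passes site
        assert kept == {"s0", "s2", "s4"}

    def test_idempotent(self):
        table, meta = self._fixture()
        res1 = scr.filter_and_dedup(table, meta, min_depth=1000, site="feces")
        res2 = scr.filter_and_dedup(res1.table, res1.meta, min_depth=1000, site="feces")
        assert res1.table.samples == res2.table.samples

    def test_unknown_site_lists_valid(self):
        table, meta = self._fixture()
        with pytest.raises(ValueError, match="feces"):
            scr.filter_and_dedup(table, meta, min_depth=1, site="gill")


class TestDetection:
    def test_threshold_rule(self):
        table = make_table([[0], [1], [4]], ["s1", "s2", "s3"], ["f"])
        det1 = scr.detect_focal(table, ["f"], threshold=1)
        assert det1.df["f"].tolist() == [False, True, True]
        det5 = scr.detect_focal(table, ["f"], threshold=5)
        assert det5.df["f"].tolist() == [False, False, False]

    def test_missing_focal_id_raises(self, toy_table):
        with pytest.raises(KeyError):
            scr.detect_focal(toy_table, ["nope"])


class TestSummarize:
    def test_prevalence_shares_and_geomean(self):
        table = make_table(
            [[96, 0, 9904], [0, 4, 9996], [0, 0, 10_000], [0, 0, 10_000]],
            ["s1", "s2", "s3", "s4"], ["fA", "fB", "bg"],
        )
        det = scr.detect_focal(table, ["fA", "fB"])
        summary = scr.summarize_focal(table, det)
        assert summary.loc["fA", "prevalence_pct"] == 25.0
        assert summary.loc["fA", "read_share_pct"] == 96.0
        assert summary.loc["fB", "read_share_pct"] == 4.0
        assert abs(summary["read_share_pct"].sum() - 100.0) < 1e-9

    def test_geometric_mean_log_scale(self):
        table = make_table(
            [[1, 9999], [100, 9900], [0, 100]],
            ["s1", "s2", "s3"], ["f", "bg"],
        )
        det = scr.detect_focal(table, ["f"])
        s = scr.summarize_focal(table, det)
        assert np.isclose(s.loc["f", "geo_mean_rel_abund"], 1e-3)

    def test_never_detected_is_nan_not_zero(self):
        table = make_table([[0, 5], [0, 5]], ["s1", "s2"], ["f", "bg"])
        det = scr.detect_focal(table, ["f"])
        s = scr.summarize_focal(table, det)
        assert np.isnan(s.loc["f", "geo_mean_rel_abund"])


class TestOverlap:
    def test_exact_p_matches_enumeration(self):
        # N=10, |A|=|B|=5, overlap 5: p = 1/252 by exhaustive placement
        det = scr.DetectionMatrix(pd.DataFrame({
            "A": [True] * 5 + [False] * 5,
            "B": [True] * 5 + [False] * 5,
        }, index=[f"s{i}" for i in range(10)]), 1)
        res = scr.overlap_test(det, "A", "B")
        a_set = frozenset(range(5))
        count = total = 0
        for b in itertools.combinations(range(10), 5):
            total += 1
            if len(a_set & set(b)) >= 5:
                count += 1
        assert total == 252 and count == 1
        assert np.isclose(res.p_value, count / total)

    def test_brute_force_agreement_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(5, 12))
            a = rng.random(n) < 0.5
            b = rng.random(n) < 0.5
            if a.sum() == 0 or b.sum() == 0:
                continue
            det = scr.DetectionMatrix(
                pd.DataFrame({"A": a, "B": b}, index=[f"s{i}" for i in range(n)]), 1)
            res = scr.overlap_test(det, "A", "B")
            k_obs = int((a & b).sum())
            count = total = 0
            for bset in itertools.combinations(range(n), int(b.sum())):
                total += 1
                if len(set(np.flatnonzero(a)) & set(bset)) >= k_obs:
                    count += 1
            assert np.isclose(res.p_value, count / total)

    def test_full_conditional_codetection(self):
        det = scr.DetectionMatrix(pd.DataFrame({
            "A": [True, True, True, False],
            "B": [True, True, False, False],
        }, index=list("wxyz")), 1)
        res = scr.overlap_test(det, "A", "B")
        assert res.conditional_pct == 100.0

    def test_empty_universe_raises(self):
        det = scr.DetectionMatrix(pd.DataFrame({"A": [], "B": []}), 1)
        with pytest.raises(ValueError):
            scr.overlap_test(det, "A", "B")


class TestCodetectionShift:
    def _setup(self, a_only_vals, both_vals):
        rows, samples = [], []
        for i, v in enumerate(a_only_vals):
            rows.append([v, 0, 1000 - v])
            samples.append(f"o{i}")
        for i, v in enumerate(both_vals):
            rows.append([v, 5, 995 - v])
            samples.append(f"b{i}")
        table = make_table(rows, samples, ["A", "B", "bg"])
        det = scr.detect_focal(table, ["A", "B"])
        return table, det

    def test_enumerated_one_sided_p(self):
        # A-only {1,2} vs co-detected {3,4}: 1 of 6 arrangements as extreme
        table, det = self._setup([1, 2], [3, 4])
        res = scr.codetection_shift(table, det, "A", "B")
        assert np.isclose(res["p_value"], 1 / 6)

    def test_direction_contract(self):
        # co-detected all smaller -> one-sided p >= 0.5
        table, det = self._setup([10, 20], [1, 2])
        res = scr.codetection_shift(table, det, "A", "B")
        assert res["p_value"] >= 0.5

    def test_empty_stratum_named(self):
        table, det = self._setup([], [3, 4])
        with pytest.raises(ValueError, match="without"):
            scr.codetection_shift(table, det, "A", "B")


class TestLongitudinal:
    def _cohort(self):
        # 6 subjects x 2 samples; patterns: --, +-, ++, --, -+, ++
        patterns = [(0, 0), (5, 0), (3, 4), (0, 0), (0, 2), (9, 9)]
        rows, samples, meta_rows = [], [], []
        for i, (v1, v2) in enumerate(patterns):
            for j, v in enumerate((v1, v2), start=1):
                rows.append([v, 1000 - v])
                samples.append(f"u{i}.t{j}")
                meta_rows.append((f"u{i}.t{j}", f"u{i}", j))
        table = make_table(rows, samples, ["f", "bg"])
        meta = pd.DataFrame(meta_rows, columns=["sample_id", "subject_id",
                                                "collection_order"]).set_index("sample_id")
        det = scr.detect_focal(table, ["f"])
        return table, meta, det

    def test_group_partition_matches_hand_count(self):
        table, meta, det = self._cohort()
        res = scr.longitudinal_groups(table, meta, det)
        sizes = res.groups.value_counts().to_dict()
        assert sizes == {"I": 2, "II": 2, "III": 2}

    def test_all_positive_is_group_iii_mixed_is_ii(self):
        table, meta, det = self._cohort()
        res = scr.longitudinal_groups(table, meta, det)
        assert res.groups["u2"] == "III"
        assert res.groups["u1"] == "II"

    def test_partition_exhaustive_exclusive(self):
        table, meta, det = self._cohort()
        res = scr.longitudinal_groups(table, meta, det)
        assert set(res.groups.index) == set(meta["subject_id"].unique())
        assert res.groups.isin(["I", "II", "III"]).all()

    def test_single_sample_subject_rejected(self):
        table, meta, det = self._cohort()
        meta2 = meta.drop(index="u0.t2")
        table2 = table.subset_samples(list(meta2.index))
        det2 = scr.DetectionMatrix(det.df.loc[meta2.index], det.threshold)
        with pytest.raises(ValueError):
            scr.longitudinal_groups(table2, meta2, det2)


class TestRankTest:
    def test_mann_whitney_two_sided_exact(self):
        # {1,2} vs {3,4}: 2 of 6 arrangements as extreme -> p = 1/3
        _, p = scr.rank_test([1, 2], [3, 4], "mann_whitney_two_sided")
        assert np.isclose(p, 1 / 3)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=5), rng.normal(size=6)
        _, p = scr.rank_test(x, y, "mann_whitney_two_sided")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert np.isclose(p, ref.pvalue)

    def test_spearman_monotone(self):
        rho, _ = scr.rank_test([1, 2, 3, 4], [10, 20, 30, 40], "spearman")
        assert rho == 1.0
        rho, _ = scr.rank_test([1, 2, 3, 4], [8, 6, 4, 2], "spearman")
        assert rho == -1.0

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError):
            scr.rank_test([1, 1, 1], [1, 2, 3], "spearman")

    def test_identical_distributions_p_centered(self):
        # average one-sided p over null simulations ~ 0.5
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            x, y = rng.normal(size=20), rng.normal(size=20)
            _, p = scr.rank_test(x, y, "mann_whitney_one_sided")
            ps.append(p)
        assert abs(np.mean(ps) - 0.5) < 0.06
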