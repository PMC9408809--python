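import numpy as np
import pytest

import myodti as m
from myodti.regional_stats import kruskal_wallis_two_group


def brute_force_kw_h(a, b):
    """Rank-sum H from first principles (explicit average ranks + tie term)."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = np.mean(np.arange(i, j) + 1)
        i = j
    n = len(pooled)
    ra, rb = ranks[: len(a)], ranks[len(a):]
    h = 12.0 / (n * (n + 1)) * (
        len(a) * (ra.mean() - (n + 1) / 2) ** 2 + len(b) * (rb.mean() - (n + 1) / 2) ** 2
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_matches_brute_force_on_small_instances(self):
        for a, b in [
            ([1.0, 2, 3], [4.0, 5, 6]),
            ([1.0, 2, 2], [2.0, 3, 4]),
            ([5.0, 1, 3, 3], [2.0, 4]),
        ]:
            h, _ = kruskal_wallis_two_group(np.array(a), np.array(b))
            assert h == pytest.approx(brute_force_kw_h(np.array(a), np.array(b)), rel=1e-12)

    def test_identical_groups_adjusted_p_is_one(self):
        groups = {"remote": np.array([1.0, 2, 3]), "border": np.array([1.0, 2, 3])}
        table = m.kruskal_wallis_pairwise(groups)
        assert table.H.iloc[0] == 0.0
        assert table.p_adjusted.iloc[0] == 1.0

    def test_constant_pooled_sample(self):
        h, p = kruskal_wallis_two_group(np.full(5, 2.0), np.full(4, 2.0))
        assert h == 0.0 and p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        groups = {
            "remote": rng.normal(0, 1, 500),
            "border": rng.normal(0, 1, 500),
            "infarct": rng.normal(2, 1, 500),
        }
        table = m.kruskal_wallis_pairwise(groups)
        row = table[(table.group_a == "infarct") & (table.group_b == "remote")].iloc[0]
        assert row.p_adjusted < 0.01 and row.significant

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(1)
        groups = {r: rng.normal(0, 1, 30) for r in ("remote", "border", "infarct")}
        table = m.kruskal_wallis_pairwise(groups)
        assert len(table) == 3
        assert (table.p_adjusted <= 1.0).all()
        np.testing.assert_allclose(
            table.p_adjusted, np.minimum(table.p_raw * 3, 1.0)
        )

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 80), rng.normal(0.5, 1, 90)
        h1, p1 = kruskal_wallis_two_group(a, b)
        h2, p2 = kruskal_wallis_two_group(np.exp(a), np.exp(b))
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.kruskal_wallis_pairwise({"remote": np.array([1.0, 2]), "border": np.array([])})


class TestAndersonDarling:
    def test_statistic_matches_scipy(self):
        from scipy import stats

        x = np.random.default_rng(3).normal(0, 1, 200)
        a2_star, _ = m.anderson_darling(x)
        ref = stats.anderson(x, dist="norm").statistic
        n = len(x)
        assert a2_star == pytest.approx(ref * (1 + 0.75 / n + 2.25 / n**2), rel=1e-10)

    def test_accepts_normal_rejects_bimodal(self):
        """p > 0.01 for N(0,1) in >= 95% of 200 seeds; p < 0.01 for a wide mixture."""
        accept = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(0, 1, 500)
            _, p = m.anderson_darling(x)
            accept += p > 0.01
        assert accept >= 190

        rng = np.random.default_rng(999)
        mix = np.concatenate([rng.normal(-5, 1, 250), rng.normal(5, 1, 250)])
        _, p = m.anderson_darling(mix)
        assert p < 0.01

    def test_statistic_nonnegative(self):
        for seed in range(10):
            x = np.random.default_rng(seed).uniform(0, 1, 100)
            a2, _ = m.anderson_darling(x)
            assert a2 >= 0

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            m.anderson_darling(np.arange(5.0))
        with pytest.raises(ValueError, match="constant"):
            m.anderson_darling(np.full(20, 3.0))


class TestPoolingAndSummaries:
    def _labels(self, arr):
        return m.LabelMap(np.asarray(arr, np.int16), (8.0, 1.0, 1.0))

    def test_all_remote_leaves_other_regions_empty(self):
        labels = self._labels(np.ones((1, 2, 2)))
        maps = {"MD": np.arange(4.0).reshape(1, 2, 2)}
        s = m.pool_by_region(maps, labels)
        assert s.get("MD", "remote").size == 4
        assert s.get("MD", "border").size == 0
        assert s.get("MD", "infarct").size == 0

    def test_counts_conserved_and_disjoint(self, default_phantom):
        labels = default_phantom.truth_labels_systole
        data = np.random.default_rng(0).normal(size=labels.labels.shape)
        valid = np.random.default_rng(1).random(labels.labels.shape) > 0.1
        s = m.pool_by_region({"x": data}, labels, valid_mask=valid)
        total = sum(s.get("x", r).size for r in ("remote", "border", "infarct"))
        assert total == int(((labels.labels > 0) & valid).sum())

    def test_pooled_means_match_generator(self, default_phantom):
        study = default_phantom
        lab = study.truth_labels_diastole
        s = m.pool_by_region({"t1": study.t1_pre}, lab)
        for region in ("remote", "border", "infarct"):
            want = study.config.t1_values[region]["native"]
            got = np.mean(s.get("t1", region))
            assert got == pytest.approx(want, abs=3.0)  # 15 ms noise, thousands of voxels

    def test_grid_mismatch_rejected(self):
        labels = self._labels(np.ones((1, 2, 2)))
        with pytest.raises(ValueError, match="grid"):
            m.pool_by_region({"x": np.zeros((1, 3, 3))}, labels)

    def test_quantile_convention(self):
        s = m.RegionSamples()
        s.add("q", "remote", np.array([1.0, 2, 3, 4]), "S1")
        row = m.summarize(s).iloc[0]
        assert row["median"] == 2.5 and row.q1 == 1.75 and row.q3 == 3.25

    def test_constant_and_singleton_summaries(self):
        s = m.RegionSamples()
        s.add("q", "remote", np.full(5, 7.0), "S1")
        s.add("q", "border", np.array([42.0]), "S1")
        table = m.summarize(s).set_index("region")
        for region, val in (("remote", 7.0), ("border", 42.0)):
            r = table.loc[region]
            assert r["mean"] == r["median"] == r.q1 == r.q3 == val

    def test_summary_quartile_order(self, default_phantom):
        fit = m.fit_tensor_loglinear(default_phantom.dwi)
        inv = m.compute_invariants(fit.tensor)
        s = m.pool_by_region({"MD": inv.md}, default_phantom.truth_labels_systole)
        t = m.summarize(s)
        assert ((t.q1 <= t["median"]) & (t["median"] <= t.q3)).all()


class TestPercentChange:
    def test_identical_is_zero(self):
        x = np.array([1.0, 2, 3])
        assert m.percent_change_of_medians(x, x) == 0.0

    def test_worked_arithmetic(self):
        a = np.array([1.0, 1.62, 2.0])
        b = np.array([1.0, 1.22, 2.0])
        assert m.percent_change_of_medians(a, b) == pytest.approx(32.79, abs=0.01)

    def test_negative_change_sign_preserved(self):
        a = np.array([0.1, 0.23, 0.5])
        b = np.array([0.1, 0.29, 0.5])
        assert m.percent_change_of_medians(a, b) == pytest.approx(-20.69, abs=0.01)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero reference"):
            m.percent_change_of_medians(np.array([1.0]), np.array([0.0]))

    def test_rounded_median_recomputation_within_one_point(self):
        """Percent changes recomputed from 2-decimal medians stay within
        1 percentage point of the unrounded computation."""
        rng = np.random.default_rng(4)
        a = 1.6234 + 0.3 * rng.standard_normal(5001)
        b = 1.2187 + 0.3 * rng.standard_normal(5001)
        exact = m.percent_change_of_medians(a, b)
        rounded = 100.0 * (round(np.median(a), 2) - round(np.median(b), 2)) / round(np.median(b), 2)
        assert abs(exact - rounded) < 1.0
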