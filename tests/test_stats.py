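"""Nonparametric group statistics: summaries, omnibus, post hoc, gating."""

import itertools

import numpy as np
import pytest
import scipy.stats

from flimfret import (
    background_gate,
    boxplot_summary,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
)
from flimfret.errors import ConfigError
from flimfret.stats import save_boxplots


class TestBoxplotSummary:
    def test_integer_grid(self):
        s = boxplot_summary(range(1, 10))
        assert (s.median, s.q1, s.q3) == (5.0, 3.0, 7.0)
        assert s.n == 9

    def test_constant_vector(self):
        s = boxplot_summary([4.2] * 7)
        assert s.median == s.q1 == s.q3 == s.p10 == s.p90 == 4.2

    def test_uniform_percentiles(self):
        rng = np.random.default_rng(1)
        s = boxplot_summary(rng.uniform(0, 1, 10_000))
        assert s.p10 == pytest.approx(0.1, abs=0.01)
        assert s.p90 == pytest.approx(0.9, abs=0.01)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        s = boxplot_summary(rng.normal(size=200))
        assert s.p10 <= s.q1 <= s.median <= s.q3 <= s.p90

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])


def brute_force_h(groups):
    """Rank-sum arithmetic oracle (no ties): 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)."""
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    n_total = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r**2 / len(g)
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_rank_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(7.2, abs=1e-12)
        assert h == pytest.approx(brute_force_h(groups), abs=1e-12)

    def test_all_constant_degenerate(self):
        h, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_null_calibration(self):
        """Type-I error of the omnibus at alpha=0.05 over 1000 null draws."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            groups = [rng.normal(size=38) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_matches_exact_permutation_on_tiny_groups(self):
        """Chi-square p agrees with full-enumeration permutation p within 0.05."""
        values = np.array([1.0, 3.0, 4.0, 2.0, 6.0, 8.0, 5.0, 9.0, 11.0])
        groups = [values[:3], values[3:6], values[6:]]
        h_obs, p_chi2 = kruskal_wallis(groups)

        n = len(values)
        count = 0
        total = 0
        for combo1 in itertools.combinations(range(n), 3):
            rest = [i for i in range(n) if i not in combo1]
            for combo2 in itertools.combinations(rest, 3):
                combo3 = [i for i in rest if i not in combo2]
                perm = [values[list(combo1)], values[list(combo2)],
                        values[list(combo3)]]
                total += 1
                if brute_force_h(perm) >= h_obs - 1e-12:
                    count += 1
        p_exact = count / total
        assert abs(p_chi2 - p_exact) < 0.05


class TestDunnPosthoc:
    def test_two_groups_z_squared_equals_h(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(size=15), "b": rng.normal(1.0, size=12)}
        h, _ = kruskal_wallis(list(groups.values()))
        table = dunn_posthoc(groups)
        assert table["z"].iloc[0] ** 2 == pytest.approx(h, rel=1e-9)

    def test_identical_groups_all_p_one(self):
        groups = {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [1, 2, 3, 4]}
        table = dunn_posthoc(groups)
        assert (table["adjusted_p"] == 1.0).all()
        assert not table["significant"].any()

    @pytest.mark.parametrize("correction", ["holm", "bonferroni", "sidak"])
    def test_adjusted_never_below_raw(self, correction):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(loc, size=20) for k, loc in
                  zip("abcd", [0, 0.3, 0.6, 1.0])}
        table = dunn_posthoc(groups, correction=correction)
        assert (table["adjusted_p"] >= table["raw_p"] - 1e-12).all()

    def test_monotone_transform_invariance(self):
        """Rank-based: exp-transforming the data changes nothing."""
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(loc, size=25) for k, loc in
                  zip("abc", [0, 0.5, 1.0])}
        t1 = dunn_posthoc(groups)
        t2 = dunn_posthoc({k: np.exp(v) for k, v in groups.items()})
        np.testing.assert_allclose(t1["z"], t2["z"], rtol=1e-12)

    def test_unknown_correction_rejected(self):
        with pytest.raises(ConfigError):
            dunn_posthoc({"a": [1, 2], "b": [3, 4]}, correction="fdr_tsbky")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc({"a": [1, 2, 3]})


class TestBackgroundGate:
    def test_identical_condition_not_flagged(self):
        rng = np.random.default_rng(6)
        ctrl = rng.normal(size=38)
        threshold, flag, p = background_gate(ctrl.copy(), ctrl)
        assert threshold == pytest.approx(np.median(ctrl))
        assert not flag

    def test_clear_separation_flagged(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(0, 1, size=38)
        cond = rng.normal(3, 1, size=38)
        _, flag, p = background_gate(cond, ctrl)
        assert flag and p < 0.05

    def test_threshold_is_control_median(self):
        ctrl = [1.0, 2.0, 3.0, 10.0]
        threshold, _, _ = background_gate([5.0, 6.0], ctrl)
        assert threshold == boxplot_summary(ctrl).median

    def test_full_gate_type_one_error(self):
        """Omnibus -> Dunn -> gate under the null keeps the false-flag rate
        at or below 0.07 (nominal 0.05) over 1000 simulations."""
        rng = np.random.default_rng(12345)
        flags = 0
        for _ in range(1000):
            groups = [rng.normal(size=38) for _ in range(3)]
            _, omnibus_p = kruskal_wallis(groups)
            if omnibus_p >= 0.05:
                continue
            _, flag, _ = background_gate(groups[0], groups[2])
            flags += flag
        assert flags / 1000 <= 0.07


class TestCompareGroups:
    def test_end_to_end_with_control(self):
        rng = np.random.default_rng(9)
        groups = {
            "WT+E47": rng.normal(40, 8, size=40),
            "del+E47": rng.normal(25, 8, size=40),
            "neg_ctrl": rng.normal(8, 5, size=40),
        }
        gc = compare_groups(
            groups, metric_name="binding_pct", negative_control="neg_ctrl"
        )
        assert gc.omnibus_p < 0.05
        assert gc.above_background["WT+E47"]
        assert gc.background_threshold == pytest.approx(
            np.median(groups["neg_ctrl"])
        )
        assert set(gc.summaries) == set(groups)

    def test_unknown_control_rejected(self):
        with pytest.raises(ConfigError):
            compare_groups(
                {"a": [1, 2, 3], "b": [4, 5, 6]}, negative_control="zzz"
            )

    def test_boxplot_export(self, tmp_path):
        rng = np.random.default_rng(10)
        groups = {"a": rng.normal(size=30), "b": rng.normal(1, size=30)}
        out = tmp_path / "box.png"
        save_boxplots(groups, out, metric_name="E")
        assert out.stat().st_size > 0
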