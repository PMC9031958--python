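"""Rank-based two-sample tests against independent oracles."""

from itertools import combinations

import numpy as np
import pytest
import scipy.stats as ss

from nuctrack.stats import fligner_killeen, per_frame_variance_tests, wilcoxon_rank_sum


def exact_wilcoxon_p_oracle(x, y):
    """Full enumeration of rank assignments, written independently."""
    pooled = np.concatenate([x, y])
    ranks = ss.rankdata(pooled)
    n1, nn = len(x), len(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (nn + 1) / 2
    count = total = 0
    for idx in combinations(range(nn), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= abs(w - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_fully_separated_small_samples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 5.0] * 5, [1.0, 2.0, 5.0] * 5)
        nn = 30
        assert res.statistic == pytest.approx(15 * (nn + 1) / 2)
        assert res.p_value == 1.0

    def test_degenerate_constant_data(self):
        res = wilcoxon_rank_sum([3.0] * 4, [3.0] * 6)
        assert res.degenerate and res.p_value == 1.0

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_exact_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, n)
            res = wilcoxon_rank_sum(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_wilcoxon_p_oracle(x, y))

    def test_normal_approx_close_to_exact_regime(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, y = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
            mine = wilcoxon_rank_sum(x, y)
            ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.method == "normal_approx"
            assert mine.p_value == pytest.approx(ref.pvalue, abs=0.02)

    def test_tie_corrected_against_reference(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 6.0]
        y = [2.0, 4.0, 5.0, 5.0, 6.0, 6.0, 7.0, 9.0]
        mine = wilcoxon_rank_sum(x, y)
        ref = ss.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.lognormal(0, 1, 25), rng.lognormal(0.5, 1, 30)
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(np.log(x), np.log(y))
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_direction_reported_via_medians(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(5, 1, 40), rng.normal(0, 1, 40)
        res = wilcoxon_rank_sum(x, y)
        assert res.group_summaries["median_1"] > res.group_summaries["median_2"]
        assert res.p_value < 1e-6


class TestFlignerKilleen:
    def test_matches_reference_implementation(self):
        # frozen two-group dataset; scipy's fligner is the independent oracle
        x = [51.0, 87.0, 50.0, 48.0, 79.0, 61.0, 53.0, 54.0]
        y = [82.0, 91.0, 92.0, 80.0, 52.0, 79.0, 73.0, 74.0]
        mine = fligner_killeen(x, y)
        ref_stat, ref_p = ss.fligner(x, y)
        assert mine.statistic == pytest.approx(ref_stat, abs=1e-6)
        assert mine.p_value == pytest.approx(ref_p, rel=1e-6)

    def test_matches_reference_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(5, 40))
            y = rng.normal(2, 3, rng.integers(5, 40))
            mine = fligner_killeen(x, y)
            ref_stat, ref_p = ss.fligner(x, y)
            assert mine.statistic == pytest.approx(ref_stat, rel=1e-9, abs=1e-9)
            assert mine.p_value == pytest.approx(ref_p, rel=1e-6, abs=1e-12)

    def test_location_shift_invariance(self):
        # dyadic values: adding the shift is exact in floating point, so
        # the median-centered deviations coincide exactly across groups
        rng = np.random.default_rng(12)
        x = rng.integers(0, 64, 40) / 4.0
        a = fligner_killeen(x, x + 100.0)
        assert a.statistic == pytest.approx(0.0, abs=1e-9)
        assert a.p_value == pytest.approx(1.0, abs=1e-6)
        # general floats: invariance holds to rounding of the medians
        y = rng.normal(0, 2, 40)
        b = fligner_killeen(y, y + 100.0)
        assert b.statistic < 0.05 and b.p_value > 0.8

    def test_common_scaling_equivariance(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 3, 30)
        a, b = fligner_killeen(x, y), fligner_killeen(5 * x, 5 * y)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_detects_scale_difference(self):
        rng = np.random.default_rng(14)
        res = fligner_killeen(rng.normal(0, 1, 50), rng.normal(0, 3, 50))
        assert res.p_value < 0.01

    def test_chi2_p_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(0, 1.0, 25), rng.normal(0, 1.8, 25)
        obs = fligner_killeen(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            p = rng.permutation(pooled)
            if fligner_killeen(p[:n1], p[n1:]).statistic >= obs.statistic - 1e-12:
                count += 1
        perm_p = count / n_perm
        mc_se = np.sqrt(perm_p * (1 - perm_p) / n_perm)
        assert abs(obs.p_value - perm_p) < max(4 * mc_se, 0.02)

    def test_zero_spread_group_handled(self):
        res = fligner_killeen([5.0] * 10, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert 0.0 <= res.p_value <= 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fligner_killeen([1.0], [1.0, 2.0])


class TestPerFrameVarianceTests:
    @staticmethod
    def frames_table(rng, sd_by_frame, n=40):
        import pandas as pd

        rows = [
            (f, v) for f, sd in sd_by_frame.items() for v in rng.normal(0, sd, n)
        ]
        return pd.DataFrame(rows, columns=["frame", "value"])

    def test_identical_groups_non_significant(self):
        rng = np.random.default_rng(20)
        a = self.frames_table(rng, {0: 1.0, 50: 1.0, 99: 1.0})
        b = self.frames_table(rng, {0: 1.0, 50: 1.0, 99: 1.0})
        out = per_frame_variance_tests(a, b, [0, 50, 99])
        assert (out["p_value"] > 0.01).all()

    def test_missing_frame_skipped_with_warning(self):
        rng = np.random.default_rng(21)
        a = self.frames_table(rng, {0: 1.0})
        b = self.frames_table(rng, {0: 1.0, 5: 1.0})
        with pytest.warns(UserWarning, match="frame 5"):
            out = per_frame_variance_tests(a, b, [0, 5])
        assert out["frame"].tolist() == [0]

    def test_bh_adjustment_for_dense_schedules(self):
        rng = np.random.default_rng(22)
        sds = {f: 1.0 for f in range(6)}
        a = self.frames_table(rng, sds)
        b = self.frames_table(rng, {f: 1.0 + 0.3 * f for f in range(6)})
        out = per_frame_variance_tests(a, b, list(range(6)), adjust="bh")
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p_value"] - 1e-12).all()


class TestNullCalibration:
    def test_rejection_rates_near_nominal(self):
        # both tests at alpha = 0.05 under the null, 200 replicates each
        rng = np.random.default_rng(30)
        alpha = 0.05
        rej_w = rej_f = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
            if wilcoxon_rank_sum(x, y).p_value < alpha:
                rej_w += 1
            if fligner_killeen(x, y).p_value < alpha:
                rej_f += 1
        assert 0.03 <= rej_w / n_rep <= 0.08
        assert 0.03 <= rej_f / n_rep <= 0.08
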