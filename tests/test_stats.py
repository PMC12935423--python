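import numpy as np
import pytest

from bradyssa.exceptions import (InsufficientDataError, PairingError,
                                 ParameterError)
from bradyssa.stats import (SlownessAnalysis, anova_oneway, eta_squared_bin,
                            kruskal_wallis, pairwise_wilcoxon,
                            rho_strength_bin, shapiro_gate, spearman)
from bradyssa.tables import fixture_table1, fixture_table2
from oracles import kruskal_h_by_hand


class TestShapiroGate:
    def test_detects_skewed_distribution(self):
        rejections = 0
        for s in range(20):
            x = np.random.default_rng(s).uniform(size=50) ** 2
            out = shapiro_gate({"g": x})
            rejections += not out["groups"]["g"]["normal"]
        assert rejections >= 18

    def test_accepts_normal_samples(self):
        accepts = 0
        for s in range(20):
            x = np.random.default_rng(s).normal(size=50)
            out = shapiro_gate({"g": x})
            accepts += bool(out["groups"]["g"]["normal"])
        assert accepts >= 17

    def test_constant_sample_is_non_testable(self):
        out = shapiro_gate({"g": np.full(10, 2.0)})
        assert out["groups"]["g"]["testable"] is False
        assert out["branch"] == "nonparametric"

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            shapiro_gate({"g": [1.0, 2.0]})


class TestKruskalWallis:
    def test_identical_groups_have_zero_h(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3],
                              "c": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_bin == "small"
        # raw eta2 = (0 - 2)/(9 - 3) is reported unfloored
        assert res.effect_size == pytest.approx(-2 / 6)

    def test_matches_hand_computed_midrank_h(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = kruskal_wallis(groups)
        expected = kruskal_h_by_hand(list(groups.values()))
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_hand_oracle_with_ties(self, rng):
        groups = [rng.integers(0, 5, size=12).astype(float)
                  for _ in range(3)]
        res = kruskal_wallis({f"g{i}": g for i, g in enumerate(groups)})
        assert res.statistic == pytest.approx(kruskal_h_by_hand(groups),
                                              rel=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, size=10) for i in range(3)}
        before = kruskal_wallis(groups).statistic
        after = kruskal_wallis(
            {k: np.exp(v) for k, v in groups.items()}).statistic
        assert after == pytest.approx(before, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            kruskal_wallis({"a": [1.0], "b": []})


@pytest.mark.parametrize("eta2, label", [
    (0.0239, "small"), (0.0419, "small"), (0.0591, "small"),
    (0.0650, "moderate"), (0.139, "moderate"),
    (0.14, "large"), (0.404, "large"), (-0.05, "small"),
])
def test_eta_squared_cohen_bins(eta2, label):
    assert eta_squared_bin(eta2) == label


class TestPairwiseWilcoxon:
    def test_identical_paired_samples_degenerate(self):
        x = list(range(10))
        res = pairwise_wilcoxon({"on": x, "off": x},
                                paired=[("on", "off")])
        assert res[0].degenerate
        assert res[0].p_value == 1.0

    def test_uniform_improvement_matches_exact_distribution(self):
        # every ON < OFF for n = 15: one-sided exact p is 2^-15, so the
        # two-sided, Bonferroni-corrected value is m * 2^-14
        off = np.arange(1, 16, dtype=float)
        on = off - 0.1 * np.arange(1, 16)  # distinct |differences|
        res = pairwise_wilcoxon({"on": on.tolist(), "off": off.tolist()},
                                paired=[("on", "off")], m=3)
        assert res[0].test_name == "wilcoxon_signed_rank"
        assert res[0].p_value == pytest.approx(3 * 2.0**-14, rel=1e-9)

    def test_three_groups_bonferroni_m(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, 12).tolist() for i in range(3)}
        res = pairwise_wilcoxon(groups)
        assert len(res) == 3
        assert all(r.m_comparisons == 3 for r in res)
        assert all(r.p_value <= 1.0 for r in res)

    def test_unpaired_groups_use_rank_sum(self, rng):
        res = pairwise_wilcoxon({"cg": rng.normal(0, 1, 15).tolist(),
                                 "eg": rng.normal(1, 1, 12).tolist()})
        assert res[0].test_name == "wilcoxon_rank_sum"

    def test_mismatched_ids_rejected(self):
        with pytest.raises(PairingError):
            pairwise_wilcoxon(
                {"on": [1.0, 2.0], "off": [2.0, 3.0]},
                paired=[("on", "off")],
                ids={"on": ["p1", "p2"], "off": ["p1", "p3"]})

    def test_correction_never_lowers_p(self, rng):
        import scipy.stats

        a = rng.normal(0, 1, 10)
        b = rng.normal(0.3, 1, 10)
        res = pairwise_wilcoxon({"a": a, "b": b}, m=3)[0]
        raw = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")[1]
        assert res.p_value >= raw
        assert res.p_value <= 1.0


class TestSpearman:
    def test_monotone_pair_is_perfect(self):
        res = spearman([1, 2, 3, 4], [10, 20, 80, 90])
        assert res.rho == 1.0
        assert res.strength_bin == "very_strong"
        assert res.sign == "positive"

    @pytest.mark.parametrize("rho, expected_bin, sign", [
        (0.147, "very_weak", "positive"),
        (-0.698, "strong", "negative"),
        (0.217, "weak", "positive"),
        (-0.41, "moderate", "negative"),
    ])
    def test_strength_bins_match_printed_cut_points(self, rho, expected_bin,
                                                    sign):
        assert rho_strength_bin(rho) == expected_bin

    def test_equals_spearman_of_ranks(self, rng):
        import scipy.stats

        x = rng.normal(size=25)
        y = rng.normal(size=25)
        direct = spearman(x, y).rho
        ranked = spearman(scipy.stats.rankdata(x),
                          scipy.stats.rankdata(y)).rho
        assert direct == pytest.approx(ranked, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert res.strength_bin == "undefined"


class TestAnova:
    def test_published_ages_are_homogeneous(self):
        t1 = fixture_table1().drop_duplicates("participant_id")
        res = anova_oneway({
            "CG": t1[t1.cohort == "CG"].age_years.to_numpy(float),
            "EG": t1[t1.cohort == "EG"].age_years.to_numpy(float),
        })
        assert res.p_value > 0.05

    def test_identical_groups_zero_f(self):
        res = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_sums_of_squares(self):
        # groups with equal means, unequal variances
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.0, 2.0, 4.0])
        res = anova_oneway({"a": a, "b": b})
        grand = np.concatenate([a, b]).mean()
        ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_expected = (ss_between / 1) / (ss_within / 4)
        assert res.statistic == pytest.approx(f_expected, abs=1e-12)


class TestSlownessAnalysis:
    def test_battery_on_published_table(self):
        res = SlownessAnalysis(fixture_table2()).fit()
        assert set(res.omnibus) == {"rt_s", "av_dps"}
        assert res.omnibus["av_dps"].effect_size > 0
        assert len(res.pairwise["rt_s"]) == 3
        signed = [r for r in res.pairwise["rt_s"]
                  if r.test_name == "wilcoxon_signed_rank"]
        assert len(signed) == 1  # only ON vs OFF is matched
        corr = res.correlations["av_dps~brad_score[pooled]"]
        assert corr.n == 30
        assert corr.sign == "negative"
        assert "Kruskal-Wallis" in res.summary()

    def test_per_state_correlations(self):
        res = SlownessAnalysis(fixture_table2(), pool_states=False).fit()
        assert "av_dps~brad_score[ON]" in res.correlations
        assert "av_dps~brad_score[OFF]" in res.correlations

    def test_type_one_error_calibrated_under_null(self):
        """KW at alpha=.05 rejects ~5% of null replicates (3 x n=15)."""
        rejections = 0
        n_rep = 300
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            groups = {f"g{i}": rng.normal(size=15) for i in range(3)}
            rejections += kruskal_wallis(groups).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
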