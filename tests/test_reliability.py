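"""Statistical tests, kappa/PABAK, rater summaries, SD-vs-agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from cectfidelity.reliability import (
    bh_adjust,
    exact_binomial,
    pabak,
    rater_pair_reliability,
    rater_summary,
    sd_vs_agreement,
    two_proportion_z,
    weighted_kappa,
    wilcoxon_rank_sum,
)


class TestExactBinomial:
    def test_three_of_three_one_sided(self):
        assert exact_binomial(3, 3, 0.5, sided="greater").p_value == pytest.approx(0.125)

    def test_saturates_toward_one(self):
        assert exact_binomial(10, 10, 0.999, sided="greater").p_value == pytest.approx(
            1.0, abs=0.02
        )

    def test_center_two_sided_near_one(self):
        assert exact_binomial(74, 148, 0.5).p_value == pytest.approx(1.0, abs=0.07)

    def test_matches_pmf_summation(self):
        # minimum-likelihood two-sided p: sum pmf(i) over i with
        # pmf(i) <= pmf(k), computed independently from the PMF
        for k, n, p0 in [(3, 10, 0.5), (7, 12, 0.3), (0, 8, 0.6), (5, 5, 0.5)]:
            pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
            expected = pmf[pmf <= pmf[k] * (1 + 1e-10)].sum()
            assert exact_binomial(k, n, p0).p_value == pytest.approx(min(1.0, expected))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial(5, 3, 0.5)
        with pytest.raises(ValueError):
            exact_binomial(1, 3, 1.0)


class TestTwoProportionZ:
    def test_equal_proportions(self):
        res = two_proportion_z(50, 100, 50, 100)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_formula(self):
        # p=0.7, se=sqrt(0.21*0.02)
        res = two_proportion_z(80, 100, 60, 100)
        assert res.statistic == pytest.approx(0.2 / np.sqrt(0.21 * 0.02))
        assert res.statistic == pytest.approx(3.086, abs=0.001)

    def test_degenerate_pooled_flagged(self):
        res = two_proportion_z(0, 10, 0, 10)
        assert np.isnan(res.statistic)
        assert "degenerate" in res.note

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        z, p = proportions_ztest([80, 60], [100, 100])
        res = two_proportion_z(80, 100, 60, 100)
        assert res.statistic == pytest.approx(z)
        assert res.p_value == pytest.approx(p)


def _enumerate_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    n = len(pooled)
    sums = [sum(c) for c in itertools.combinations(ranks, len(x))]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= rx)
    p_ge = np.mean(sums >= rx)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_exact_small_sample_by_hand(self):
        # x=(1,2), y=(3,4): one-sided 1/6, two-sided 1/3
        res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.note == "exact"

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_tied_values(self):
        res = wilcoxon_rank_sum([5.0] * 4, [5.0] * 4)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 13 - nx))
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # distinct values
        x, y = pooled[:nx], pooled[nx:]
        res = wilcoxon_rank_sum(x, y)
        assert res.note == "exact"
        assert res.p_value == pytest.approx(_enumerate_ranksum_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_formula_on_random_families(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 40)))
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            expected[i] = running
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(9)
        p = rng.random(20)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        # order preservation: sorting by p sorts q
        np.testing.assert_allclose(np.argsort(q[np.argsort(p)]), np.arange(20))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestKappa:
    def test_perfect_agreement(self):
        r = weighted_kappa([1, 2, 3, 4, 5, 1], [1, 2, 3, 4, 5, 1], n_boot=0)
        assert r.value == 1.0

    def test_two_category_linear_equals_unweighted_cohen(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 2, 50)
            b = rng.integers(0, 2, 50)
            if len(set(zip(a, b))) < 2:
                continue
            ours = weighted_kappa(a, b, n_boot=0).value
            theirs = cohen_kappa_score(a, b)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_matches_sklearn_weighted_on_five_categories(self):
        rng = np.random.default_rng(8)
        a = rng.integers(1, 6, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 1, 5)
        for w in ("linear", "quadratic"):
            ours = weighted_kappa(a, b, weights=w, n_boot=0).value
            theirs = cohen_kappa_score(a, b, weights=w)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 6, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 1, 5)
        r1 = weighted_kappa(a, b, n_boot=200, seed=5)
        r2 = weighted_kappa(a, b, n_boot=200, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.value <= r1.ci_high

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([3, 3, 3], [3, 3, 3], n_boot=0)


class TestPabak:
    def test_perfect_agreement(self):
        assert pabak([1, 2, 1], [1, 2, 1], k_categories=2, n_boot=0).value == 1.0

    def test_formula_arithmetic(self):
        # Po = 0.75, k = 2 -> 0.5
        r = pabak([1, 1, 1, 0], [1, 1, 1, 1], k_categories=2, n_boot=0)
        assert r.value == pytest.approx(0.5)

    def test_chance_floor(self):
        # Po = 1/k -> PABAK = 0
        a = [1, 2, 3, 4]
        b = [1, 3, 2, 1]  # one agreement of four, k=4
        assert pabak(a, b, k_categories=4, n_boot=0).value == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_category_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 60)
        b = rng.integers(0, 2, 60)
        po = np.mean(a == b)
        assert pabak(a, b, k_categories=2, n_boot=0).value == pytest.approx(2 * po - 1)


class TestRaterSummary:
    def test_all_fives(self):
        df = pd.DataFrame(
            {"image_id": ["a", "b"], "phase": ["precontrast"] * 2,
             "rater": ["R1"] * 2, "score": [5, 5]}
        )
        s = rater_summary(df)
        assert s["mean_score"] == 5.0
        assert s["fraction_below_threshold"] == 0.0

    def test_arithmetic_with_threshold(self):
        df = pd.DataFrame(
            {"image_id": list("abc"), "phase": ["precontrast"] * 3,
             "rater": ["R1"] * 3, "score": [1, 3, 5]}
        )
        s = rater_summary(df)
        assert s["mean_score"] == pytest.approx(3.0)
        assert s["fraction_below_threshold"] == pytest.approx(1 / 3)

    def test_phase_strata_partition_pooled_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "image_id": [f"i{k}" for k in range(40)],
                "phase": ["precontrast", "corticomedullary"] * 20,
                "rater": ["R1"] * 40,
                "score": rng.integers(1, 6, 40),
            }
        )
        s = rater_summary(df)
        counts = df.groupby("phase")["score"].count()
        weighted = sum(s["per_phase_mean"][p] * counts[p] for p in counts.index)
        assert weighted / counts.sum() == pytest.approx(s["mean_score"])


class TestRaterPairReliability:
    def test_category_agreements_sum_to_total(self):
        rng = np.random.default_rng(6)
        a = rng.integers(1, 6, 100)
        b = rng.integers(1, 6, 100)
        r = rater_pair_reliability(a, b, n_boot=50)
        assert r.percent_agreement["total"] == pytest.approx(
            r.percent_agreement["0"] + r.percent_agreement["1"]
        )
        assert -1 <= r.weighted_kappa.value <= 1
        assert -1 <= r.pabak.value <= 1


class TestSdVsAgreement:
    @staticmethod
    def _tables(n, rng, features=("f1", "f2"), planted=None):
        idx = pd.MultiIndex.from_tuples(
            [(f"S{i}", "nephrographic") for i in range(n)], names=["study_id", "phase"]
        )
        hm = pd.DataFrame(index=idx)
        sd = rng.normal(30, 3, n)
        for f in features:
            agree = rng.random(n) > 0.3
            hm[f] = agree.astype(float)
            if planted == f:
                sd = np.where(agree, sd, sd * 2)  # disagreeing images noisier
        hm["fraction_agree"] = hm[list(features)].mean(axis=1)
        sd_table = pd.DataFrame(
            {"study_id": [t[0] for t in idx], "phase": [t[1] for t in idx], "sd": sd}
        )
        return sd_table, hm

    def test_no_disagreements_skips_all_features(self):
        idx = pd.MultiIndex.from_tuples(
            [("S0", "nephrographic"), ("S1", "nephrographic")],
            names=["study_id", "phase"],
        )
        hm = pd.DataFrame({"f1": [1.0, 1.0], "fraction_agree": [1.0, 1.0]}, index=idx)
        sd = pd.DataFrame({"study_id": ["S0", "S1"],
                           "phase": ["nephrographic"] * 2, "sd": [10.0, 12.0]})
        out = sd_vs_agreement(sd, hm, features=["f1"])
        assert out["per_feature"]["skipped"].all()

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(1)
        sd, hm = self._tables(200, rng, planted="f1")
        out = sd_vs_agreement(sd, hm)
        per = out["per_feature"].set_index("feature")
        assert per.loc["f1", "adjusted_p"] < 0.05

    def test_null_rarely_rejects(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            sd, hm = self._tables(100, rng)
            out = sd_vs_agreement(sd, hm)
            q = out["per_feature"]["adjusted_p"].dropna()
            hits += int((q < 0.05).any())
        assert hits <= 6  # ~family-wise 5% with slack over 40 replicates
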