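"""Agreement, correlation and intensity-profile concordance statistics."""

import numpy as np
import pandas as pd
import pytest

from cectfidelity.characterize import CATEGORICAL_FEATURES, QUANTITATIVE_FEATURES
from cectfidelity.concord import (
    agreement_heatmap_data,
    categorical_agreement,
    intensity_profiles,
    profile_diff_summary,
    quantitative_correlation,
)
from cectfidelity.core import PHASES


def _toy_tables(n_studies=4, flip=()):
    """Minimal paired feature tables; ``flip`` lists (study, phase, feature)."""
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n_studies):
        for p in PHASES:
            row = {"study_id": f"S{i}", "phase": p.value}
            for f in CATEGORICAL_FEATURES:
                row[f] = f"v{(i + len(f)) % 2}"
            for q in QUANTITATIVE_FEATURES:
                row[q] = float(rng.normal(50, 20))
            rows.append(row)
    gt = pd.DataFrame(rows)
    imp = gt.copy(deep=True)
    for study, phase, feature in flip:
        sel = (imp.study_id == study) & (imp.phase == phase)
        imp.loc[sel, feature] = "flipped"
    return gt, imp


class TestCategoricalAgreement:
    def test_identical_tables_agree_everywhere(self):
        gt, imp = _toy_tables()
        table = categorical_agreement(gt, imp)
        assert (table["agreement_fraction"].dropna() == 1.0).all()

    def test_fraction_arithmetic(self):
        # 141 of 148 pairs agreeing -> 0.9527...
        gt, imp = _toy_tables(n_studies=37)
        flips = [(f"S{i}", "excretory", "margin_shape") for i in range(7)]
        gt, imp = _toy_tables(n_studies=37, flip=flips)
        table = categorical_agreement(gt, imp)
        row = table[(table.feature == "margin_shape") & (table.stratum == "all")].iloc[0]
        assert row.n_pairs == 148
        assert row.n_agree == 141
        assert row.agreement_fraction == pytest.approx(141 / 148)

    def test_pooled_is_weighted_mean_of_phase_strata(self):
        flips = [("S0", "excretory", "necrosis"), ("S1", "precontrast", "necrosis")]
        gt, imp = _toy_tables(n_studies=5, flip=flips)
        table = categorical_agreement(gt, imp)
        t = table[table.feature == "necrosis"].set_index("stratum")
        phases = [p.value for p in PHASES]
        weighted = (t.loc[phases, "n_agree"].sum()) / (t.loc[phases, "n_pairs"].sum())
        assert t.loc["all", "agreement_fraction"] == pytest.approx(weighted)

    def test_all_missing_feature_reported_undefined(self):
        gt, imp = _toy_tables()
        gt["necrosis"] = None
        table = categorical_agreement(gt, imp)
        assert table[(table.feature == "necrosis")]["agreement_fraction"].isna().all()


class TestQuantitativeCorrelation:
    def test_identity_fit(self):
        res = quantitative_correlation([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_closed_form_scaling(self):
        res = quantitative_correlation([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(0.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_constant_vector_flagged_undefined(self):
        res = quantitative_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert not res["defined"]
        assert np.isnan(res["r_squared"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            quantitative_correlation([1.0, 2.0], [1.0, 2.0])

    def test_r_squared_affine_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(scale=0.5, size=30)
        r0 = quantitative_correlation(x, y)["r_squared"]
        r1 = quantitative_correlation(3.0 * x - 7.0, -0.5 * y + 11.0)["r_squared"]
        assert r1 == pytest.approx(r0)


class TestProfiles:
    def test_phantom_profile_matches_phase_curve(self, identity_features, identity_cohort):
        gt_df, imp_df, _ = identity_features
        profiles = intensity_profiles(gt_df, imp_df)
        pairs, truth = identity_cohort
        one = profiles[profiles.study_id == pairs[0]["study_id"]]
        roi = pairs[0]["gt"].tumor_roi
        for _, row in one.iterrows():
            expected = pairs[0]["gt"][row["phase"]].pixels[roi].mean()
            assert row["mean_hu_gt"] == pytest.approx(expected, abs=1e-9)

    def test_identical_profiles_give_zero_summaries(self):
        profiles = pd.DataFrame(
            {
                "study_id": ["A"] * 4,
                "phase": [p.value for p in PHASES],
                "mean_hu_gt": [30.0, 80.0, 110.0, 90.0],
                "mean_hu_imp": [30.0, 80.0, 110.0, 90.0],
            }
        )
        summary = profile_diff_summary(profiles)
        assert (summary["mean_signed_diff"].dropna() == 0).all()
        assert (summary["mean_magnitude_diff"].dropna() == 0).all()

    def test_signed_and_magnitude_arithmetic(self):
        profiles = pd.DataFrame(
            {
                "study_id": ["A", "B"],
                "phase": ["nephrographic"] * 2,
                "mean_hu_gt": [100.0, 100.0],
                "mean_hu_imp": [110.0, 90.0],
            }
        )
        pooled = profile_diff_summary(profiles).set_index("stratum").loc["all"]
        assert pooled["mean_signed_diff"] == 0.0
        assert pooled["mean_magnitude_diff"] == 10.0

    def test_signed_bounded_by_magnitude(self, identity_features):
        gt_df, imp_df, _ = identity_features
        summary = profile_diff_summary(intensity_profiles(gt_df, imp_df))
        ok = summary.dropna()
        assert (ok["mean_signed_diff"].abs() <= ok["mean_magnitude_diff"] + 1e-12).all()


class TestHeatmap:
    def test_identical_tables_all_true(self):
        gt, imp = _toy_tables()
        hm = agreement_heatmap_data(gt, imp)
        assert (hm[CATEGORICAL_FEATURES].to_numpy() == 1.0).all()

    def test_single_flip_single_false_cell(self):
        gt, imp = _toy_tables(flip=[("S1", "excretory", "composition")])
        hm = agreement_heatmap_data(gt, imp)
        vals = hm[CATEGORICAL_FEATURES].to_numpy()
        assert (vals == 0).sum() == 1
        assert hm.loc[("S1", "excretory"), "composition"] == 0.0

    def test_fraction_column_is_row_mean(self):
        gt, imp = _toy_tables(flip=[("S1", "excretory", "composition")])
        hm = agreement_heatmap_data(gt, imp)
        np.testing.assert_allclose(
            hm["fraction_agree"], hm[CATEGORICAL_FEATURES].mean(axis=1)
        )
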