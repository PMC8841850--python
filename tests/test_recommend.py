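"""Counterfactual therapy recommendation and McNemar benefit comparison."""

import numpy as np
import pandas as pd
import pytest

import radsurv as rs


def _toy_model(coefs):
    terms = [
        rs.PredictorTerm("main", "fA"),
        rs.PredictorTerm("interaction", "fB", "z1"),
        rs.PredictorTerm("interaction", "fC", "z2"),
    ]
    return rs.CoxModel(terms=terms, coefficients=coefs)


class TestRecommendTherapy:
    def test_positive_actionable_slope_recommends_therapy(self):
        model = _toy_model([0.5, 2.0, 1.0])
        rec = rs.recommend_therapy(model, {"fA": 1.0, "fB": 1.0, "fC": 1.0})
        # S = 2 + 1 > 0: no-therapy setting raises risk -> therapy
        assert rec.recommend_therapy == 1 and (rec.v1, rec.v2) == (0, 0)
        assert rec.y_at_1 - rec.y_at_0 == pytest.approx(3.0)

    def test_negative_actionable_slope_recommends_no_therapy(self):
        model = _toy_model([0.5, -2.0, 1.0])
        rec = rs.recommend_therapy(model, {"fA": 1.0, "fB": 2.0, "fC": 1.0})
        assert rec.recommend_therapy == 0 and (rec.v1, rec.v2) == (1, 1)

    def test_tie_abstains_from_therapy(self):
        model = _toy_model([0.5, 1.0, -1.0])
        rec = rs.recommend_therapy(model, {"fA": 3.0, "fB": 1.0, "fC": 1.0})
        assert rec.y_at_0 == rec.y_at_1
        assert rec.recommend_therapy == 0

    def test_published_fixture_case(self):
        model = rs.load_published_model()
        features = {
            "wavelet-HHH_glcm_Imc1": 123.0,  # main effect: cancels in the contrast
            "wavelet-HHL_firstorder_Skewness": 0.2,
            "original_glrlm_ShortRunHighGrayLevelEmphasis": 0.1,
            "wavelet-LHH_firstorder_Mean": 0.3,
            "wavelet-LHH_glcm_Imc1": 0.2,
        }
        rec = rs.recommend_therapy(model, features)
        s = -1.957 * 0.2 + 3.981 * 0.1 - 2.373 * 0.3 - 2.122 * 0.2
        assert rec.y_at_1 - rec.y_at_0 == pytest.approx(s, abs=1e-12)
        assert s < 0 and rec.recommend_therapy == 0

    def test_invariant_to_plain_main_effects(self, rng):
        model = _toy_model([rng.standard_normal(), 1.3, -0.4])
        a = rs.recommend_therapy(model, {"fA": -5.0, "fB": 1.0, "fC": 2.0})
        b = rs.recommend_therapy(model, {"fA": 9.0, "fB": 1.0, "fC": 2.0})
        assert a.recommend_therapy == b.recommend_therapy
        assert a.y_at_1 - a.y_at_0 == pytest.approx(b.y_at_1 - b.y_at_0)

    def test_augmented_main_effects_contribute_to_contrast(self):
        model = rs.CoxModel(
            terms=[rs.PredictorTerm("main", "fA"), rs.PredictorTerm("main", "z1")],
            coefficients=[1.0, -0.7],
        )
        rec = rs.recommend_therapy(model, {"fA": 0.3})
        assert rec.y_at_1 - rec.y_at_0 == pytest.approx(-0.7)
        assert rec.recommend_therapy == 0

    def test_model_without_actionable_terms_is_an_error(self):
        model = rs.CoxModel(terms=[rs.PredictorTerm("main", "fA")], coefficients=[1.0])
        with pytest.raises(ValueError, match="actionable"):
            rs.recommend_therapy(model, {"fA": 1.0})

    def test_recommendations_match_generating_interaction_sign(self):
        """When the fitted model recovers the generating signs, the
        per-case recommendation equals the sign rule on the actionable sum."""
        cfg = rs.SimConfig(n_cases=300, n_features=24, block_size=6, seed=77)
        feats, cohort, aug = rs.generate_cohort(cfg)
        terms = [
            rs.PredictorTerm("main", "feature_0000"),
            rs.PredictorTerm("interaction", "feature_0010", "z1"),
            rs.PredictorTerm("interaction", "feature_0020", "z2"),
        ]
        M = rs.term_design_matrix(terms, feats.transformed, aug)
        fit = rs.fit_cox(M, cohort.os_days, cohort.event, terms=terms)
        assert np.sign(fit.coefficients[1]) == -1 and np.sign(fit.coefficients[2]) == 1
        agree = 0
        for cid in feats.case_ids:
            rec = rs.recommend_therapy(fit, feats.transformed.loc[cid], case_id=cid)
            s = (
                fit.coefficients[1] * feats.transformed.loc[cid, "feature_0010"]
                + fit.coefficients[2] * feats.transformed.loc[cid, "feature_0020"]
            )
            agree += rec.recommend_therapy == int(s > 0)
        assert agree == feats.n_cases


class TestBenefitGroup:
    def test_filter_definition(self):
        frame = pd.DataFrame(
            {
                "os_days": [10.0, 20.0, 30.0, 40.0],
                "event": [1, 0, 1, 0],
                "adjuvant_therapy": [0, 0, 1, 1],
                "recurrence": pd.array([0, 1, 0, 1], dtype="Int64"),
            },
            index=["a", "b", "c", "d"],
        )
        benefit, excluded = rs.define_benefit_group(rs.CohortTable(frame=frame))
        assert benefit == ["a"] and excluded == []

    def test_missing_recurrence_excluded_and_reported(self):
        frame = pd.DataFrame(
            {
                "os_days": [10.0, 20.0, 30.0],
                "event": [1, 0, 1],
                "adjuvant_therapy": [0, 0, 0],
                "recurrence": pd.array([0, None, 0], dtype="Int64"),
            },
            index=["a", "b", "c"],
        )
        benefit, excluded = rs.define_benefit_group(rs.CohortTable(frame=frame))
        assert benefit == ["a", "c"] and excluded == ["b"]


class TestMcNemar:
    def _published_vectors(self):
        # 18 both-yes, 20 reference-yes/model-no, 2 reference-no/model-yes, 4 both-no
        model = np.r_[np.ones(18, int), np.zeros(20, int), np.ones(2, int), np.zeros(4, int)]
        ref = np.r_[np.ones(18, int), np.ones(20, int), np.zeros(2, int), np.zeros(4, int)]
        return model, ref

    def test_published_decision_table(self):
        model, ref = self._published_vectors()
        res = rs.mcnemar_compare(model, ref)
        assert res.mcnemar_chi2 == pytest.approx((18 - 1) ** 2 / 22, abs=1e-12)
        assert round(res.mcnemar_chi2, 3) == 13.136
        assert res.p == pytest.approx(0.0003, abs=5e-5)
        assert res.prop_no_reference == pytest.approx(6 / 44)
        assert res.prop_no_model == pytest.approx(24 / 44)
        assert res.table.tolist() == [[18, 20], [2, 4]]

    def test_balanced_discordance_without_clamping(self):
        model = np.r_[np.zeros(5, int), np.ones(5, int)]
        ref = np.r_[np.ones(5, int), np.zeros(5, int)]
        res = rs.mcnemar_compare(model, ref)
        assert res.mcnemar_chi2 == pytest.approx(0.1)  # (|5-5|-1)^2 / 10

    def test_statistic_symmetric_in_arms(self):
        model, ref = self._published_vectors()
        assert rs.mcnemar_compare(model, ref).mcnemar_chi2 == pytest.approx(
            rs.mcnemar_compare(ref, model).mcnemar_chi2
        )

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        model, ref = self._published_vectors()
        res = rs.mcnemar_compare(model, ref)
        table = [[18, 2], [20, 4]]  # model x reference orientation; b/c swap is symmetric
        ref_res = sm.mcnemar(table, exact=False, correction=True)
        assert res.mcnemar_chi2 == pytest.approx(float(ref_res.statistic))
        assert res.p == pytest.approx(float(ref_res.pvalue))

    def test_no_discordant_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="discordant"):
            rs.mcnemar_compare([1, 0, 1], [1, 0, 1])
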