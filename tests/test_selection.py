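"""Screening, candidate-set construction, and stepwise selection."""

import numpy as np
import pytest

import radsurv as rs


class TestSelectTopK:
    def test_boundary_tie_extends_selection(self, rng):
        # 851 distinct scores except ranks 199-203 share one value
        scores = np.sort(rng.random(851))[::-1].copy()
        scores[198:203] = scores[200]
        names = [f"f{i}" for i in range(851)]
        selected = rs.select_top_k(names, scores, k=200)
        assert len(selected) == 203

    def test_k_at_or_beyond_p_selects_everything(self, rng):
        scores = rng.integers(0, 3, size=10).astype(float)  # heavy ties
        names = list("abcdefghij")
        assert len(rs.select_top_k(names, scores, k=10)) == 10
        assert len(rs.select_top_k(names, scores, k=50)) == 10

    def test_selected_scores_dominate_unselected(self, rng):
        scores = rng.random(30)
        names = [f"f{i}" for i in range(30)]
        selected = set(rs.select_top_k(names, scores, k=7))
        smin = min(scores[names.index(n)] for n in selected)
        assert all(scores[i] <= smin for i, n in enumerate(names) if n not in selected)


class TestUnivariateScreen:
    def test_signal_features_rank_high(self):
        hits = 0
        for seed in range(25):
            cfg = rs.SimConfig(
                n_cases=200, n_features=60, block_size=10, seed=9000 + seed,
                true_effects=(
                    rs.TrueEffect(0, 1.0), rs.TrueEffect(10, -1.0), rs.TrueEffect(20, 1.0),
                ),
            )
            feats, cohort, _ = rs.generate_cohort(cfg)
            res = rs.univariate_screen(feats.transformed, cohort.os_days, cohort.event, k=10)
            hits += {"feature_0000", "feature_0010", "feature_0020"} <= set(res.selected)
        assert hits >= 23

    def test_c_indices_sorted_descending(self, small_cohort):
        feats, cohort, _ = small_cohort
        res = rs.univariate_screen(feats.transformed, cohort.os_days, cohort.event, k=5)
        cs = [c for _, c in res.ranked]
        assert cs == sorted(cs, reverse=True)
        assert res.k_effective >= res.k_requested


class TestCandidateSet:
    def test_counts_follow_3m_plus_2(self):
        names203 = [f"f{i}" for i in range(203)]
        assert len(rs.build_candidate_set(names203)) == 611
        assert len(rs.build_candidate_set(["only"])) == 5
        assert len(rs.build_candidate_set(names203, include_augmented=False)) == 609

    @pytest.mark.parametrize("m", [1, 2, 7, 50])
    def test_composition(self, m):
        terms = rs.build_candidate_set([f"f{i}" for i in range(m)])
        assert len(terms) == 3 * m + 2
        kinds = [(t.kind, t.augmented_factor) for t in terms]
        assert kinds.count(("main", "none")) == m + 2
        assert kinds.count(("interaction", "z1")) == m
        assert kinds.count(("interaction", "z2")) == m
        assert [t.feature_name for t in terms[-2:]] == ["z1", "z2"]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rs.build_candidate_set(["a", "a"])


class TestStepwise:
    def test_invalid_thresholds_rejected(self, small_cohort):
        feats, cohort, aug = small_cohort
        cands = rs.build_candidate_set(["feature_0000"])
        with pytest.raises(ValueError, match="p_entry"):
            rs.stepwise_select(cands, feats.transformed, aug,
                               cohort.os_days, cohort.event, p_entry=0.2, p_removal=0.1)

    def test_single_noise_candidate_enters_at_nominal_rate(self):
        """With one pure-noise candidate the per-step false-entry chance is
        the nominal 5%, so ~95% of seeds end with the empty model."""
        empty = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = rs.SimConfig(n_cases=100, n_features=4, block_size=2,
                               true_effects=(), seed=20_000 + seed)
            feats, cohort, aug = rs.generate_cohort(cfg)
            cands = [rs.PredictorTerm("main", "feature_0000")]
            model = rs.stepwise_select(cands, feats.transformed, aug,
                                       cohort.os_days, cohort.event)
            empty += model.k == 0
        assert 0.88 <= empty / n_seeds <= 1.0

    def test_multiple_noise_candidates_rarely_all_survive(self):
        """False entries accumulate roughly per candidate; with 5 noise
        mains the empty-model rate stays above the 0.95**5 first-step bound
        less sampling slack."""
        empty = 0
        for seed in range(50):
            cfg = rs.SimConfig(n_cases=100, n_features=10, block_size=5,
                               true_effects=(), seed=30_000 + seed)
            feats, cohort, aug = rs.generate_cohort(cfg)
            cands = [rs.PredictorTerm("main", f"feature_{i:04d}") for i in range(5)]
            model = rs.stepwise_select(cands, feats.transformed, aug,
                                       cohort.os_days, cohort.event)
            empty += model.k == 0
        assert empty / 50 >= 0.6

    def test_dominant_term_always_found(self):
        hits = 0
        for seed in range(25):
            cfg = rs.SimConfig(n_cases=400, n_features=20, block_size=5,
                               true_effects=(rs.TrueEffect(0, 1.5),), seed=40_000 + seed)
            feats, cohort, aug = rs.generate_cohort(cfg)
            cands = rs.build_candidate_set([f"feature_{i:04d}" for i in range(20)])
            model = rs.stepwise_select(cands, feats.transformed, aug,
                                       cohort.os_days, cohort.event)
            hits += any(
                t.kind == "main" and t.feature_name == "feature_0000" for t in model.terms
            )
        assert hits >= 24

    def test_selected_model_not_worse_than_true_terms(self, small_cohort):
        feats, cohort, aug = small_cohort
        truth = [
            rs.PredictorTerm("main", "feature_0000"),
            rs.PredictorTerm("interaction", "feature_0010", "z1"),
            rs.PredictorTerm("interaction", "feature_0020", "z2"),
        ]
        cands = rs.build_candidate_set([f"feature_{i:04d}" for i in range(20)])
        model = rs.stepwise_select(cands, feats.transformed, aug,
                                   cohort.os_days, cohort.event)
        M = rs.term_design_matrix(truth, feats.transformed, aug)
        true_fit = rs.fit_cox(M, cohort.os_days, cohort.event)
        if model.k >= len(truth) and all(t in model.terms for t in truth):
            assert (
                model.log_partial_likelihood
                >= true_fit.log_partial_likelihood - 1e-6
            )

    def test_candidate_order_does_not_matter_without_ties(self, small_cohort):
        feats, cohort, aug = small_cohort
        names = [f"feature_{i:04d}" for i in range(10)]
        cands = rs.build_candidate_set(names)
        rng = np.random.default_rng(3)
        shuffled = [cands[i] for i in rng.permutation(len(cands))]
        a = rs.stepwise_select(cands, feats.transformed, aug,
                               cohort.os_days, cohort.event)
        b = rs.stepwise_select(shuffled, feats.transformed, aug,
                               cohort.os_days, cohort.event)
        assert set(a.terms) == set(b.terms)
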