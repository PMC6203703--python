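import numpy as np
import pytest

from climrefugia.niche_model import (
    BETA_GRID,
    CandidateSet,
    aicc,
    build_features,
    compute_vif,
    enumerate_candidate_sets,
    fit_maxent,
    predict_logistic,
    predict_raw,
    select_variables,
    tune_beta_multiplier,
)


def gibbs_sample(rng, bg_feat, lam, m):
    """Presence rows drawn from the background with probability ∝ exp(λ·f)
    — the model's own data-generating process (simulation oracle)."""
    w = np.exp(bg_feat @ lam)
    w = w / w.sum()
    idx = rng.choice(bg_feat.shape[0], size=m, replace=True, p=w)
    return bg_feat[idx]


class TestFeatures:
    def test_linear_feature_midpoint(self):
        bg = np.array([[0.0], [10.0]])
        spec, _, pres = build_features(["v"], bg, np.array([[5.0]]))
        assert pres[0, 0] == pytest.approx(0.5)

    def test_projection_clamps_to_background_bounds(self):
        bg = np.array([[0.0], [10.0]])
        spec, _, _ = build_features(["v"], bg)
        feats = spec.featurize(np.array([[20.0]]))
        assert feats[0, 0] == pytest.approx(1.0)
        assert feats[0, 1] == pytest.approx(1.0)

    def test_quadratic_feature_of_negative_value(self):
        # background v in [-3, 3] -> v^2 in [0, 9]; v = -3 maps to 1.0
        bg = np.array([[-3.0], [0.0], [3.0]])
        spec, _, pres = build_features(["v"], bg, np.array([[-3.0]]))
        assert pres[0, 1] == pytest.approx(1.0)

    def test_constant_variable_rejected_by_name(self):
        bg = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="flat"):
            build_features(["flat", "ok"], bg)


class TestFitMaxent:
    def test_matched_means_give_zero_lambdas(self, rng):
        bg = rng.uniform(size=(500, 3))
        # presences = a reshuffle of background rows: identical means
        model = fit_maxent(bg[rng.permutation(500)], bg, beta_multiplier=0.0)
        raw = predict_raw(model, bg)
        assert np.allclose(raw, 1 / 500, atol=1e-6)

    def test_exact_constraint_matching_unpenalized(self, rng):
        bg = rng.uniform(size=(2000, 2))
        pres = gibbs_sample(rng, bg, np.array([1.0, -0.5]), 200)
        model = fit_maxent(pres, bg, beta_multiplier=0.0)
        q = predict_raw(model, bg)
        e_model = q @ bg
        np.testing.assert_allclose(e_model, pres.mean(axis=0), atol=1e-6)

    def test_parameter_recovery_from_known_coefficients(self, rng):
        lam_true = np.array([1.5, -0.8])
        bg = rng.uniform(size=(10_000, 2))
        pres = gibbs_sample(rng, bg, lam_true, 1000)
        model = fit_maxent(pres, bg, beta_multiplier=0.0)
        np.testing.assert_allclose(model.lambdas, lam_true, atol=0.2)

    def test_kkt_holds_with_penalty(self, rng):
        bg = rng.uniform(size=(2000, 2))
        pres = gibbs_sample(rng, bg, np.array([2.0, -1.0]), 60)
        model = fit_maxent(pres, bg, beta_multiplier=1.0)
        q = predict_raw(model, bg)
        gap = np.abs(q @ bg - pres.mean(axis=0))
        assert np.all(gap <= model.beta_j + 1e-5)
        active = np.abs(model.lambdas) > 1e-8
        np.testing.assert_allclose(
            gap[active], model.beta_j[active], atol=1e-4
        )

    def test_concavity_two_starts_same_optimum(self, rng):
        bg = rng.uniform(size=(1000, 3))
        pres = gibbs_sample(rng, bg, np.array([1.0, 0.5, -1.5]), 80)
        m1 = fit_maxent(pres, bg, beta_multiplier=0.5)
        m2 = fit_maxent(pres, bg, beta_multiplier=0.5, x0=np.array([3.0, -3.0, 3.0]))
        def objective(m):
            lnl = np.mean(pres @ m.lambdas) - m.log_z
            return lnl - m.beta_j @ np.abs(m.lambdas)
        assert objective(m1) == pytest.approx(objective(m2), abs=1e-7)

    def test_shrinkage_monotone_over_beta_grid(self, rng):
        bg = rng.uniform(size=(1000, 2))
        pres = gibbs_sample(rng, bg, np.array([2.0, -1.2]), 40)
        norms = []
        for beta in BETA_GRID:
            m = fit_maxent(pres, bg, beta_multiplier=float(beta))
            norms.append(np.sum(np.abs(m.lambdas)))
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(np.array([[np.nan]]), np.array([[0.0], [1.0]]))


class TestPredict:
    def test_raw_sums_to_one_over_training_background(self, rng):
        bg = rng.uniform(size=(800, 2))
        pres = gibbs_sample(rng, bg, np.array([1.0, 1.0]), 50)
        model = fit_maxent(pres, bg, beta_multiplier=0.5)
        assert predict_raw(model, bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_raw_renormalizes_on_projection(self, rng):
        bg = rng.uniform(size=(800, 2))
        pres = gibbs_sample(rng, bg, np.array([1.0, -1.0]), 50)
        model = fit_maxent(pres, bg, beta_multiplier=0.0)
        proj = rng.uniform(size=(300, 2))
        assert predict_raw(model, proj, renormalize=True).sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_uniform_model_logistic_is_half(self, rng):
        bg = rng.uniform(size=(400, 2))
        model = fit_maxent(bg.copy(), bg, beta_multiplier=0.0)
        assert np.allclose(predict_logistic(model, bg), 0.5, atol=1e-6)

    def test_logistic_monotone_in_raw(self, rng):
        bg = rng.uniform(size=(500, 2))
        pres = gibbs_sample(rng, bg, np.array([2.0, -1.0]), 60)
        model = fit_maxent(pres, bg, beta_multiplier=0.5)
        raw = predict_raw(model, bg)
        logi = predict_logistic(model, bg)
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(logi))


class TestAicc:
    def _model_with(self, lambdas, log_z=0.0, rng=None):
        from climrefugia.niche_model import FeatureSpec, MaxentModel

        k = len(lambdas)
        spec = FeatureSpec(
            variables=[f"v{i}" for i in range(k)],
            v_min=np.zeros(k), v_max=np.ones(k),
            v2_min=np.zeros(k), v2_max=np.ones(k),
        )
        return MaxentModel(
            features=spec, lambdas=np.array(lambdas, float),
            beta_multiplier=0.0, beta_j=np.zeros(k),
            log_z=log_z, entropy=1.0, n_presence=10,
        )

    def test_formula_arithmetic(self):
        # K = 2, n = 10, lnL = -20 -> 44 + 12/7
        model = self._model_with([1.0, 1.0], log_z=2.0)
        pres = np.full((10, 2), 0.0)
        # lnL = sum(lam.f - lnZ) = 10 * (0 - 2) = -20
        assert aicc(model, pres) == pytest.approx(44 + 12 / 7)

    def test_inadmissible_when_n_too_small(self):
        model = self._model_with([1.0, 1.0, 1.0, 1.0])
        pres = np.zeros((5, 4))
        assert aicc(model, pres) == np.inf

    def test_zero_coefficient_features_do_not_count(self):
        m1 = self._model_with([1.0, 0.5], log_z=1.0)
        m2 = self._model_with([1.0, 0.5, 0.0], log_z=1.0)
        p1 = np.tile([0.2, 0.4], (20, 1))
        p2 = np.tile([0.2, 0.4, 0.9], (20, 1))
        assert aicc(m1, p1) == pytest.approx(aicc(m2, p2))


class TestVif:
    def test_uncorrelated_pair_near_one(self, rng):
        x = rng.standard_normal((5000, 2))
        np.testing.assert_allclose(compute_vif(x), [1.0, 1.0], atol=0.05)

    def test_perfect_collinearity_infinite(self):
        x1 = np.arange(10.0)
        x = np.column_stack([x1, 2 * x1])
        assert np.all(np.isinf(compute_vif(x)))

    def test_equicorrelated_triple_closed_form(self, rng):
        # pairwise r = 0.5 -> R^2 = 1/3 -> VIF = 1.5
        cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        x = rng.multivariate_normal(np.zeros(3), cov, size=60_000)
        np.testing.assert_allclose(compute_vif(x), 1.5, atol=0.05)

    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.standard_normal((300, 3))
        x[:, 2] += 0.8 * x[:, 0]
        ours = compute_vif(x)
        for j in range(3):
            others = sm.add_constant(np.delete(x, j, axis=1))
            r2 = sm.OLS(x[:, j], others).fit().rsquared
            assert ours[j] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compute_vif(np.ones((2, 3)))


class TestCandidateEnumeration:
    def _sample(self, rng, corr):
        return rng.multivariate_normal(np.zeros(corr.shape[0]), corr, size=4000)

    def test_correlated_pair_excluded(self, rng):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.9
        x = self._sample(rng, corr)
        cands = enumerate_candidate_sets(x, ["a", "b", "c"])
        subsets = {c.subset for c in cands}
        assert subsets == {("a", "c"), ("b", "c")}

    def test_all_correlated_gives_empty(self, rng):
        corr = np.full((3, 3), 0.95) + 0.05 * np.eye(3)
        x = self._sample(rng, corr)
        assert enumerate_candidate_sets(x, ["a", "b", "c"]) == []

    def test_orthogonal_variables_all_subsets_vif_one(self, rng):
        x = rng.standard_normal((5000, 3))
        cands = enumerate_candidate_sets(x, ["a", "b", "c"])
        assert len(cands) == 4  # 3 pairs + 1 triple
        assert all(c.max_vif < 1.1 for c in cands)

    def test_cap_raises(self, rng):
        x = rng.standard_normal((500, 8))
        with pytest.raises(Exception, match="cap|candidate"):
            enumerate_candidate_sets(x, [f"v{i}" for i in range(8)],
                                     max_candidates=5)


class TestSelection:
    def test_single_candidate_returned(self, rng):
        bg = rng.standard_normal((1000, 2))
        pres = bg[rng.choice(1000, 50)]
        cand = CandidateSet(subset=("a", "b"), max_abs_pairwise_r=0.0, max_vif=1.0)
        best = select_variables([cand], pres, bg, ["a", "b"])
        assert best.subset == ("a", "b")

    def test_true_variables_beat_noise(self, rng):
        bg = rng.standard_normal((3000, 4))
        # species responds to variables 0,1 only
        eta = 1.5 * bg[:, 0] - 1.0 * bg[:, 1]
        w = np.exp(eta - eta.max()); w /= w.sum()
        pres = bg[rng.choice(3000, 500, p=w)]
        names = ["true1", "true2", "noise1", "noise2"]
        cands = [
            CandidateSet(("noise1", "noise2"), 0.0, 1.0),
            CandidateSet(("true1", "true2"), 0.0, 1.0),
        ]
        best = select_variables(cands, pres, bg, names)
        assert best.subset == ("true1", "true2")

    def test_duplicate_candidates_deterministic(self, rng):
        bg = rng.standard_normal((800, 2))
        pres = bg[rng.choice(800, 40)]
        cands = [
            CandidateSet(("a", "b"), 0.0, 1.0),
            CandidateSet(("a", "b"), 0.0, 1.0),
        ]
        best = select_variables(cands, pres, bg, ["a", "b"])
        assert best.subset == ("a", "b")


class TestBetaTuning:
    def test_grid_has_31_values(self):
        assert len(BETA_GRID) == 31
        assert BETA_GRID[0] == 0.0 and BETA_GRID[-1] == 15.0
        assert np.allclose(np.diff(BETA_GRID), 0.5)

    def test_large_sample_prefers_small_beta(self, rng):
        bg = rng.standard_normal((4000, 2))
        eta = 1.2 * bg[:, 0] - 0.9 * bg[:, 1]
        w = np.exp(eta - eta.max()); w /= w.sum()
        pres = bg[rng.choice(4000, 800, p=w)]
        beta, model = tune_beta_multiplier(
            ("a", "b"), pres, bg, ["a", "b"]
        )
        assert beta <= 1.0
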