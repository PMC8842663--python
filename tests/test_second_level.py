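"""Moderation regression and cross-analysis profile comparison."""

import numpy as np
import pytest
import scipy.stats

import statedyn as sd


def _z(v):
    return (v - v.mean()) / v.std(ddof=1)


class TestModeration:
    def test_residual_df_at_cohort_scale(self, rng):
        n = 564  # three predictors + intercept -> df = 560
        res = sd.moderation_fit(
            rng.normal(size=n), rng.normal(size=n), rng.uniform(18, 88, n)
        )
        assert res.df_resid == 560
        assert res.n == n

    def test_noise_free_outcome_recovered_exactly(self, rng):
        n = 300
        brain = rng.normal(size=n)
        age = rng.uniform(18, 88, n)
        zb, za = _z(brain), _z(age)
        inter = _z(zb * za)
        coef = np.array([0.3, -0.25, 0.15])
        outcome = coef[0] * zb + coef[1] * za + coef[2] * inter
        res = sd.moderation_fit(outcome, brain, age)
        # the outcome is z-scored inside, so betas are coef / sd(outcome)
        expected = coef / outcome.std(ddof=1)
        assert np.allclose(res.beta, expected, atol=1e-8)

    def test_t_equals_beta_over_se(self, rng):
        res = sd.moderation_fit(
            rng.normal(size=100), rng.normal(size=100), rng.uniform(18, 88, 100)
        )
        assert np.allclose(res.t, res.beta / res.se, atol=1e-10)
        # two-sided p from the t distribution with df_resid
        assert np.allclose(
            res.p, 2 * scipy.stats.t.sf(np.abs(res.t), res.df_resid), atol=1e-12
        )

    def test_covariates_enter_standardized(self, rng):
        n = 200
        res = sd.moderation_fit(
            rng.normal(size=n), rng.normal(size=n), rng.uniform(18, 88, n),
            covariates={"sex": rng.integers(0, 2, n).astype(float)},
        )
        assert res.names == ["brain", "age", "brain_x_age", "sex"]
        assert res.df_resid == n - 5

    def test_rank_deficient_design_names_column(self, rng):
        n = 100
        brain = rng.normal(size=n)
        with pytest.raises(ValueError, match="collinear"):
            sd.moderation_fit(
                rng.normal(size=n), brain, rng.uniform(18, 88, n),
                covariates={"brain_copy": brain.copy()},
            )

    def test_product_then_z_alternative(self, rng):
        n = 150
        out = rng.normal(size=n)
        brain = rng.normal(size=n)
        age = rng.uniform(18, 88, n)
        a = sd.moderation_fit(out, brain, age, interaction="z_then_product")
        b = sd.moderation_fit(out, brain, age, interaction="product_then_z")
        assert not np.allclose(a.beta[2], b.beta[2])  # genuinely different conventions

    def test_negative_age_slope_recovered_directionally(self):
        hits = 0
        for seed in range(5):
            cfg = sd.test_scenario(
                n_subjects=300, samples_per_subject=120, seed=seed, age_slope=-0.015
            )
            _, _, truth = sd.simulate_cohort(cfg, emit=False)
            res = sd.moderation_fit(truth.latent_sleep, truth.latent_brain, truth.ages)
            hits += res.beta[1] < 0
        assert hits == 5


class TestCompareProfiles:
    def _result(self, loadings, scores, perm_p=None, x_names=None, subject_ids=None):
        r = loadings.shape[1]
        return sd.PLSResult(
            saliences_X=np.eye(loadings.shape[0], r),
            saliences_Y=np.eye(3, r),
            singular_values=np.linspace(1.0, 0.5, r),
            scores_X=scores, scores_Y=scores,
            structure_loadings_X=loadings, structure_loadings_Y=np.zeros((3, r)),
            perm_p=perm_p, x_names=x_names, subject_ids=subject_ids,
        )

    def test_self_comparison_is_unity(self, rng):
        L = rng.normal(size=(12, 2))
        S = rng.normal(size=(30, 2))
        res = self._result(L, S)
        cmp = sd.compare_profiles(res, res, component=(0, 0))
        assert cmp.r_loadings_overall == pytest.approx(1.0)
        assert cmp.r_scores == pytest.approx(1.0)
        assert not cmp.flipped_b

    def test_orthogonal_loadings_give_zero(self):
        # centered vectors with exactly zero correlation
        a = np.array([1.0, -1.0, 1.0, -1.0])[:, None]
        b = np.array([1.0, 1.0, -1.0, -1.0])[:, None]
        s = np.random.default_rng(0).normal(size=(10, 1))
        cmp = sd.compare_profiles(
            self._result(a, s), self._result(b, s), component=(0, 0)
        )
        assert abs(cmp.r_loadings_overall) < 1e-10

    def test_matches_textbook_pearson_on_toy_vectors(self):
        la = np.array([0.1, 0.5, -0.2, 0.8, 0.0, -0.4])[:, None]
        lb = np.array([0.2, 0.4, -0.1, 0.9, 0.1, -0.5])[:, None]
        s = np.random.default_rng(1).normal(size=(8, 1))
        cmp = sd.compare_profiles(self._result(la, s), self._result(lb, s), component=(0, 0))
        r_ref = scipy.stats.pearsonr(la[:, 0], lb[:, 0])[0]
        assert cmp.r_loadings_overall == pytest.approx(r_ref, abs=1e-12)

    def test_sign_alignment_recorded_and_applied(self, rng):
        L = rng.normal(size=(10, 1))
        S = rng.normal(size=(20, 1))
        cmp = sd.compare_profiles(
            self._result(L, S), self._result(-L, -S), component=(0, 0)
        )
        assert cmp.flipped_b
        assert cmp.r_loadings_overall == pytest.approx(1.0)
        assert cmp.r_scores == pytest.approx(1.0)

    def test_group_correlations_use_named_columns(self, rng):
        names = [f"{m}_state{k}" for m in ("FO", "MLT", "NO", "MIL") for k in (1, 2)]
        L = rng.normal(size=(8, 1))
        L2 = L + 0.1 * rng.normal(size=(8, 1))
        S = rng.normal(size=(15, 1))
        groups = sd.state_groups(2)
        cmp = sd.compare_profiles(
            self._result(L, S, x_names=names), self._result(L2, S, x_names=names),
            groups=groups, component=(0, 0),
        )
        assert set(cmp.r_loadings_per_group) == {"state1", "state2"}
        idx = [names.index(c) for c in groups["state1"]]
        r_ref = scipy.stats.pearsonr(L[idx, 0], L2[idx, 0])[0]
        assert cmp.r_loadings_per_group["state1"] == pytest.approx(r_ref, abs=1e-12)

    def test_disjoint_subjects_rejected(self, rng):
        L = rng.normal(size=(6, 1))
        S = rng.normal(size=(5, 1))
        a = self._result(L, S, subject_ids=[f"a{i}" for i in range(5)])
        b = self._result(L, S, subject_ids=[f"b{i}" for i in range(5)])
        with pytest.raises(ValueError, match="disjoint"):
            sd.compare_profiles(a, b, component=(0, 0))

    def test_per_group_r_does_not_average_to_overall(self):
        """Constructed counter-example: each group is perfectly correlated,
        yet the overall correlation differs from any group-weighted average
        because the group means differ between analyses."""
        la = np.array([0.0, 1.0, 10.0, 11.0])[:, None] / 11.0
        lb = np.array([10.0, 11.0, 0.0, 1.0])[:, None] / 11.0
        names = ["FO_state1", "MLT_state1", "FO_state2", "MLT_state2"]
        s = np.random.default_rng(2).normal(size=(10, 1))
        cmp = sd.compare_profiles(
            self._result(la, s, x_names=names), self._result(lb, s, x_names=names),
            groups={"g1": names[:2], "g2": names[2:]}, component=(0, 0),
        )
        group_mean = np.mean(list(cmp.r_loadings_per_group.values()))
        assert abs(cmp.r_loadings_overall - group_mean) > 0.5
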