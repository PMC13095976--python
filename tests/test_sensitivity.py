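"""Robust first-level fits, second-level symptom regressions, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest

from effortlab.sensitivity import (RankDeficiencyError,
                                   actual_force_sensitivity,
                                   benjamini_hochberg,
                                   fit_cohort_sensitivities,
                                   fit_group_regression,
                                   fit_participant_robust,
                                   intercept_symptom_analysis)


def _participant_frame(intercept=10.0, force_slope=60.0, failure_slope=8.0,
                       hand_coef=0.0, noise=None, seed=0, n=24):
    rng = np.random.default_rng(seed)
    force = np.tile([0.2, 0.4, 0.6, 0.8], n // 4)
    failure = (np.arange(n) % 3 == 0).astype(float)
    hand = np.arange(n) % 2
    rating = (intercept + force_slope * force ** 2 + failure_slope * failure
              + hand_coef * hand)
    if noise is not None:
        rating = rating + noise
    return pd.DataFrame({
        "participant_id": "P1", "target_force_sq": force ** 2,
        "failure": failure, "hand_code": hand, "rating": rating,
    })


class TestParticipantRobust:
    def test_noise_free_coefficients_recovered_exactly(self):
        est = fit_participant_robust(_participant_frame(
            intercept=10.0, force_slope=60.0, failure_slope=8.0,
            hand_coef=1.5))
        assert est.intercept == pytest.approx(10.0, abs=1e-6)
        assert est.force_slope == pytest.approx(60.0, abs=1e-6)
        assert est.failure_slope == pytest.approx(8.0, abs=1e-6)
        assert est.hand_coefficient == pytest.approx(1.5, abs=1e-6)

    def test_huber_beats_ols_under_gross_outlier(self):
        """One wild rating: the Huber slope stays closer to truth than the
        ordinary least-squares oracle's."""
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 2.0, 24)
        frame = _participant_frame(noise=noise)
        frame.loc[5, "rating"] += 80.0  # gross outlier
        est = fit_participant_robust(frame)
        X = np.column_stack([np.ones(len(frame)),
                             frame["target_force_sq"], frame["failure"],
                             frame["hand_code"]])
        ols = np.linalg.lstsq(X, frame["rating"].to_numpy(), rcond=None)[0]
        assert abs(est.force_slope - 60.0) < abs(ols[1] - 60.0)

    def test_huber_with_huge_tuning_constant_matches_ols(self):
        rng = np.random.default_rng(4)
        frame = _participant_frame(noise=rng.normal(0, 5.0, 24))
        est = fit_participant_robust(frame, huber_t=1e6)
        X = np.column_stack([np.ones(len(frame)),
                             frame["target_force_sq"], frame["failure"],
                             frame["hand_code"]])
        ols = np.linalg.lstsq(X, frame["rating"].to_numpy(), rcond=None)[0]
        assert est.intercept == pytest.approx(ols[0], abs=1e-8)
        assert est.force_slope == pytest.approx(ols[1], abs=1e-8)
        assert est.failure_slope == pytest.approx(ols[2], abs=1e-8)

    def test_single_class_outcome_raises_rank_deficiency(self):
        frame = _participant_frame()
        frame["failure"] = 0.0
        with pytest.raises(RankDeficiencyError):
            fit_participant_robust(frame)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_participant_robust(_participant_frame(n=4))


@pytest.fixture(scope="module")
def cohort_estimates():
    """Synthetic second-level data with known standardised couplings."""
    rng = np.random.default_rng(7)
    n = 500
    latent = rng.standard_normal(n)
    phq9 = np.clip(np.round(6.4 + 4.0 * latent), 0, 27)
    estimates = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "intercept": 10 + rng.normal(0, 2, n),
        "force_slope": 60 + 15 * (-0.5 * latent
                                  + np.sqrt(0.75) * rng.standard_normal(n)),
        "failure_slope": 5 + 8 * (0.5 * latent
                                  + np.sqrt(0.75) * rng.standard_normal(n)),
    })
    participants = pd.DataFrame({
        "id": estimates["participant_id"],
        "phq9": phq9, "aes": np.clip(np.round(
            31 + 7 * rng.standard_normal(n)), 18, 72),
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(28, 5, n),
        "mvc_dom": np.exp(rng.normal(5.7, 0.2, n)),
    })
    participants["mvc_nondom"] = participants["mvc_dom"] / np.exp(
        rng.normal(0.07, 0.09, n))
    return estimates, participants


class TestGroupRegression:
    def test_known_couplings_recovered(self, cohort_estimates):
        estimates, participants = cohort_estimates
        res = fit_group_regression(estimates, participants)
        force_b = res.coefficients.loc[("force_slope", "phq9"),
                                       "coefficient"]
        fail_b = res.coefficients.loc[("failure_slope", "phq9"),
                                      "coefficient"]
        assert force_b == pytest.approx(-0.5, abs=0.15)
        assert fail_b == pytest.approx(0.5, abs=0.15)

    def test_fdr_family_is_the_four_symptom_tests(self, cohort_estimates):
        res = fit_group_regression(*cohort_estimates)
        assert len(res.fdr) == 4
        assert np.all(res.fdr["q_value"].to_numpy()
                      >= res.fdr["p_value"].to_numpy() - 1e-12)

    def test_duplicating_participants_preserves_coefficients(
            self, cohort_estimates):
        estimates, participants = cohort_estimates
        res1 = fit_group_regression(estimates, participants)
        doubled_est = pd.concat([
            estimates,
            estimates.assign(participant_id=estimates["participant_id"]
                             + "_b")], ignore_index=True)
        doubled_part = pd.concat([
            participants,
            participants.assign(id=participants["id"] + "_b")],
            ignore_index=True)
        res2 = fit_group_regression(doubled_est, doubled_part)
        np.testing.assert_allclose(res1.coefficients["coefficient"],
                                   res2.coefficients["coefficient"],
                                   atol=1e-10)
        assert np.all(res2.fdr["p_value"].to_numpy()
                      <= res1.fdr["p_value"].to_numpy() + 1e-12)

    def test_affine_rescaling_of_covariates_is_equivariant(
            self, cohort_estimates):
        """z-scoring makes the standardised coefficients invariant to
        affine rescaling of raw covariates."""
        estimates, participants = cohort_estimates
        res1 = fit_group_regression(estimates, participants)
        rescaled = participants.copy()
        rescaled["age"] = rescaled["age"] * 12 + 3      # years -> months
        rescaled["phq9"] = rescaled["phq9"] * 2.0
        res2 = fit_group_regression(estimates, rescaled)
        np.testing.assert_allclose(res1.coefficients["coefficient"],
                                   res2.coefficients["coefficient"],
                                   atol=1e-10)

    def test_constant_covariate_named_in_error(self, cohort_estimates):
        estimates, participants = cohort_estimates
        broken = participants.copy()
        broken["age"] = 30.0
        with pytest.raises(ValueError, match="age"):
            fit_group_regression(estimates, broken)


class TestBenjaminiHochberg:
    @staticmethod
    def _brute_force(p):
        """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            q[order[i]] = min(min(m * sorted_p[j] / (j + 1)
                                  for j in range(i, m)), 1.0)
        return q

    def test_matches_brute_force_on_all_subsets_of_four(self):
        pool = [0.001, 0.01, 0.02, 0.03, 0.04, 0.049, 0.2, 0.5, 0.9, 1.0]
        for combo in itertools.combinations(pool, 4):
            np.testing.assert_allclose(benjamini_hochberg(list(combo)),
                                       self._brute_force(combo),
                                       atol=1e-12)

    def test_uniform_ladder_collapses_to_largest(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(benjamini_hochberg([1.0] * 4), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestInterceptAnalysis:
    def test_positive_intercept_coupling_gives_positive_r(
            self, feature_matrices, preprocessed):
        retained, _ = preprocessed
        res = intercept_symptom_analysis(feature_matrices,
                                         retained.participants)
        truth = retained.participants
        expected_sign = np.sign(np.corrcoef(
            truth["phq9"], truth["sim_rating_intercept"])[0, 1])
        assert np.sign(res["r"]) == expected_sign

    def test_cap_at_100_is_identity(self, feature_matrices, preprocessed):
        retained, _ = preprocessed
        full = intercept_symptom_analysis(feature_matrices,
                                          retained.participants)
        capped = intercept_symptom_analysis(feature_matrices,
                                            retained.participants,
                                            rating_cap=100.0)
        assert capped["r"] == pytest.approx(full["r"])

    def test_invalid_cap_rejected(self, feature_matrices, preprocessed):
        retained, _ = preprocessed
        with pytest.raises(ValueError):
            intercept_symptom_analysis(feature_matrices,
                                       retained.participants,
                                       rating_cap=0.0)


class TestActualForceSensitivity:
    def test_auc_based_slopes_track_target_based_slopes(
            self, feature_matrices):
        """Exerted force tracks target force in the simulator, so the two
        slope sets are strongly rank-correlated."""
        from scipy.stats import spearmanr

        target_based = fit_cohort_sensitivities(feature_matrices)
        auc_based = actual_force_sensitivity(feature_matrices)
        merged = target_based.merge(auc_based, on="participant_id",
                                    suffixes=("_t", "_a"))
        rho, _ = spearmanr(merged["force_slope_t"], merged["force_slope_a"])
        assert rho > 0.7

    def test_missing_auc_column_reported(self, feature_matrices):
        import copy

        broken = {pid: copy.copy(fm)
                  for pid, fm in feature_matrices.items()}
        for fm in broken.values():
            fm.data = fm.data.drop(columns=["auc"])
        with pytest.raises(KeyError, match="AUC"):
            actual_force_sensitivity(broken)
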