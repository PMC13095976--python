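"""Simulation validation studies: does the pipeline recover what the
generator built in?

These are the package's self-checks, run both by the test suite and by
``scripts/acceptance.py``: link-function recovery over seeded cohorts,
second-level coupling recovery, false-positive control under a null
generator, the qualitative ridge feature pattern, and exact oracle
equivalences (Huber vs OLS in the all-inlier limit, the ridge solver vs the
penalised normal equations, step-up FDR vs its brute-force definition).

Monte-Carlo studies simulate traces at 50 Hz (a five-fold downsampling of
the 250 Hz acquisition rate) to keep repeated cohort generation cheap; the
sample rate only discretises time-in-band scoring and feature integrals, and
the task's dynamics live well below 25 Hz.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import link_selection, preprocessing, sensitivity, trace_features
from .ridge_features import (fit_cohort_ridge, fit_weighted_ridge_cv,
                             huber_trial_weights, summarize_group)
from .synthetic_cohort import (CohortCoupling, TaskDesign,
                               failure_rate_by_level, generate_cohort)

__all__ = [
    "fast_design",
    "link_recovery_study",
    "coupling_recovery_study",
    "null_fdr_study",
    "ridge_pattern_study",
    "huber_ols_max_gap",
    "ridge_closed_form_max_gap",
    "bh_brute_force_max_gap",
]


def fast_design() -> TaskDesign:
    return TaskDesign(sample_rate_hz=50.0)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _analysed_cohort(n_participants: int, seed: int,
                     coupling: CohortCoupling | None = None):
    cohort = generate_cohort(n_participants, design=fast_design(),
                             coupling=coupling, seed=seed)
    retained, _ = preprocessing.preprocess_cohort(cohort)
    return retained


def link_recovery_study(n_runs: int = 20, n_participants: int = 40,
                        seed: int = 0) -> pd.DataFrame:
    """Fit the 4 x 2 BIC grid on seeded cohorts generated with the
    quadratic rating model and heterogeneous slopes; one row per run with
    the selected cell."""
    rows = []
    for run_seed in _spawn_seeds(seed, n_runs):
        retained = _analysed_cohort(n_participants, run_seed)
        comparison = link_selection.fit_link_models(retained.trials)
        link, re_structure = comparison.selected
        rows.append({"seed": run_seed, "link": link,
                     "re_structure": re_structure,
                     "quadratic_slope_wins":
                         (link, re_structure) == ("quadratic",
                                                  "intercept_slope")})
    return pd.DataFrame(rows)


def _group_fit(retained):
    fms = trace_features.build_cohort_features(retained)
    estimates = sensitivity.fit_cohort_sensitivities(fms)
    return sensitivity.fit_group_regression(estimates,
                                            retained.participants)


def coupling_recovery_study(n_runs: int = 20, n_participants: int = 100,
                            seed: int = 0) -> pd.DataFrame:
    """Recover the generative symptom couplings (force -0.5, failure +0.5)
    through the full pipeline; one row per run with the standardised PHQ9
    coefficients."""
    truth = CohortCoupling()   # defaults carry the +/-0.5 couplings
    rows = []
    for run_seed in _spawn_seeds(seed, n_runs):
        retained = _analysed_cohort(n_participants, run_seed, truth)
        group = _group_fit(retained)
        rows.append({
            "seed": run_seed,
            "n": group.n,
            "force_phq9": group.coefficients.loc[("force_slope", "phq9"),
                                                 "coefficient"],
            "failure_phq9": group.coefficients.loc[
                ("failure_slope", "phq9"), "coefficient"],
        })
    df = pd.DataFrame(rows)
    df["force_err"] = (df["force_phq9"]
                       - truth.force_slope_vs_symptom).abs()
    df["failure_err"] = (df["failure_phq9"]
                         - truth.failure_slope_vs_symptom).abs()
    df["signs_correct"] = ((df["force_phq9"] < 0)
                           & (df["failure_phq9"] > 0))
    return df


def null_fdr_study(n_reps: int = 200, n_participants: int = 100,
                   seed: int = 0) -> pd.DataFrame:
    """With both slope couplings set to zero, count FDR-significant symptom
    findings (q <= 0.05) across replicates; one row per replicate with the
    number of the four q-values that cross the threshold."""
    null = CohortCoupling(force_slope_vs_symptom=0.0,
                          failure_slope_vs_symptom=0.0)
    rows = []
    for run_seed in _spawn_seeds(seed, n_reps):
        retained = _analysed_cohort(n_participants, run_seed, null)
        group = _group_fit(retained)
        rows.append({"seed": run_seed,
                     "n_significant": int(group.fdr["significant"].sum()),
                     "n_tests": len(group.fdr)})
    return pd.DataFrame(rows)


def ridge_pattern_study(n_participants: int = 40,
                        seed: int = 0) -> pd.DataFrame:
    """Group-mean ridge coefficients on a default cohort (where overshoot
    lowers ratings and cumulative force raises them)."""
    retained = _analysed_cohort(n_participants, seed)
    fms = trace_features.build_cohort_features(retained)
    fits = fit_cohort_ridge(fms, seed=seed)
    return summarize_group(fits)


# --------------------------------------------------------------------------
# oracle equivalences
# --------------------------------------------------------------------------

def huber_ols_max_gap(seed: int = 0) -> float:
    """Max |Huber - OLS| coefficient gap on clean data with a tuning
    constant large enough that every residual is an inlier."""
    rng = np.random.default_rng(seed)
    n = 40
    force = np.tile([0.2, 0.4, 0.6, 0.8, 1.0], n // 5)
    failure = (rng.random(n) < 0.4).astype(float)
    hand = np.arange(n) % 2
    rating = (10 + 60 * force ** 2 + 5 * failure + rng.normal(0, 5, n))
    frame = pd.DataFrame({"participant_id": "P1",
                          "target_force_sq": force ** 2,
                          "failure": failure, "hand_code": hand,
                          "rating": rating})
    est = sensitivity.fit_participant_robust(frame, huber_t=1e8)
    X = np.column_stack([np.ones(n), force ** 2, failure, hand])
    ols = np.linalg.lstsq(X, rating, rcond=None)[0]
    fitted = np.array([est.intercept, est.force_slope, est.failure_slope,
                       est.hand_coefficient])
    return float(np.max(np.abs(fitted - ols)))


def ridge_closed_form_max_gap(seed: int = 0) -> float:
    """Max gap between the ridge solver and the penalised weighted normal
    equations over the whole lambda grid."""
    rng = np.random.default_rng(seed)
    cols = trace_features.FEATURE_COLUMNS
    n = 60
    X = rng.normal(size=(n, len(cols)))
    y = X @ np.linspace(1, -1, len(cols)) + rng.normal(0, 0.4, n)
    frame = pd.DataFrame(X, columns=cols)
    w = huber_trial_weights(frame, y)
    Z = ((frame - frame.mean()) / frame.std(ddof=1)).to_numpy()
    yz = (y - y.mean()) / y.std(ddof=1)
    gap = 0.0
    from .ridge_features import default_lambda_grid

    for lam in default_lambda_grid():
        res = fit_weighted_ridge_cv(frame, y, w, lambda_grid=[lam], k=5)
        oracle = np.linalg.solve(
            Z.T @ (w[:, None] * Z) + lam * np.eye(len(cols)),
            Z.T @ (w * yz))
        gap = max(gap, float(np.max(np.abs(
            res.coefficients.to_numpy() - oracle))))
    return gap


def bh_brute_force_max_gap() -> float:
    """Max gap between the FDR adjustment and the literal step-up
    definition over all 4-subsets of a p-value pool."""
    pool = [0.0005, 0.004, 0.01, 0.02, 0.03, 0.04, 0.049, 0.051, 0.1,
            0.25, 0.5, 0.75, 0.9, 1.0]
    gap = 0.0
    for combo in itertools.combinations(pool, 4):
        q = sensitivity.benjamini_hochberg(list(combo))
        m = len(combo)
        order = np.argsort(combo)
        sorted_p = np.asarray(combo)[order]
        brute = np.empty(m)
        for i in range(m):
            brute[order[i]] = min(min(m * sorted_p[j] / (j + 1)
                                      for j in range(i, m)), 1.0)
        gap = max(gap, float(np.max(np.abs(q - brute))))
    return gap
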