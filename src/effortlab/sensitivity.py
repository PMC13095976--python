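"""Per-participant force/failure sensitivity and symptom associations.

First level: each participant's effort ratings are regressed on squared
target force, the failure indicator, and a hand covariate with a Huber
M-estimator (iteratively reweighted least squares), yielding a rating
intercept, a force slope ("force sensitivity") and a failure slope
("failure sensitivity") that are robust to occasional aberrant ratings.

Second level: the two sensitivities are each regressed on PHQ9, AES, sex,
age and the MVC ratio, with all continuous variables z-scored so the
coefficients are standardised; the four symptom coefficients (PHQ9/AES x
force/failure) form one Benjamini-Hochberg FDR family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from . import trace_features as tf
from .link_selection import transform_force
from .preprocessing import compute_mvc_ratio

__all__ = [
    "SensitivityEstimate",
    "GroupModelResult",
    "RankDeficiencyError",
    "HUBER_T",
    "fit_participant_robust",
    "fit_cohort_sensitivities",
    "fit_group_regression",
    "benjamini_hochberg",
    "intercept_symptom_analysis",
    "actual_force_sensitivity",
]

#: Huber tuning constant (95% efficiency at the Gaussian) and IRLS settings
HUBER_T = 1.345
MAX_ITER = 50
TOL = 1e-8

MIN_TRIALS = 8


class RankDeficiencyError(ValueError):
    """The design matrix is rank-deficient (e.g. a single-class outcome)."""


@dataclass
class SensitivityEstimate:
    """Robust-regression coefficients for one participant."""

    participant_id: str
    intercept: float
    force_slope: float
    failure_slope: float
    hand_coefficient: float
    n_trials: int
    iterations: int
    converged: bool


@dataclass
class GroupModelResult:
    """Second-level regressions of the two sensitivities on covariates.

    ``coefficients`` is indexed by (outcome, predictor) with standardised
    estimates, SEs and p-values; ``fdr`` holds the four symptom tests with
    Benjamini-Hochberg q-values.
    """

    coefficients: pd.DataFrame
    fdr: pd.DataFrame
    n: int
    notes: list[str] = field(default_factory=list)


def _huber_fit(X: np.ndarray, y: np.ndarray, huber_t: float = HUBER_T):
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=huber_t))
    result = model.fit(maxiter=MAX_ITER, tol=TOL, conv="coefs")
    iterations = getattr(result, "fit_history", {})
    n_iter = len(iterations.get("params", [])) or MAX_ITER
    converged = n_iter < MAX_ITER
    return result, n_iter, converged


def fit_participant_robust(features: pd.DataFrame,
                           force_column: str = "target_force_sq",
                           huber_t: float = HUBER_T) -> SensitivityEstimate:
    """Huber IRLS fit of rating ~ force^2 + failure + hand for one
    participant.

    ``features`` is a per-trial table with columns ``force_column``,
    ``failure``, ``hand_code`` and ``rating`` (one row per trial; a
    ``FeatureMatrix.data`` frame works directly).  Requires at least 8
    trials and both outcome classes; a single-class outcome raises
    :class:`RankDeficiencyError`, mirroring the exclusion of the all-success
    participant upstream.
    """
    pid = str(features["participant_id"].iloc[0]) \
        if "participant_id" in features else "?"
    n = len(features)
    if n < MIN_TRIALS:
        raise ValueError(f"participant {pid}: need >= {MIN_TRIALS} trials, "
                         f"got {n}")
    failure = features["failure"].to_numpy(dtype=float)
    if len(np.unique(failure)) < 2:
        raise RankDeficiencyError(
            f"participant {pid}: outcome has a single class "
            f"({'all failures' if failure[0] else 'all successes'}); "
            "the failure regressor is rank-deficient")
    X = np.column_stack([
        np.ones(n),
        features[force_column].to_numpy(dtype=float),
        failure,
        features["hand_code"].to_numpy(dtype=float),
    ])
    y = features["rating"].to_numpy(dtype=float)
    result, n_iter, converged = _huber_fit(X, y, huber_t)
    b = result.params
    return SensitivityEstimate(
        participant_id=pid, intercept=float(b[0]), force_slope=float(b[1]),
        failure_slope=float(b[2]), hand_coefficient=float(b[3]),
        n_trials=n, iterations=n_iter, converged=converged)


def fit_cohort_sensitivities(feature_matrices: dict[str, "tf.FeatureMatrix"],
                             force_column: str = "target_force_sq",
                             ) -> pd.DataFrame:
    """First-level fits for every participant; one row per estimate."""
    rows = []
    for pid in sorted(feature_matrices):
        fm = feature_matrices[pid]
        data = fm.data.copy()
        data["participant_id"] = pid
        est = fit_participant_robust(data, force_column=force_column)
        rows.append({
            "participant_id": pid, "intercept": est.intercept,
            "force_slope": est.force_slope,
            "failure_slope": est.failure_slope,
            "hand_coefficient": est.hand_coefficient,
            "n_trials": est.n_trials, "iterations": est.iterations,
            "converged": est.converged,
        })
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    # population SD: keeps standardised coefficients exactly invariant
    # under sample replication
    sd = np.std(x)
    if sd == 0:
        raise ValueError(f"covariate {name!r} is constant; cannot z-score")
    return (x - np.mean(x)) / sd


def fit_group_regression(estimates: pd.DataFrame,
                         participants: pd.DataFrame,
                         alpha: float = 0.05) -> GroupModelResult:
    """Standardised multiple regressions of force and failure sensitivity on
    PHQ9, AES, sex, age and MVC ratio.

    Continuous variables (both outcomes, PHQ9, AES, age, MVC ratio) are
    z-scored; sex enters as its 0/1 code.  The four symptom p-values (PHQ9
    and AES predicting each sensitivity) are jointly FDR-adjusted.
    """
    merged = estimates.merge(participants, left_on="participant_id",
                             right_on="id", how="inner")
    n = len(merged)
    if n < 10:
        raise ValueError(f"need >= 10 participants, got {n}")
    merged = merged.copy()
    merged["mvc_ratio"] = merged.apply(compute_mvc_ratio, axis=1)

    predictors = ["phq9", "aes", "sex", "age", "mvc_ratio"]
    X = pd.DataFrame({"const": np.ones(n)})
    for p in predictors:
        vals = merged[p].to_numpy(dtype=float)
        X[p] = vals if p == "sex" else _zscore(vals, p)
    if X["sex"].nunique() < 2:
        raise ValueError("covariate 'sex' is constant")

    coef_rows = []
    for outcome in ("force_slope", "failure_slope"):
        y = _zscore(merged[outcome].to_numpy(dtype=float), outcome)
        fit = sm.OLS(y, X).fit()
        for p in predictors:
            coef_rows.append({
                "outcome": outcome, "predictor": p,
                "coefficient": float(fit.params[p]),
                "se": float(fit.bse[p]),
                "p_value": float(fit.pvalues[p]),
            })
    coefficients = pd.DataFrame(coef_rows).set_index(["outcome", "predictor"])

    fdr = coefficients.loc[
        [("force_slope", "phq9"), ("force_slope", "aes"),
         ("failure_slope", "phq9"), ("failure_slope", "aes")]].copy()
    fdr["q_value"] = benjamini_hochberg(fdr["p_value"].to_numpy())
    fdr["significant"] = fdr["q_value"] <= alpha
    return GroupModelResult(coefficients=coefficients, fdr=fdr, n=n)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted q-values (with monotonicity enforcement)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def intercept_symptom_analysis(feature_matrices: dict[str, "tf.FeatureMatrix"],
                               participants: pd.DataFrame,
                               rating_cap: float = 100.0,
                               ) -> dict[str, float]:
    """Pearson correlation between PHQ9 and the robust rating intercepts.

    With ``rating_cap < 100`` the first-level fits are repeated after
    discarding trials rated above the cap (a ceiling-effect check);
    participants left with too few trials or a single outcome class drop out
    of the correlation and are counted in ``n_dropped``.
    """
    if not (0 < rating_cap <= 100):
        raise ValueError("rating_cap must lie in (0, 100]")
    phq9 = participants.set_index("id")["phq9"]
    xs, ys = [], []
    n_dropped = 0
    for pid in sorted(feature_matrices):
        data = feature_matrices[pid].data.copy()
        data["participant_id"] = pid
        if rating_cap < 100:
            data = data[data["rating"] <= rating_cap]
        try:
            est = fit_participant_robust(data)
        except (ValueError, RankDeficiencyError):
            n_dropped += 1
            continue
        xs.append(float(phq9.loc[pid]))
        ys.append(est.intercept)
    if len(xs) < 3:
        raise ValueError("fewer than 3 participants with estimable "
                         "intercepts")
    r, p = pearsonr(xs, ys)
    return {"r": float(r), "p_value": float(p), "n": len(xs),
            "n_dropped": n_dropped, "rating_cap": float(rating_cap)}


def actual_force_sensitivity(feature_matrices: dict[str, "tf.FeatureMatrix"],
                             link: str = "quadratic") -> pd.DataFrame:
    """First-level fits with the *exerted* force (per-trial AUC, transformed
    per the selected link) replacing the squared target force."""
    rows = []
    for pid in sorted(feature_matrices):
        fm = feature_matrices[pid]
        if "auc" not in fm.data:
            raise KeyError(f"participant {pid}: feature matrix has no AUC "
                           "column; traces were not available")
        data = fm.data.copy()
        data["participant_id"] = pid
        data["auc_tf"] = transform_force(data["auc"].to_numpy() /
                                         data["auc"].abs().max(), link)
        est = fit_participant_robust(data, force_column="auc_tf")
        rows.append({"participant_id": pid, "intercept": est.intercept,
                     "force_slope": est.force_slope,
                     "failure_slope": est.failure_slope,
                     "hand_coefficient": est.hand_coefficient,
                     "n_trials": est.n_trials,
                     "iterations": est.iterations,
                     "converged": est.converged})
    return pd.DataFrame(rows)
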