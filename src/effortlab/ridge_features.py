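"""Two-step robust-weights -> cross-validated ridge feature model.

For each participant, the full feature set (target force, failure, lagged
rating/target, cumulative force, coefficient of variation, initial force
difference, excess force, hand) predicts the trial ratings.  Because the
features are collinear and ratings heteroscedastic, a Huber M-estimator is
fit first and its final IRLS weights are carried into a weighted ridge
regression whose shrinkage parameter is picked by 10-fold cross-validation
(minimum weighted validation MSE).  Ridge shrinks correlated coefficients
without zeroing them, so every feature keeps an interpretable standardised
weight; the per-participant weights are then averaged with t-based 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

from .sensitivity import HUBER_T, MAX_ITER, TOL
from .trace_features import FEATURE_COLUMNS, FeatureMatrix

__all__ = [
    "RidgeFitResult",
    "default_lambda_grid",
    "huber_trial_weights",
    "fit_weighted_ridge_cv",
    "fit_cohort_ridge",
    "summarize_group",
    "feature_correlations",
]


def default_lambda_grid() -> np.ndarray:
    """50 log-spaced shrinkage values in [1e-3, 1e3]."""
    return np.logspace(-3, 3, 50)


@dataclass
class RidgeFitResult:
    """One participant's regularised feature weights.

    Coefficients are standardised (features and outcome z-scored within the
    participant); ``cv_mse`` is the mean weighted validation MSE per lambda.
    """

    participant_id: str
    coefficients: pd.Series
    lambda_selected: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray
    trial_weights: np.ndarray


def _standardise(M: np.ndarray, names: list[str]) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    degenerate = [n for n, s in zip(names, sd) if s == 0]
    if degenerate:
        raise ValueError("constant feature column(s) within participant: "
                         + ", ".join(degenerate))
    return (M - M.mean(axis=0)) / sd


def _check_rank(Z: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        corr = np.corrcoef(Z, rowvar=False)
        pairs = [f"{names[i]}~{names[j]}"
                 for i in range(len(names)) for j in range(i + 1, len(names))
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError("feature matrix is rank deficient; collinear "
                         "columns: " + (", ".join(pairs) or "unidentified"))


def huber_trial_weights(features: pd.DataFrame, ratings: np.ndarray,
                        columns: list[str] | None = None,
                        huber_t: float = HUBER_T) -> np.ndarray:
    """Final IRLS weights (in (0, 1]) from a Huber fit of rating on all
    features.

    Inlying trials get weight 1; weights decay as |residual| grows beyond
    the tuning threshold (which scales with the robust residual spread, so
    the weights are invariant to rating rescaling).
    """
    columns = columns or FEATURE_COLUMNS
    X = features[columns].to_numpy(dtype=float)
    y = np.asarray(ratings, dtype=float)
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"need at least {X.shape[1] + 2} trials, "
                         f"got {len(y)}")
    Z = _standardise(X, columns)
    _check_rank(Z, columns)
    design = sm.add_constant(Z)
    result = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=huber_t)).fit(
        maxiter=MAX_ITER, tol=TOL, conv="coefs")
    return np.asarray(result.weights, dtype=float)


def _weighted_ridge_path(Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                         lams: np.ndarray) -> np.ndarray:
    """Solve min_b sum_i w_i (y_i - Z_i b)^2 + lam * ||b||^2 for every lam.

    One eigendecomposition of Z' W Z serves the whole path; returns an array
    of shape (len(lams), p).
    """
    A = Z.T @ (w[:, None] * Z)
    b = Z.T @ (w * y)
    evals, Q = np.linalg.eigh(A)
    qb = Q.T @ b
    return np.stack([Q @ (qb / (evals + lam)) for lam in lams])


def _weighted_ridge(Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                    lam: float) -> np.ndarray:
    """min_b sum_i w_i (y_i - Z_i b)^2 + lam * ||b||^2 (no intercept)."""
    return _weighted_ridge_path(Z, y, w, np.array([lam]))[0]


def fit_weighted_ridge_cv(features: pd.DataFrame, ratings: np.ndarray,
                          weights: np.ndarray,
                          lambda_grid: np.ndarray | None = None,
                          k: int = 10, seed: int = 0,
                          weighted_validation: bool = True,
                          columns: list[str] | None = None,
                          participant_id: str = "?") -> RidgeFitResult:
    """Weighted ridge with a cross-validated shrinkage parameter.

    Features and outcome are z-scored within the participant; for each
    lambda the ridge is solved on the training folds and scored on the
    held-out fold (weighted MSE by default, plain MSE when
    ``weighted_validation`` is off).  The smallest lambda attaining the
    minimum mean MSE wins, and the final coefficients are refit on all rows.
    """
    columns = columns or FEATURE_COLUMNS
    grid = default_lambda_grid() if lambda_grid is None \
        else np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    X = features[columns].to_numpy(dtype=float)
    y = np.asarray(ratings, dtype=float)
    w = np.asarray(weights, dtype=float)
    if k > len(y):
        raise ValueError(f"k={k} folds exceed {len(y)} rows")
    Z = _standardise(X, columns)
    yz = (y - y.mean()) / y.std(ddof=1)

    folds = list(KFold(n_splits=k, shuffle=True,
                       random_state=seed).split(Z))
    fold_mse = np.zeros((len(folds), len(grid)))
    for fi, (train, test) in enumerate(folds):
        path = _weighted_ridge_path(Z[train], yz[train], w[train], grid)
        resid = yz[test][None, :] - path @ Z[test].T
        if weighted_validation:
            fold_mse[fi] = (resid ** 2 @ w[test]) / np.sum(w[test])
        else:
            fold_mse[fi] = np.mean(resid ** 2, axis=1)
    cv_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(cv_mse))  # argmin takes the first (smallest) lambda
    lam_star = float(grid[best])
    coef = _weighted_ridge(Z, yz, w, lam_star)
    return RidgeFitResult(
        participant_id=participant_id,
        coefficients=pd.Series(coef, index=columns),
        lambda_selected=lam_star, lambda_grid=grid, cv_mse=cv_mse,
        trial_weights=w)


def fit_cohort_ridge(feature_matrices: dict[str, FeatureMatrix],
                     lambda_grid: np.ndarray | None = None,
                     k: int = 10, seed: int = 0,
                     weighted_validation: bool = True,
                     columns: list[str] | None = None,
                     ) -> dict[str, RidgeFitResult]:
    """Huber weights -> CV ridge for every participant."""
    out = {}
    for pid in sorted(feature_matrices):
        data = feature_matrices[pid].data
        ratings = data["rating"].to_numpy(dtype=float)
        w = huber_trial_weights(data, ratings, columns=columns)
        out[pid] = fit_weighted_ridge_cv(
            data, ratings, w, lambda_grid=lambda_grid, k=k, seed=seed,
            weighted_validation=weighted_validation, columns=columns,
            participant_id=pid)
    return out


def summarize_group(results: dict[str, RidgeFitResult],
                    ci: float = 0.95) -> pd.DataFrame:
    """Across-participant mean coefficient per feature with a t-based CI."""
    if len(results) < 2:
        raise ValueError("need at least 2 participants to summarise")
    betas = pd.DataFrame({pid: r.coefficients for pid, r in results.items()}).T
    n = len(betas)
    mean = betas.mean(axis=0)
    se = betas.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci / 2, df=n - 1)
    return pd.DataFrame({
        "mean": mean, "se": se,
        "ci_lo": mean - tcrit * se, "ci_hi": mean + tcrit * se,
        "n": n,
    })


def feature_correlations(feature_matrices: dict[str, FeatureMatrix],
                         columns: list[str] | None = None,
                         ) -> pd.DataFrame:
    """Mean (across participants) Pearson correlation matrix of the features.

    Per-participant matrices are averaged elementwise; a participant with a
    constant feature contributes NaN entries for that feature, which are
    excluded from the mean.  The result is symmetric with a unit diagonal.
    """
    columns = columns or FEATURE_COLUMNS
    if len(feature_matrices) < 2:
        raise ValueError("need at least 2 participants")
    mats = []
    for pid in sorted(feature_matrices):
        data = feature_matrices[pid].data
        if len(data) < 3:
            raise ValueError(f"participant {pid}: need >= 3 rows")
        X = data[columns].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
        mats.append(C)
    mean = np.nanmean(np.stack(mats), axis=0)
    mean = (mean + mean.T) / 2
    np.fill_diagonal(mean, 1.0)
    return pd.DataFrame(mean, index=columns, columns=columns)
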