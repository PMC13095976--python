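"""Trial-level and within-trial features extracted from force traces.

The feature set mirrors the study's exploratory model of trial-by-trial
effort ratings: the target force (goal), failure feedback, the previous
trial's rating (perseveration) and target (relative expectation), cumulative
exerted force (fatigue), the coefficient of variation of the force trace
(instability), the initial peak's deviation from target (overshoot), and
excess force beyond what success required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic_cohort import Cohort, ForceTrace, HAND_CODE

__all__ = [
    "FeatureMatrix",
    "area_under_curve",
    "coefficient_of_variation",
    "detect_initial_peak",
    "initial_force_difference",
    "excess_force",
    "cumulative_force",
    "build_feature_matrix",
    "build_cohort_features",
    "FEATURE_COLUMNS",
]

#: predictor columns, in model order (plus the hand covariate)
FEATURE_COLUMNS = [
    "target_force", "failure", "rating_lag1", "target_lag1",
    "cumulative_force", "coefficient_of_variation",
    "initial_force_difference", "excess_force", "hand_code",
]


@dataclass
class FeatureMatrix:
    """Per-trial features aligned to ratings for one participant.

    ``data`` has one row per retained trial (the first trial, whose lag
    features are undefined, is dropped); ``units`` documents each column.
    """

    participant_id: str
    data: pd.DataFrame
    units: dict[str, str]
    flags: pd.DataFrame  # per-trial quality flags (cv_undefined, peak_fallback)


def area_under_curve(trace: ForceTrace) -> float:
    """Trapezoidal integral of force over the trial (fraction-of-MVC * s)."""
    if len(trace.samples) == 0:
        raise ValueError("empty force trace")
    return float(np.trapezoid(trace.samples, dx=1.0 / trace.sample_rate_hz))


def coefficient_of_variation(trace: ForceTrace) -> float:
    """Sample SD (ddof=1) of force over its mean; NaN if the mean is zero."""
    if len(trace.samples) == 0:
        raise ValueError("empty force trace")
    mean = float(np.mean(trace.samples))
    if mean == 0:
        return float("nan")
    if len(trace.samples) < 2:
        return 0.0
    return float(np.std(trace.samples, ddof=1) / mean)


def detect_initial_peak(trace: ForceTrace,
                        min_height: float = 0.1) -> tuple[float, bool]:
    """Force at the first local maximum of height >= ``min_height``
    (fraction-of-MVC units).

    Returns ``(peak_force, fallback)``; when no qualifying interior peak
    exists (e.g. a monotone trace), falls back to the global maximum and sets
    the flag.
    """
    samples = np.asarray(trace.samples, dtype=float)
    if len(samples) == 0:
        raise ValueError("empty force trace")
    peaks, _ = find_peaks(samples, height=min_height)
    if len(peaks):
        return float(samples[peaks[0]]), False
    return float(samples.max()), True


def initial_force_difference(trace: ForceTrace, target_force_frac: float,
                             min_height: float = 0.1) -> tuple[float, bool]:
    """Initial force peak minus target force (positive = overshoot)."""
    peak, fallback = detect_initial_peak(trace, min_height)
    return peak - target_force_frac, fallback


def excess_force(trace: ForceTrace, target_force_frac: float,
                 required_hold_s: float = 3.0) -> float:
    """AUC minus the ideal area ``target * required_hold_s``; may be
    negative when less force was produced than success required."""
    return area_under_curve(trace) - target_force_frac * required_hold_s


def cumulative_force(aucs: "pd.Series | np.ndarray | list[float]",
                     up_to_index: int) -> float:
    """Sum of per-trial AUCs over trials ``1..up_to_index`` inclusive
    (1-based, ordered by trial_index)."""
    aucs = np.asarray(aucs, dtype=float)
    if not 1 <= up_to_index <= len(aucs):
        raise IndexError(f"up_to_index {up_to_index} out of range "
                         f"[1, {len(aucs)}]")
    return float(aucs[:up_to_index].sum())


_UNITS = {
    "target_force": "fraction of MVC",
    "target_force_sq": "(fraction of MVC)^2",
    "failure": "indicator (1 = failure)",
    "rating_lag1": "rating units (0-100)",
    "target_lag1": "fraction of MVC",
    "cumulative_force": "fraction-of-MVC * s",
    "coefficient_of_variation": "dimensionless",
    "initial_force_difference": "fraction of MVC",
    "excess_force": "fraction-of-MVC * s",
    "hand_code": "0 = dominant, 1 = nondominant",
    "rating": "rating units (0-100)",
    "auc": "fraction-of-MVC * s",
}


def build_feature_matrix(participant_id: str, trials: pd.DataFrame,
                         traces: dict[tuple[str, int], ForceTrace],
                         required_hold_s: float = 3.0,
                         peak_min_height: float = 0.1) -> FeatureMatrix:
    """Assemble the full feature matrix for one participant.

    ``trials`` must be that participant's corrected, trial-index-ordered
    rows; forces are fractions of the correct hand's MVC.  The first trial is
    dropped (undefined lag features).
    """
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    rows, flag_rows = [], []
    aucs = []
    for _, tr in trials.iterrows():
        key = (participant_id, int(tr["trial_index"]))
        if key not in traces:
            raise KeyError(
                f"missing force trace for participant {participant_id}, "
                f"trial {int(tr['trial_index'])}")
        trace = traces[key]
        auc = area_under_curve(trace)
        aucs.append(auc)
        cv = coefficient_of_variation(trace)
        diff, fallback = initial_force_difference(
            trace, tr["target_force_frac"], peak_min_height)
        rows.append({
            "trial_index": int(tr["trial_index"]),
            "target_force": tr["target_force_frac"],
            "target_force_sq": tr["target_force_frac"] ** 2,
            "failure": int(tr["outcome"]),
            "cumulative_force": cumulative_force(aucs, len(aucs)),
            "coefficient_of_variation": cv,
            "initial_force_difference": diff,
            "excess_force": auc - tr["target_force_frac"] * required_hold_s,
            "hand_code": HAND_CODE[tr["hand"]],
            "rating": tr["rating"],
            "auc": auc,
        })
        flag_rows.append({
            "trial_index": int(tr["trial_index"]),
            "cv_undefined": bool(np.isnan(cv)),
            "peak_fallback": fallback,
        })
    data = pd.DataFrame(rows)
    data["rating_lag1"] = data["rating"].shift(1)
    data["target_lag1"] = data["target_force"].shift(1)
    data = data.iloc[1:].reset_index(drop=True)
    cols = (["trial_index", "target_force", "target_force_sq", "failure",
             "rating_lag1", "target_lag1", "cumulative_force",
             "coefficient_of_variation", "initial_force_difference",
             "excess_force", "hand_code", "auc", "rating"])
    return FeatureMatrix(
        participant_id=participant_id,
        data=data[cols],
        units={c: _UNITS.get(c, "") for c in cols if c != "trial_index"},
        flags=pd.DataFrame(flag_rows),
    )


def build_cohort_features(cohort: Cohort) -> dict[str, FeatureMatrix]:
    """Feature matrices for every participant in a (corrected) cohort."""
    out = {}
    for pid, trials in cohort.trials.groupby("participant_id", sort=True):
        out[pid] = build_feature_matrix(
            pid, trials, cohort.traces,
            required_hold_s=cohort.design.required_hold_s)
    return out
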