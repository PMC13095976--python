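"""Force correction and participant-level exclusion rules.

The task software scaled target forces by the *opposite* hand's MVC, so the
logged target fractions must first be corrected to the fraction of the
squeezing hand's own MVC that was actually demanded.  Participants are then
excluded (a) when their dominant/nondominant MVC ratio falls in the top
quartile (the miscalibration hits them hardest), and (b) as data-quality
outliers: Spearman force-rating correlation or failure proportion beyond
mean +/- 2.5 SD of the post-quartile cohort, or a 100% success rate (which
would make the failure regressor degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .synthetic_cohort import Cohort

__all__ = [
    "ExclusionReport",
    "correct_target_forces",
    "correct_cohort",
    "compute_mvc_ratio",
    "exclude_top_quartile_ratio",
    "spearman_force_rating",
    "apply_outlier_exclusions",
    "preprocess_cohort",
]

OUTLIER_SD = 2.5
QUARTILE_FRAC = 0.25


@dataclass
class ExclusionReport:
    """Audit trail of the exclusion cascade.

    ``table`` has one row per participant seen at the relevant step with the
    computed statistics and boolean flags; ``steps`` records the retained
    count after each step; ``thresholds`` the cutoffs used.
    """

    table: pd.DataFrame
    steps: list[tuple[str, int]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.steps[-1][1]

    def validate_counts(self) -> None:
        prev = self.steps[0][1]
        for name, n in self.steps[1:]:
            excluded = int(self.table[f"excluded_{name}"].sum()) \
                if f"excluded_{name}" in self.table else prev - n
            if prev - excluded != n:
                raise AssertionError(
                    f"inconsistent counts at step {name}: "
                    f"{prev} - {excluded} != {n}")
            prev = n


def correct_target_forces(participant: pd.Series,
                          trials: pd.DataFrame) -> pd.DataFrame:
    """Rescale logged target fractions to the squeezing hand's own MVC.

    Dominant-hand targets are multiplied by ``mvc_nondom / mvc_dom`` and
    nondominant-hand targets by ``mvc_dom / mvc_nondom``; band edges move
    with the target, everything else is untouched.
    """
    mvc_dom = float(participant["mvc_dom"])
    mvc_nondom = float(participant["mvc_nondom"])
    if not (mvc_dom > 0 and mvc_nondom > 0):
        raise ValueError(
            f"participant {participant.get('id', '?')}: both MVCs must be "
            f"positive (got {mvc_dom}, {mvc_nondom})")
    out = trials.copy()
    is_dom = (out["hand"] == "dominant").to_numpy()
    scale = np.where(is_dom, mvc_nondom / mvc_dom, mvc_dom / mvc_nondom)
    for col in ("target_force_frac", "band_lo", "band_hi"):
        out[col] = out[col].to_numpy() * scale
    return out


def correct_cohort(cohort: Cohort) -> Cohort:
    """Apply the MVC correction to every participant's trials."""
    parts = []
    by_id = cohort.participants.set_index("id", drop=False)
    for pid, trials in cohort.trials.groupby("participant_id", sort=False):
        parts.append(correct_target_forces(by_id.loc[pid], trials))
    trials = pd.concat(parts).sort_index()
    return Cohort(participants=cohort.participants.copy(), trials=trials,
                  traces=cohort.traces, design=cohort.design)


def compute_mvc_ratio(participant: pd.Series) -> float:
    """Dominant over nondominant MVC."""
    mvc_nondom = float(participant["mvc_nondom"])
    if mvc_nondom <= 0:
        raise ValueError("nondominant MVC must be positive")
    return float(participant["mvc_dom"]) / mvc_nondom


def exclude_top_quartile_ratio(cohort: Cohort,
                               frac: float = QUARTILE_FRAC,
                               ) -> tuple[Cohort, ExclusionReport]:
    """Drop the ``floor(frac * n)`` participants with the largest MVC ratio.

    With n divisible by 4 this removes exactly n/4 (108 -> 81).  Ties at the
    boundary are broken by stable participant-id order and noted in the
    report.
    """
    n = len(cohort.participants)
    if n < 4:
        raise ValueError("need at least 4 participants for the quartile rule")
    ratios = cohort.participants.apply(compute_mvc_ratio, axis=1)
    table = cohort.participants[["id"]].copy()
    table["mvc_ratio"] = ratios.to_numpy()
    n_drop = int(np.floor(frac * n))
    # stable sort: descending ratio, id order breaks ties deterministically
    order = table.sort_values(["mvc_ratio", "id"],
                              ascending=[False, True],
                              kind="mergesort")
    drop_ids = set(order["id"].iloc[:n_drop])
    table["excluded_quartile"] = table["id"].isin(drop_ids)

    report = ExclusionReport(table=table,
                             steps=[("input", n), ("quartile", n - n_drop)],
                             thresholds={"quartile_frac": frac})
    boundary = order["mvc_ratio"].iloc[n_drop - 1] if n_drop else np.nan
    if n_drop and (order["mvc_ratio"].iloc[n_drop:] == boundary).any():
        report.notes.append(
            f"tie at quartile boundary (ratio={boundary:.6g}) broken by "
            "participant-id order")
    keep = ~cohort.participants["id"].isin(drop_ids)
    retained = Cohort(
        participants=cohort.participants[keep].reset_index(drop=True),
        trials=cohort.trials[
            ~cohort.trials["participant_id"].isin(drop_ids)].reset_index(
                drop=True),
        traces=cohort.traces, design=cohort.design)
    return retained, report


def spearman_force_rating(trials: pd.DataFrame) -> float:
    """Spearman rank correlation between (corrected) target force and rating
    across one participant's trials; NaN when either variable is constant."""
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    force = trials["target_force_frac"].to_numpy(dtype=float)
    rating = trials["rating"].to_numpy(dtype=float)
    if np.ptp(rating) == 0 or np.ptp(force) == 0:
        return float("nan")
    rho, _ = spearmanr(force, rating)
    return float(rho)


def apply_outlier_exclusions(cohort: Cohort, sd_threshold: float = OUTLIER_SD,
                             ) -> tuple[Cohort, ExclusionReport]:
    """Data-quality exclusions on the post-quartile cohort.

    Computes each participant's Spearman force-rating correlation and
    failure proportion; excludes those outside mean +/- ``sd_threshold`` SD
    on either statistic (both evaluated on the same cohort snapshot), plus
    any participant who never failed a trial.  A zero cohort SD disables
    that criterion (noted in the report).
    """
    rows = []
    for pid, trials in cohort.trials.groupby("participant_id", sort=True):
        # regressions run on the lag-complete trials (the first trial is
        # dropped for its undefined lag features), so the single-class
        # outcome check must look at that subset
        analysed = trials.sort_values("trial_index").iloc[1:]
        rows.append({
            "id": pid,
            "spearman_force_rating": spearman_force_rating(trials),
            "failure_proportion": float(trials["outcome"].mean()),
            "analysed_failure_proportion": float(analysed["outcome"].mean()),
            "n_trials": len(trials),
        })
    table = pd.DataFrame(rows)
    n_in = len(table)

    report = ExclusionReport(table=table, steps=[("input", n_in)],
                             thresholds={"sd_threshold": sd_threshold})

    def _bounds(col):
        vals = table[col].to_numpy()
        ok = np.isfinite(vals)
        mean, sd = float(np.mean(vals[ok])), float(np.std(vals[ok], ddof=1))
        report.thresholds[f"{col}_mean"] = mean
        report.thresholds[f"{col}_sd"] = sd
        if sd == 0:
            report.notes.append(f"{col}: cohort SD is 0, criterion disabled")
            return None
        return mean - sd_threshold * sd, mean + sd_threshold * sd

    rho_b = _bounds("spearman_force_rating")
    fail_b = _bounds("failure_proportion")

    rho = table["spearman_force_rating"].to_numpy()
    fail = table["failure_proportion"].to_numpy()
    table["spearman_outlier"] = (
        ~np.isfinite(rho) if rho_b is None
        else (~np.isfinite(rho)) | (rho < rho_b[0]) | (rho > rho_b[1]))
    table["failure_outlier"] = (
        np.zeros(n_in, bool) if fail_b is None
        else (fail < fail_b[0]) | (fail > fail_b[1]))
    # a single-class outcome (all successes, or all failures) makes the
    # failure regressor rank-deficient downstream
    analysed_fail = table["analysed_failure_proportion"].to_numpy()
    table["all_success"] = (fail == 0) | (analysed_fail == 0)
    table["all_failure"] = (fail == 1) | (analysed_fail == 1)
    table["excluded_outlier"] = (table["spearman_outlier"]
                                 | table["failure_outlier"]
                                 | table["all_success"]
                                 | table["all_failure"])

    drop_ids = set(table.loc[table["excluded_outlier"], "id"])
    report.steps.append(("outlier", n_in - len(drop_ids)))
    keep = ~cohort.participants["id"].isin(drop_ids)
    retained = Cohort(
        participants=cohort.participants[keep].reset_index(drop=True),
        trials=cohort.trials[
            ~cohort.trials["participant_id"].isin(drop_ids)].reset_index(
                drop=True),
        traces=cohort.traces, design=cohort.design)
    return retained, report


def preprocess_cohort(cohort: Cohort, quartile_frac: float = QUARTILE_FRAC,
                      sd_threshold: float = OUTLIER_SD,
                      ) -> tuple[Cohort, ExclusionReport]:
    """Full cascade: MVC correction -> quartile exclusion -> outlier rules.

    Returns the retained cohort (with corrected target fractions) and a
    merged exclusion report.
    """
    corrected = correct_cohort(cohort)
    after_q, rep_q = exclude_top_quartile_ratio(corrected, quartile_frac)
    retained, rep_o = apply_outlier_exclusions(after_q, sd_threshold)

    table = rep_q.table.merge(rep_o.table, on="id", how="left")
    report = ExclusionReport(
        table=table,
        steps=rep_q.steps + rep_o.steps[1:],
        thresholds={**rep_q.thresholds, **rep_o.thresholds},
        notes=rep_q.notes + rep_o.notes)
    return retained, report
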