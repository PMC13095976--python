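"""Synthetic cohorts for a grip-force effort-perception task.

The simulated task: on each trial a participant squeezes a hand dynamometer,
alternating hands, trying to hold force inside a narrow band around a target
(20--100% of that hand's maximal voluntary contraction, MVC) for a cumulative
3 s within a 7 s window; afterwards they rate perceived effort on a 0--100
visual-analogue scale.  The generator reproduces the statistical structure the
downstream analyses assume:

* perceived effort grows with the *square* of exerted force, with individual
  slopes ("force sensitivity") and an additive shift on failed trials
  ("failure sensitivity");
* failure rates rise with target force, via signal-dependent motor noise whose
  spread grows supra-linearly with the intended force level;
* individual force/failure sensitivities (and the rating intercept) are
  coupled to a latent symptom trait from which a PHQ9 depression score is
  discretised, so second-level symptom regressions have a known ground truth;
* the task software's cross-hand MVC mix-up: targets are physically scaled by
  the *opposite* hand's MVC while the logged fraction stays nominal.

Ratings additionally carry modest contributions from within-trial motor
features (initial overshoot lowers ratings; cumulative exerted force, force
instability and excess force raise them), so the exploratory feature analysis
has a recoverable ground truth too.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "TaskDesign",
    "ParticipantProfile",
    "ForceTrace",
    "CohortCoupling",
    "Cohort",
    "ConfigurationError",
    "generate_trial_schedule",
    "simulate_force_trace",
    "determine_outcome",
    "generate_rating",
    "generate_participant_profiles",
    "generate_cohort",
    "apply_miscalibration",
    "failure_rate_by_level",
    "HANDS",
]

HANDS = ("dominant", "nondominant")

#: hand → numeric covariate code used everywhere downstream
HAND_CODE = {"dominant": 0, "nondominant": 1}


class ConfigurationError(ValueError):
    """Invalid task design or cohort-coupling request."""


# --------------------------------------------------------------------------
# task design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Parameters of the force-matching task.

    Defaults match the study design: five target forces {20, 40, 60, 80,
    100}% MVC, four repetitions per hand except three at 100% MVC (38 trials
    in total), a +/-5% target band, a cumulative 3 s hold within a 7 s
    window, force sampled at 250 Hz, and a 20 s inter-trial break.
    """

    force_levels: tuple[float, ...] = (0.20, 0.40, 0.60, 0.80, 1.00)
    reps_per_level: int = 4
    reps_at_max: int = 3
    band_halfwidth_rel: float = 0.05
    trial_window_s: float = 7.0
    required_hold_s: float = 3.0
    rating_scale: tuple[float, float] = (0.0, 100.0)
    sample_rate_hz: float = 250.0
    break_s: float = 20.0          # metadata only
    ramp_s: float = 0.7            # simulated rise time of the squeeze
    consecutive_hold: bool = False  # False: cumulative time-in-band rule
    release_after_success: bool = True

    def validate(self) -> None:
        if self.required_hold_s >= self.trial_window_s:
            raise ConfigurationError(
                "required_hold_s must be smaller than trial_window_s "
                f"({self.required_hold_s} >= {self.trial_window_s})"
            )
        if not self.force_levels or any(f <= 0 for f in self.force_levels):
            raise ConfigurationError("force levels must be positive")
        if self.reps_per_level < 1 or self.reps_at_max < 1:
            raise ConfigurationError("repetition counts must be >= 1")
        if not (0 < self.band_halfwidth_rel < 1):
            raise ConfigurationError("band_halfwidth_rel must be in (0, 1)")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")

    @property
    def trials_per_hand(self) -> int:
        n_sub = self.reps_per_level * (len(self.force_levels) - 1)
        return n_sub + self.reps_at_max

    @property
    def trials_per_participant(self) -> int:
        return 2 * self.trials_per_hand

    def band(self, target: float) -> tuple[float, float]:
        """Multiplicative target band ``target * (1 -/+ halfwidth)``."""
        return (target * (1 - self.band_halfwidth_rel),
                target * (1 + self.band_halfwidth_rel))


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters for one simulated participant.

    ``force_sensitivity_true`` is the slope of rating on squared force
    fraction; ``failure_sensitivity_true`` the additive rating shift on a
    failed trial.  ``motor_noise_scale`` sets the stationary SD of the
    signal-dependent motor noise (SD = scale * level^1.5); ``capacity`` is the
    fraction of MVC the participant can actually sustain, so targets above it
    are matched at the capacity ceiling instead.
    """

    id: str
    age: float
    sex: int                    # 0 = male, 1 = female
    dominant_hand: str          # "right" / "left"
    mvc_dom: float              # newtons
    mvc_nondom: float
    latent_symptom: float
    phq9: int
    aes: int
    rating_intercept: float
    force_sensitivity_true: float
    failure_sensitivity_true: float
    motor_noise_scale: float
    rating_noise_sd: float
    capacity: float = 1.0
    overshoot_mean: float = 0.10    # initial-peak overshoot, fraction of level
    overshoot_sd: float = 0.07
    # rating weights on within-trial motor features
    w_overshoot: float = -15.0
    w_cumulative: float = 0.05
    w_cv: float = 4.0
    w_excess: float = 1.5
    w_lag_rating: float = 0.0
    w_lag_target: float = 0.0

    def validate(self) -> None:
        if self.mvc_dom <= 0 or self.mvc_nondom <= 0:
            raise ConfigurationError("MVC must be positive for both hands")
        if not (0 <= self.phq9 <= 27):
            raise ConfigurationError("PHQ9 outside [0, 27]")
        if not (18 <= self.aes <= 72):
            raise ConfigurationError("AES outside [18, 72]")
        if not (0 <= self.rating_intercept <= 100):
            raise ConfigurationError("rating intercept outside [0, 100]")

    def mvc(self, hand: str) -> float:
        return self.mvc_dom if hand == "dominant" else self.mvc_nondom


@dataclass(frozen=True)
class ForceTrace:
    """One trial's uniformly sampled force series (fraction-of-MVC units)."""

    samples: np.ndarray
    sample_rate_hz: float
    hand: str

    def __post_init__(self):
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class CohortCoupling:
    """Second-level ground truth linking sensitivities to the symptom trait.

    ``force_slope_vs_symptom`` / ``failure_slope_vs_symptom`` are the
    *standardised* couplings (correlation with the latent trait) of the two
    sensitivities; ``intercept_vs_symptom`` likewise for the rating
    intercept.  Means/SDs are in rating units.
    """

    force_slope_vs_symptom: float = -0.5
    failure_slope_vs_symptom: float = 0.5
    intercept_vs_symptom: float = 0.33
    force_slope_mean: float = 60.0
    force_slope_sd: float = 15.0
    failure_slope_mean: float = 5.0
    failure_slope_sd: float = 8.0
    intercept_mean: float = 10.0
    intercept_sd: float = 6.0

    def validate(self) -> None:
        for name in ("force_slope_sd", "failure_slope_sd", "intercept_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("force_slope_vs_symptom", "failure_slope_vs_symptom",
                     "intercept_vs_symptom"):
            if abs(getattr(self, name)) > 1:
                raise ConfigurationError(
                    f"|{name}| > 1: residual noise SD would be negative"
                )


@dataclass
class Cohort:
    """A simulated (or loaded) dataset: participants, trials and traces.

    ``trials.target_force_frac`` holds the *logged* nominal fraction, exactly
    as the miscalibrated task software would have recorded it; the fraction
    each hand actually experienced is recovered downstream by
    ``preprocessing.correct_target_forces``.
    """

    participants: pd.DataFrame
    trials: pd.DataFrame
    traces: dict[tuple[str, int], ForceTrace] = field(default_factory=dict)
    design: TaskDesign = field(default_factory=TaskDesign)


# --------------------------------------------------------------------------
# schedule
# --------------------------------------------------------------------------

def _hand_target_multiset(design: TaskDesign) -> list[float]:
    levels = sorted(design.force_levels)
    out: list[float] = []
    for lv in levels[:-1]:
        out.extend([lv] * design.reps_per_level)
    out.extend([levels[-1]] * design.reps_at_max)
    return out


def generate_trial_schedule(design: TaskDesign, first_hand: str,
                            seed: int | np.random.Generator,
                            ) -> list[tuple[str, float]]:
    """Pseudo-random trial order: per-hand target multisets shuffled
    independently, then interleaved under strict hand alternation.

    Returns a list of ``(hand, target_force_frac)`` pairs (38 under the
    default design).
    """
    design.validate()
    if first_hand not in HANDS:
        raise ConfigurationError(f"unknown hand {first_hand!r}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    per_hand = {}
    for hand in HANDS:
        targets = np.array(_hand_target_multiset(design))
        rng.shuffle(targets)
        per_hand[hand] = list(targets)
    second = HANDS[1] if first_hand == HANDS[0] else HANDS[0]
    schedule = []
    for a, b in itertools.zip_longest(per_hand[first_hand], per_hand[second]):
        schedule.append((first_hand, float(a)))
        if b is not None:
            schedule.append((second, float(b)))
    return schedule


# --------------------------------------------------------------------------
# force traces and outcomes
# --------------------------------------------------------------------------

#: OU correlation time of the motor noise (s); exponent of the
#: signal-dependent noise law SD = motor_noise_scale * level**NOISE_EXPONENT
OU_TAU_S = 0.4
#: low-pass time constant (s) applied to the motor noise: muscle force is
#: rate-limited, so recorded traces are smooth at the sample level
SMOOTH_TAU_S = 0.08
NOISE_EXPONENT = 1.5
RELEASE_TAU_S = 0.25
OVERSHOOT_WIDTH_S = 0.18


def _smooth_noise(white: np.ndarray, dt: float) -> np.ndarray:
    """OU noise low-passed to unit stationary SD.

    An AR(1) with time constant ``OU_TAU_S`` cascaded with an AR(1)
    smoother (``SMOOTH_TAU_S``), normalised exactly via the cascade's
    impulse response so the output SD is 1 regardless of sample rate.
    """
    phi1 = np.exp(-dt / OU_TAU_S)
    phi2 = np.exp(-dt / SMOOTH_TAU_S)
    n = white.shape[-1]
    delta = np.zeros(n)
    delta[0] = 1.0
    h = lfilter([1.0], [1.0, -phi2], lfilter([1.0], [1.0, -phi1], delta))
    gain = np.sqrt(np.sum(h ** 2))
    x = lfilter([1.0], [1.0, -phi1], white, axis=-1)
    x = lfilter([1.0], [1.0, -phi2], x, axis=-1)
    return x / gain


def simulate_force_trace(profile: ParticipantProfile, target_force_frac: float,
                         design: TaskDesign,
                         seed: int | np.random.Generator) -> ForceTrace:
    """Simulate one trial's force trace toward ``target_force_frac`` of the
    squeezing hand's own MVC.

    Model: a linear ramp over ``design.ramp_s`` to an intended level
    ``min(target, capacity)``, an initial overshoot/undershoot transient, and
    Ornstein--Uhlenbeck motor noise with stationary SD
    ``motor_noise_scale * level**1.5`` (signal-dependent noise).  If the
    cumulative-hold success criterion is met and ``release_after_success`` is
    set, the grip is released with a short exponential decay.  The trace is
    clipped at zero.
    """
    if target_force_frac <= 0:
        raise ValueError("target_force_frac must be positive")
    design.validate()
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    traces = _simulate_traces(profile, np.array([target_force_frac]),
                              design, rng)
    return ForceTrace(samples=traces[0], sample_rate_hz=design.sample_rate_hz,
                      hand="dominant")


def _simulate_traces(profile: ParticipantProfile, targets: np.ndarray,
                     design: TaskDesign, rng: np.random.Generator,
                     ) -> np.ndarray:
    """Vectorised trace simulation for a batch of trials (rows)."""
    rate = design.sample_rate_hz
    dt = 1.0 / rate
    n = int(round(design.trial_window_s * rate))
    t = np.arange(n) * dt
    m = len(targets)

    mu = np.minimum(targets, profile.capacity)[:, None]        # intended level
    env = np.clip(t / design.ramp_s, 0.0, 1.0)[None, :]

    # smoothed OU noise with signal-dependent stationary SD
    sigma = profile.motor_noise_scale * mu ** NOISE_EXPONENT
    if profile.motor_noise_scale > 0:
        ou = _smooth_noise(rng.standard_normal((m, n)), dt) * sigma
        os_frac = rng.normal(profile.overshoot_mean, profile.overshoot_sd,
                             size=(m, 1))
    else:
        ou = np.zeros((m, n))
        os_frac = np.zeros((m, 1))

    pulse = mu * os_frac * np.exp(
        -0.5 * ((t[None, :] - design.ramp_s) / OVERSHOOT_WIDTH_S) ** 2)
    pulse[:, t < design.ramp_s * 0.5] = 0.0

    force = env * (mu + ou) + pulse
    np.clip(force, 0.0, None, out=force)

    if design.release_after_success:
        need = int(round(design.required_hold_s * rate))
        lo = targets[:, None] * (1 - design.band_halfwidth_rel)
        hi = targets[:, None] * (1 + design.band_halfwidth_rel)
        in_band = (force >= lo) & (force <= hi)
        cum = np.cumsum(in_band, axis=1)
        for i in range(m):
            hit = np.searchsorted(cum[i], need)
            if hit < n:
                tail = t[hit + 1:] - t[hit]
                force[i, hit + 1:] *= np.exp(-tail / RELEASE_TAU_S)
    return force


def determine_outcome(trace: ForceTrace, band_lo: float, band_hi: float,
                      required_hold_s: float, trial_window_s: float,
                      consecutive: bool = False) -> tuple[int, float]:
    """Score a trial: time in the target band and the failure indicator.

    Samples within the trial window with ``band_lo <= force <= band_hi``
    accumulate (non-consecutively by default); success (outcome 0) requires
    ``time_in_band_s >= required_hold_s``.  Returns ``(outcome,
    time_in_band_s)`` with outcome coded 1 = failure, 0 = success.
    """
    if len(trace.samples) == 0:
        raise ValueError("empty force trace")
    if not band_lo < band_hi:
        raise ValueError("band_lo must be below band_hi")
    rate = trace.sample_rate_hz
    n_window = min(len(trace.samples), int(round(trial_window_s * rate)))
    samples = trace.samples[:n_window]
    in_band = (samples >= band_lo) & (samples <= band_hi)
    if consecutive:
        # longest run of consecutive in-band samples
        best = run = 0
        for flag in in_band:
            run = run + 1 if flag else 0
            best = max(best, run)
        time_in_band = best / rate
    else:
        time_in_band = float(np.count_nonzero(in_band)) / rate
    outcome = 0 if time_in_band >= required_hold_s else 1
    if consecutive:
        time_in_band = float(np.count_nonzero(in_band)) / rate
    return outcome, time_in_band


# --------------------------------------------------------------------------
# ratings
# --------------------------------------------------------------------------

def generate_rating(profile: ParticipantProfile, target_force_frac: float,
                    outcome: int, seed: int | np.random.Generator,
                    noise: float | None = None,
                    feature_terms: float = 0.0,
                    rating_scale: tuple[float, float] = (0.0, 100.0),
                    ) -> float:
    """Rating = clip(intercept + force_sens * f^2 + failure_sens * outcome
    + feature_terms + Gaussian noise, scale bounds)."""
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 (success) or 1 (failure)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if noise is None:
        noise = rng.normal(0.0, profile.rating_noise_sd) \
            if profile.rating_noise_sd > 0 else 0.0
    raw = (profile.rating_intercept
           + profile.force_sensitivity_true * target_force_frac ** 2
           + profile.failure_sensitivity_true * outcome
           + feature_terms + noise)
    return float(np.clip(raw, *rating_scale))


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

# demographic defaults: young healthy adults of the kind the task recruits
AGE_MEAN, AGE_SD, AGE_RANGE = 27.7, 5.8, (18.0, 45.0)
P_FEMALE = 62 / 108
P_RIGHT_HANDED = 98 / 108
MVC_LOG_MEAN, MVC_LOG_SD = np.log(320.0), 0.25     # newtons
MVC_RATIO_LOG_MEAN, MVC_RATIO_LOG_SD = np.log(1.07), 0.09
PHQ9_MEAN, PHQ9_SD = 6.41, 4.03
AES_MEAN, AES_SD = 31.41, 6.82
MOTOR_NOISE_MEDIAN, MOTOR_NOISE_LOG_SD = 0.13, 0.35
RATING_NOISE_SD = 7.0
CAPACITY_MEAN, CAPACITY_SD = 1.0, 0.05


def generate_participant_profiles(n_participants: int,
                                  coupling: CohortCoupling,
                                  rng: np.random.Generator,
                                  ) -> list[ParticipantProfile]:
    coupling.validate()
    profiles = []
    for i in range(n_participants):
        latent = rng.standard_normal()
        latent_apathy = rng.standard_normal()

        def coupled(mean, sd, rho):
            eps = rng.standard_normal()
            return mean + sd * (rho * latent + np.sqrt(1 - rho ** 2) * eps)

        mvc_dom = float(np.exp(rng.normal(MVC_LOG_MEAN, MVC_LOG_SD)))
        ratio = float(np.exp(rng.normal(MVC_RATIO_LOG_MEAN, MVC_RATIO_LOG_SD)))
        profile = ParticipantProfile(
            id=f"P{i + 1:03d}",
            age=float(np.clip(rng.normal(AGE_MEAN, AGE_SD), *AGE_RANGE)),
            sex=int(rng.random() < P_FEMALE),
            dominant_hand="right" if rng.random() < P_RIGHT_HANDED else "left",
            mvc_dom=mvc_dom,
            mvc_nondom=mvc_dom / ratio,
            latent_symptom=latent,
            phq9=int(np.clip(round(PHQ9_MEAN + PHQ9_SD * latent), 0, 27)),
            aes=int(np.clip(round(AES_MEAN + AES_SD * latent_apathy), 18, 72)),
            rating_intercept=float(np.clip(
                coupled(coupling.intercept_mean, coupling.intercept_sd,
                        coupling.intercept_vs_symptom), 0, 100)),
            force_sensitivity_true=coupled(
                coupling.force_slope_mean, coupling.force_slope_sd,
                coupling.force_slope_vs_symptom),
            failure_sensitivity_true=coupled(
                coupling.failure_slope_mean, coupling.failure_slope_sd,
                coupling.failure_slope_vs_symptom),
            motor_noise_scale=float(MOTOR_NOISE_MEDIAN * np.exp(
                rng.normal(0.0, MOTOR_NOISE_LOG_SD))),
            rating_noise_sd=RATING_NOISE_SD,
            capacity=float(rng.normal(CAPACITY_MEAN, CAPACITY_SD)),
        )
        profile.validate()
        profiles.append(profile)
    return profiles


def _trial_feature_terms(profile, corrected_target, trace, outcome,
                         cum_auc, prev_rating, prev_target, design):
    """Within-trial motor-feature contributions to the generative rating.

    Uses the same feature definitions the analysis extracts (area under the
    curve, CV, first peak), so the exploratory feature model has a faithful
    ground truth.
    """
    from . import trace_features as tf

    auc = tf.area_under_curve(trace)
    cv = tf.coefficient_of_variation(trace)
    peak, _ = tf.detect_initial_peak(trace)
    overshoot = peak - corrected_target
    excess = auc - corrected_target * design.required_hold_s
    terms = (profile.w_overshoot * overshoot
             + profile.w_cumulative * cum_auc
             + profile.w_cv * cv
             + profile.w_excess * excess)
    if prev_rating is not None:
        terms += (profile.w_lag_rating * prev_rating
                  + profile.w_lag_target * prev_target)
    return terms, auc


def generate_cohort(n_participants: int,
                    design: TaskDesign | None = None,
                    coupling: CohortCoupling | None = None,
                    seed: int = 0,
                    miscalibrate: bool = True,
                    keep_traces: bool = True) -> Cohort:
    """Simulate a full cohort: profiles, schedules, traces, outcomes, ratings.

    With ``miscalibrate`` (the default, matching the study's software bug)
    each trial is *experienced* at ``nominal * MVC_opposite / MVC_own`` of the
    squeezing hand's MVC while ``trials.target_force_frac`` logs the nominal
    fraction.  Set ``miscalibrate=False`` for a bug-free task.
    """
    if n_participants < 2:
        raise ConfigurationError("need at least 2 participants")
    design = design or TaskDesign()
    coupling = coupling or CohortCoupling()
    design.validate()
    coupling.validate()

    root = np.random.SeedSequence(seed)
    prof_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = generate_participant_profiles(n_participants, coupling,
                                             prof_rng)
    part_seeds = root.spawn(n_participants)

    trial_rows = []
    traces: dict[tuple[str, int], ForceTrace] = {}
    for profile, ss in zip(profiles, part_seeds):
        rng = np.random.default_rng(ss)
        first_hand = HANDS[int(rng.random() < 0.5)]
        schedule = generate_trial_schedule(design, first_hand, rng)

        nominal = np.array([tgt for _, tgt in schedule])
        hands = [hand for hand, _ in schedule]
        if miscalibrate:
            scale = np.array([
                profile.mvc(_other(h)) / profile.mvc(h) for h in hands])
        else:
            scale = np.ones(len(hands))
        experienced = nominal * scale

        force = _simulate_traces(profile, experienced, design, rng)
        cum_auc = 0.0
        prev_rating = prev_target = None
        for k, (hand, tgt) in enumerate(schedule):
            trace = ForceTrace(samples=force[k],
                               sample_rate_hz=design.sample_rate_hz,
                               hand=hand)
            e_lo, e_hi = design.band(experienced[k])
            outcome, tib = determine_outcome(
                trace, e_lo, e_hi, design.required_hold_s,
                design.trial_window_s, consecutive=design.consecutive_hold)
            terms, auc = _trial_feature_terms(
                profile, experienced[k], trace, outcome, cum_auc + 0.0,
                prev_rating, prev_target, design)
            cum_auc += auc
            rating = generate_rating(profile, experienced[k], outcome, rng,
                                     feature_terms=terms,
                                     rating_scale=design.rating_scale)
            lo, hi = design.band(nominal[k])
            trial_rows.append({
                "participant_id": profile.id,
                "trial_index": k + 1,
                "hand": hand,
                "target_force_frac": nominal[k],
                "band_lo": lo,
                "band_hi": hi,
                "outcome": outcome,
                "rating": rating,
                "time_in_band_s": tib,
            })
            if keep_traces:
                traces[(profile.id, k + 1)] = trace
            prev_rating, prev_target = rating, experienced[k]

    participants = pd.DataFrame([{
        "id": p.id, "age": p.age, "sex": p.sex,
        "dominant_hand": p.dominant_hand,
        "mvc_dom": p.mvc_dom, "mvc_nondom": p.mvc_nondom,
        "phq9": p.phq9, "aes": p.aes,
        "sim_latent_symptom": p.latent_symptom,
        "sim_rating_intercept": p.rating_intercept,
        "sim_force_sensitivity": p.force_sensitivity_true,
        "sim_failure_sensitivity": p.failure_sensitivity_true,
        "sim_motor_noise_scale": p.motor_noise_scale,
        "sim_capacity": p.capacity,
    } for p in profiles])
    trials = pd.DataFrame(trial_rows)
    return Cohort(participants=participants, trials=trials, traces=traces,
                  design=design)


def _other(hand: str) -> str:
    return "nondominant" if hand == "dominant" else "dominant"


def apply_miscalibration(cohort: Cohort) -> Cohort:
    """Map experienced force fractions back to the fractions the buggy task
    software logged (functional inverse of
    ``preprocessing.correct_target_forces``).

    The software scaled every target by the *opposite* hand's MVC, so a trial
    experienced at fraction ``e`` of the squeezing hand's own MVC was logged
    as ``e * MVC_own / MVC_opposite``.  Targets and band edges are remapped;
    all other fields are untouched.
    """
    mvc = cohort.participants.set_index("id")[["mvc_dom", "mvc_nondom"]]
    trials = cohort.trials.copy()
    dom = mvc.loc[trials["participant_id"], "mvc_dom"].to_numpy()
    nondom = mvc.loc[trials["participant_id"], "mvc_nondom"].to_numpy()
    is_dom = (trials["hand"] == "dominant").to_numpy()
    scale = np.where(is_dom, dom / nondom, nondom / dom)
    for col in ("target_force_frac", "band_lo", "band_hi"):
        trials[col] = trials[col].to_numpy() * scale
    return Cohort(participants=cohort.participants.copy(), trials=trials,
                  traces=cohort.traces, design=cohort.design)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def failure_rate_by_level(design: TaskDesign | None = None,
                          n_trials_per_level: int = 200,
                          seed: int = 0,
                          coupling: CohortCoupling | None = None,
                          ) -> pd.Series:
    """Monte-Carlo failure fraction at each target level.

    Trials are spread over freshly drawn participant profiles (one trial per
    profile per level) so the estimate reflects the population, not a single
    noise draw.
    """
    design = design or TaskDesign()
    coupling = coupling or CohortCoupling()
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    profiles = generate_participant_profiles(n_trials_per_level, coupling, rng)
    sim_rng = np.random.default_rng(root.spawn(2)[1])
    levels = sorted(design.force_levels)
    rates = {}
    for level in levels:
        fails = 0
        for profile in profiles:
            trace = simulate_force_trace(profile, level, design, sim_rng)
            lo, hi = design.band(level)
            outcome, _ = determine_outcome(
                trace, lo, hi, design.required_hold_s, design.trial_window_s,
                consecutive=design.consecutive_hold)
            fails += outcome
        rates[level] = fails / n_trials_per_level
    return pd.Series(rates, name="failure_rate")
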