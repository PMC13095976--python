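"""Simulator contracts: schedules, traces, outcomes, ratings, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from effortlab.synthetic_cohort import (CohortCoupling, ConfigurationError,
                                        ForceTrace, TaskDesign,
                                        apply_miscalibration,
                                        determine_outcome, generate_cohort,
                                        generate_rating,
                                        generate_trial_schedule,
                                        simulate_force_trace)
from effortlab.preprocessing import correct_cohort


class TestTrialSchedule:
    def test_default_design_yields_38_trials(self):
        schedule = generate_trial_schedule(TaskDesign(), "dominant", seed=0)
        assert len(schedule) == 38

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_composition_and_alternation_for_any_seed(self, seed):
        """Per hand: four repetitions of each submaximal level, three of
        100% MVC; hands strictly alternate."""
        schedule = generate_trial_schedule(TaskDesign(), "nondominant", seed)
        hands = [h for h, _ in schedule]
        assert all(a != b for a, b in zip(hands, hands[1:]))
        assert hands[0] == "nondominant"
        for hand in ("dominant", "nondominant"):
            targets = sorted(t for h, t in schedule if h == hand)
            assert targets == sorted([0.2] * 4 + [0.4] * 4 + [0.6] * 4
                                     + [0.8] * 4 + [1.0] * 3)

    def test_three_maximal_trials_per_hand(self):
        schedule = generate_trial_schedule(TaskDesign(), "dominant", seed=5)
        for hand in ("dominant", "nondominant"):
            assert sum(1 for h, t in schedule
                       if h == hand and t == 1.0) == 3

    def test_same_seed_reproduces_schedule(self):
        a = generate_trial_schedule(TaskDesign(), "dominant", seed=7)
        b = generate_trial_schedule(TaskDesign(), "dominant", seed=7)
        assert a == b

    def test_invalid_hold_duration_rejected(self):
        bad = TaskDesign(required_hold_s=8.0, trial_window_s=7.0)
        with pytest.raises(ConfigurationError):
            generate_trial_schedule(bad, "dominant", seed=0)


class TestForceTrace:
    def test_noise_free_trace_holds_target_after_ramp(self, quiet_profile):
        design = TaskDesign(release_after_success=False)
        trace = simulate_force_trace(quiet_profile, 0.6, design, seed=0)
        t = trace.times
        post_ramp = trace.samples[t >= design.ramp_s]
        assert np.allclose(post_ramp, 0.6, atol=1e-12)
        assert trace.duration_s == pytest.approx(design.trial_window_s)

    def test_same_seed_gives_identical_trace(self, profile):
        a = simulate_force_trace(profile, 0.4, TaskDesign(), seed=9)
        b = simulate_force_trace(profile, 0.4, TaskDesign(), seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_trace_nonnegative_and_bounded_duration(self, profile):
        design = TaskDesign()
        for target in (0.2, 1.0):
            trace = simulate_force_trace(profile, target, design, seed=3)
            assert np.all(trace.samples >= 0)
            assert trace.duration_s <= design.trial_window_s + 1e-9

    def test_nonpositive_target_rejected(self, profile):
        with pytest.raises(ValueError):
            simulate_force_trace(profile, 0.0, TaskDesign(), seed=0)

    def test_failure_rate_rises_with_target_force(self):
        """Monte-Carlo: signal-dependent noise makes the tight relative band
        harder to hold at higher targets, so failures increase."""
        from effortlab.synthetic_cohort import failure_rate_by_level

        rates = failure_rate_by_level(
            design=TaskDesign(sample_rate_hz=50.0),
            n_trials_per_level=200, seed=0)
        values = rates.to_numpy()
        assert np.all(np.diff(values) >= 0)
        assert values[-1] > values[0]


class TestDetermineOutcome:
    def _trace(self, samples, rate=10.0):
        return ForceTrace(samples=np.asarray(samples, float),
                          sample_rate_hz=rate, hand="dominant")

    def test_holding_target_for_required_time_succeeds(self):
        # 3 s at target within a 7 s window, 10 Hz
        samples = [0.5] * 30 + [0.0] * 40
        outcome, tib = determine_outcome(self._trace(samples), 0.45, 0.55,
                                         3.0, 7.0)
        assert outcome == 0
        assert tib == pytest.approx(3.0)

    def test_never_entering_band_fails_with_zero_time(self):
        outcome, tib = determine_outcome(self._trace([0.1] * 70), 0.45,
                                         0.55, 3.0, 7.0)
        assert outcome == 1
        assert tib == 0.0

    def test_time_in_band_accumulates_across_interruptions(self):
        # two separated 1.5 s segments satisfy the cumulative rule
        samples = [0.5] * 15 + [0.0] * 20 + [0.5] * 15 + [0.0] * 20
        outcome, tib = determine_outcome(self._trace(samples), 0.45, 0.55,
                                         3.0, 7.0)
        assert outcome == 0
        assert tib == pytest.approx(3.0)

    def test_consecutive_rule_rejects_interrupted_hold(self):
        samples = [0.5] * 15 + [0.0] * 20 + [0.5] * 15 + [0.0] * 20
        outcome, _ = determine_outcome(self._trace(samples), 0.45, 0.55,
                                       3.0, 7.0, consecutive=True)
        assert outcome == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            determine_outcome(self._trace([]), 0.4, 0.6, 3.0, 7.0)


class TestGenerateRating:
    def test_noise_free_rating_is_affine_in_squared_force(self):
        p = make_profile(rating_intercept=10.0, force_sensitivity_true=60.0,
                         failure_sensitivity_true=5.0, rating_noise_sd=0.0)
        assert generate_rating(p, 0.5, 0, seed=0) == pytest.approx(25.0)
        assert generate_rating(p, 0.5, 1, seed=0) == pytest.approx(30.0)

    def test_rating_clipped_to_scale(self):
        p = make_profile(rating_intercept=95.0, force_sensitivity_true=60.0,
                         rating_noise_sd=0.0)
        assert generate_rating(p, 1.0, 0, seed=0) == 100.0
        low = make_profile(rating_intercept=0.0,
                           force_sensitivity_true=-500.0,
                           rating_noise_sd=0.0)
        assert generate_rating(low, 1.0, 0, seed=0) == 0.0

    def test_invalid_outcome_rejected(self, profile):
        with pytest.raises(ValueError):
            generate_rating(profile, 0.5, 2, seed=0)


class TestGenerateCohort:
    def test_cohort_tables_reproducible_from_seed(self, fast_design):
        a = generate_cohort(4, design=fast_design, seed=11)
        b = generate_cohort(4, design=fast_design, seed=11)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.participants, b.participants)

    def test_negative_coupling_yields_negative_slope_phq9_correlation(
            self, fast_design):
        c = generate_cohort(
            200, design=fast_design, seed=2, keep_traces=False,
            coupling=CohortCoupling(force_slope_vs_symptom=-0.5))
        r = np.corrcoef(c.participants["sim_force_sensitivity"],
                        c.participants["phq9"])[0, 1]
        assert r < -0.2

    def test_zero_coupling_leaves_correlation_small(self, fast_design):
        c = generate_cohort(
            200, design=fast_design, seed=3, keep_traces=False,
            coupling=CohortCoupling(force_slope_vs_symptom=0.0))
        r = np.corrcoef(c.participants["sim_force_sensitivity"],
                        c.participants["phq9"])[0, 1]
        assert abs(r) <= 0.2

    def test_overcoupled_request_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(4, seed=0,
                            coupling=CohortCoupling(
                                force_slope_vs_symptom=1.5))

    def test_trial_count_and_alternation_per_participant(self, small_cohort):
        for _, grp in small_cohort.trials.groupby("participant_id"):
            assert len(grp) == 38
            hands = grp.sort_values("trial_index")["hand"].tolist()
            assert all(a != b for a, b in zip(hands, hands[1:]))


class TestMiscalibration:
    def test_equal_mvcs_leave_cohort_unchanged(self, fast_design):
        c = generate_cohort(4, design=fast_design, seed=5, keep_traces=False)
        c.participants["mvc_nondom"] = c.participants["mvc_dom"]
        remapped = apply_miscalibration(c)
        pd.testing.assert_frame_equal(remapped.trials, c.trials)

    def test_roundtrip_with_correction_restores_fractions(self, fast_design):
        """apply_miscalibration is the exact inverse of the per-hand MVC
        correction."""
        c = generate_cohort(6, design=fast_design, seed=8, keep_traces=False)
        roundtrip = apply_miscalibration(correct_cohort(c))
        np.testing.assert_allclose(
            roundtrip.trials["target_force_frac"],
            c.trials["target_force_frac"], atol=1e-12)

    def test_logged_fraction_reflects_opposite_hand_scaling(self,
                                                            fast_design):
        """A trial experienced at fraction e of its own MVC was logged by
        the buggy software as e * MVC_own / MVC_opposite."""
        c = generate_cohort(2, design=fast_design, seed=5, keep_traces=False)
        row = c.participants.iloc[0]
        trials = c.trials[c.trials["participant_id"] == row["id"]]
        experienced = correct_cohort(c).trials.loc[trials.index]
        dom = trials["hand"] == "dominant"
        np.testing.assert_allclose(
            trials.loc[dom, "target_force_frac"],
            experienced.loc[dom, "target_force_frac"]
            * row["mvc_dom"] / row["mvc_nondom"], rtol=1e-12)
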