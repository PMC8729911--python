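"""Behavioural scoring: optomotor rules, 2AFC summaries, criteria, intervals."""

import math

import numpy as np
import pandas as pd
import pytest

import visacuity as va
from visacuity.behaviour import (
    choice_log_from_frame,
    choice_log_to_frame,
    optomotor_log_from_frame,
    optomotor_log_to_frame,
)


def _rot(subject, freq, cat="<1/4", eye=False, stress=False, direction="cw"):
    return va.OptomotorRotation(
        subject=subject,
        frequency_cpd=freq,
        direction=direction,
        eye_tracking=eye,
        turn_category=cat,
        stress=stress,
    )


def _block(subject, freq, cats, eyes=None, stresses=None):
    eyes = eyes or [False] * 4
    stresses = stresses or [False] * 4
    dirs = ["cw", "ccw", "cw", "ccw"]
    return [
        _rot(subject, freq, cat=c, eye=e, stress=s, direction=d)
        for c, e, s, d in zip(cats, eyes, stresses, dirs)
    ]


def hand_annotated_log():
    """30 rotations for one subject, scored by hand.

    0.2 cpd: 3 half-turns + 1 negative            -> positive
    0.4 cpd: 2 big turns + 1 eye-track + 1 neg    -> positive
    0.8 cpd: 2 positives, 1 negative, 1 stressed  -> 2/3 usable, negative
    1.0 cpd: 3 positives but one of them stressed -> 2/3 usable, negative
    2.0 cpd: all four stressed                    -> excluded
    control: all negative                          -> subject valid
    + 2 extra rotations at 3.0 cpd (both negative, low-confidence block)
    Expected acuity limit: 0.4 cpd.
    """
    log = []
    log += _block("f1", 0.2, ["1/2-1", "1/2-1", "1/2-1", "<1/4"])
    log += _block("f1", 0.4, [">1", "1/2-1", "<1/4", "1/4-1/2"], eyes=[False, False, True, False])
    log += _block("f1", 0.8, ["1/2-1", ">1", "<1/4", "1/2-1"], stresses=[False, False, False, True])
    log += _block("f1", 1.0, ["1/2-1", "1/2-1", "1/2-1", "<1/4"], stresses=[True, False, False, False])
    log += _block("f1", 2.0, ["1/2-1", ">1", "1/2-1", ">1"], stresses=[True, True, True, True])
    log += _block("f1", None, ["<1/4", "<1/4", "1/4-1/2", "<1/4"])
    log += [
        _rot("f1", 3.0, cat="<1/4", direction="cw"),
        _rot("f1", 3.0, cat="1/4-1/2", direction="ccw"),
    ]
    return log


class TestOptomotorScoring:
    def test_hand_annotated_fixture_scored_exactly(self):
        scores = va.score_optomotor(hand_annotated_log())
        s = scores["f1"]
        t = s.per_frequency.set_index("frequency_cpd")
        assert bool(t.loc[0.2, "positive"])
        assert bool(t.loc[0.4, "positive"])
        # 0.8: 3 usable (one stressed dropped), only 2 positive -> negative
        assert t.loc[0.8, "n_usable"] == 3 and not bool(t.loc[0.8, "positive"])
        # 1.0: stressed positive dropped leaves 2/3 -> negative
        assert t.loc[1.0, "n_usable"] == 3 and not bool(t.loc[1.0, "positive"])
        # 2.0: everything stressed -> excluded from the limit computation
        assert t.loc[2.0, "n_usable"] == 0 and t.loc[2.0, "positive"] is None
        # 3.0: two usable, both negative, low-confidence block
        assert bool(t.loc[3.0, "low_confidence"]) and not bool(t.loc[3.0, "positive"])
        assert s.acuity_limit_cpd == 0.4
        assert s.valid and not s.control_positive and not s.non_monotone

    def test_three_of_four_half_turns_is_positive(self):
        log = _block("m1", 0.2, ["1/2-1", "1/2-1", "1/2-1", "<1/4"])
        s = va.score_optomotor(log)["m1"]
        assert bool(s.per_frequency["positive"].iloc[0])

    def test_limit_is_finest_positive_frequency(self):
        # positive at 0.2 and 0.8 only -> limit 0.8 (non-monotone profiles allowed)
        log = []
        log += _block("m2", 0.2, ["1/2-1", ">1", "1/2-1", "<1/4"])
        log += _block("m2", 0.4, ["<1/4", "<1/4", "<1/4", "<1/4"])
        log += _block("m2", 0.8, [">1", ">1", "1/2-1", "<1/4"])
        log += _block("m2", 1.0, ["<1/4", "<1/4", "1/4-1/2", "<1/4"])
        s = va.score_optomotor(log)["m2"]
        assert s.acuity_limit_cpd == 0.8
        assert s.non_monotone

    def test_eye_tracking_alone_counts(self):
        log = _block("m3", 0.6, ["<1/4"] * 4, eyes=[True, True, True, False])
        s = va.score_optomotor(log)["m3"]
        assert bool(s.per_frequency["positive"].iloc[0])

    def test_control_positive_invalidates_subject(self):
        log = _block("f2", 0.2, ["1/2-1"] * 4)
        log += _block("f2", None, [">1", ">1", "1/2-1", "<1/4"])
        s = va.score_optomotor(log)["f2"]
        assert s.control_positive and not s.valid

    def test_all_stressed_subject_unusable(self):
        log = _block("f3", 0.2, ["1/2-1"] * 4, stresses=[True] * 4)
        s = va.score_optomotor(log)["f3"]
        assert s.acuity_limit_cpd is None and not s.valid

    def test_csv_round_trip(self, tmp_path):
        log = hand_annotated_log()
        frame = optomotor_log_to_frame(log)
        path = tmp_path / "rot.csv"
        frame.to_csv(path, index=False)
        back = optomotor_log_from_frame(pd.read_csv(path, keep_default_na=False))
        assert back == log


class TestChoiceSummary:
    def test_proportion_arithmetic(self):
        trials = [
            va.ChoiceTrial("s", 1.0, "left", "left" if i < 11 else "right")
            for i in range(15)
        ]
        summary = va.summarize_choices(trials)
        assert summary.table["proportion"].iloc[0] == pytest.approx(11 / 15)
        assert summary.table["n"].iloc[0] == 15

    def test_exact_binomial_interval_brackets_proportion(self):
        trials = [
            va.ChoiceTrial("s", 2.0, "left", "left" if i < 12 else "right")
            for i in range(15)
        ]
        t = va.summarize_choices(trials).table.iloc[0]
        assert t.ci_low < t.proportion < t.ci_high
        assert t.ci_low == pytest.approx(0.5191, abs=1e-3)  # Clopper-Pearson 12/15

    def test_side_balance_on_simulated_log(self):
        obs = va.SyntheticObserver(threshold_cpd=2.0)
        trials = va.simulate_choice_trials(obs, [0.5, 1.0, 2.0], 200, seed=41)
        summary = va.summarize_choices(trials)
        assert abs(summary.side_balance - 0.5) < 0.06

    def test_csv_round_trip(self, tmp_path):
        obs = va.SyntheticObserver(threshold_cpd=1.5)
        trials = va.simulate_choice_trials(obs, [1.0, 2.0], 10, seed=42)
        path = tmp_path / "choice.csv"
        choice_log_to_frame(trials).to_csv(path, index=False)
        assert choice_log_from_frame(pd.read_csv(path)) == trials


class TestBinomialCriterion:
    def test_fifteen_trial_criterion(self):
        # P(X>=11)=0.059, P(X>=12)=0.018 -> 12/15 = 0.80
        k, prop = va.binomial_criterion(15, alpha=0.05, chance=0.5)
        assert (k, prop) == (12, 0.8)

    def test_single_trial_saturates_at_perfection(self):
        assert va.binomial_criterion(1) == (1, 1.0)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_matches_exhaustive_enumeration(self, n):
        # independent oracle: count the 2^n equally likely outcome strings
        def tail(k):
            return sum(math.comb(n, j) for j in range(k, n + 1)) / 2**n

        # saturation convention: when no count is significant, criterion = n/n
        k_oracle = next((k for k in range(n + 1) if tail(k) < 0.05), n)
        k_pkg, _ = va.binomial_criterion(n, alpha=0.05, chance=0.5)
        assert k_pkg == k_oracle

    def test_large_n_approaches_normal_approximation(self):
        n = 1_000
        _, prop = va.binomial_criterion(n, alpha=0.05, chance=0.5)
        approx = 0.5 + 1.6449 * math.sqrt(0.25 / n)
        assert abs(prop - approx) < 2.0 / math.sqrt(n) * 0.1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            va.binomial_criterion(0)
        with pytest.raises(ValueError):
            va.binomial_criterion(10, alpha=1.5)


def _summary(props: dict[float, float]) -> va.PsychometricSummary:
    table = pd.DataFrame(
        [
            dict(frequency_cpd=f, n=15, k=round(p * 15), proportion=p, ci_low=0, ci_high=1)
            for f, p in props.items()
        ]
    )
    return va.PsychometricSummary(table=table, side_balance=0.5)


class TestThresholdInterval:
    def test_male_group_profile(self):
        s = va.threshold_interval(_summary({0.2: 0.85, 1.0: 0.74, 2.0: 0.51}), 0.73)
        assert s.interval == (1.0, 2.0)

    def test_female_group_profile(self):
        s = va.threshold_interval(_summary({0.4: 0.87, 2.0: 0.79, 3.0: 0.65}), 0.73)
        assert s.interval == (2.0, 3.0)

    def test_monotone_synthetic_curve(self):
        s = va.threshold_interval(
            _summary({0.5: 0.95, 1.0: 0.9, 2.0: 0.8, 3.0: 0.6, 4.0: 0.5}), 0.73
        )
        assert s.interval == (2.0, 3.0)

    def test_nothing_above_criterion(self):
        s = va.threshold_interval(_summary({1.0: 0.6, 2.0: 0.5}), 0.73)
        assert s.interval == (None, 1.0)

    def test_never_below_criterion(self):
        s = va.threshold_interval(_summary({1.0: 0.9, 2.0: 0.85}), 0.73)
        assert s.interval == (2.0, None)

    def test_isolated_dip_skipped_and_flagged(self):
        s = va.threshold_interval(
            _summary({0.5: 0.9, 1.0: 0.70, 2.0: 0.8, 3.0: 0.6, 4.0: 0.45}), 0.73
        )
        assert s.interval == (2.0, 3.0)
        assert s.non_monotone

    def test_invalid_criterion(self):
        with pytest.raises(ValueError):
            va.threshold_interval(_summary({1.0: 0.9}), 1.2)


class TestParameterRecovery:
    """Simulated observers must be recovered by the interval method."""

    @pytest.mark.parametrize(
        "threshold,expected", [(1.5, (1.0, 2.0)), (2.5, (2.0, 3.0))]
    )
    def test_interval_recovery_quick(self, threshold, expected):
        ladder = [0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        obs = va.SyntheticObserver(threshold_cpd=threshold, slope=6.0, lapse=0.02)
        hits = 0
        for rep in range(20):
            trials = va.simulate_choice_trials(obs, ladder, 200, seed=1_000 + rep)
            s = va.threshold_interval(va.summarize_choices(trials), 0.73)
            hits += s.interval == expected
        assert hits >= 19

    def test_optomotor_limit_recovery_quick(self):
        ladder = [0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        obs = va.SyntheticObserver(threshold_cpd=2.5, optomotor_false_positive=0.02)
        hits = 0
        for rep in range(20):
            rots = va.simulate_optomotor_session(obs, ladder, seed=2_000 + rep)
            s = va.score_optomotor(rots)["sim"]
            hits += s.acuity_limit_cpd == 2.0  # finest tested sub-threshold frequency
        assert hits >= 17
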