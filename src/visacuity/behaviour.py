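"""Scoring of behavioural acuity assays.

Two paradigms are supported:

* **Optomotor assay** — a fish inside a rotating striped drum reflexively
  tracks the rotation when it can resolve the stripes.  Each stimulus
  frequency is shown for four rotations (two clockwise, two counter-clockwise);
  a frequency counts as positive when at least three of the four rotations
  show either eye tracking or at least a half-turn in the stimulus direction.
  Rotations with stress behaviour are discarded before scoring.  The acuity
  limit is the finest (highest-cpd) stimulus with a positive response.

* **Conditioned two-alternative forced choice (2AFC)** — a fish chooses
  between a grating and a luminance-matched grey; chance performance is 0.5.
  Per-frequency proportions correct are compared against a criterion (either
  a fixed replication constant such as 0.73, or the exact-binomial criterion
  for the session's trial count), and the acuity limit is reported as the
  interval between the last frequency above criterion and the next tested
  frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "OptomotorRotation",
    "ChoiceTrial",
    "PsychometricSummary",
    "OptomotorScore",
    "score_optomotor",
    "summarize_choices",
    "binomial_criterion",
    "threshold_interval",
    "optomotor_log_to_frame",
    "optomotor_log_from_frame",
    "choice_log_to_frame",
    "choice_log_from_frame",
]

#: turn-fraction categories, in increasing order of rotation
TURN_CATEGORIES = ("<1/4", "1/4-1/2", "1/2-1", ">1")
#: categories that count as a positive tracking response on their own
POSITIVE_TURNS = frozenset({"1/2-1", ">1"})


@dataclass(frozen=True)
class OptomotorRotation:
    """One 45-s drum rotation shown to one subject.

    ``turn_category`` records how far the fish turned *in the stimulus
    direction*; ``frequency_cpd`` is ``None`` for grey control rotations.
    """

    subject: str
    frequency_cpd: float | None
    direction: str  # "cw" | "ccw"
    eye_tracking: bool
    turn_category: str
    stress: bool = False

    def __post_init__(self) -> None:
        if self.turn_category not in TURN_CATEGORIES:
            raise ValueError(
                f"turn_category must be one of {TURN_CATEGORIES}, "
                f"got {self.turn_category!r}"
            )
        if self.direction not in ("cw", "ccw"):
            raise ValueError(f"direction must be 'cw' or 'ccw', got {self.direction!r}")

    @property
    def is_control(self) -> bool:
        return self.frequency_cpd is None

    @property
    def positive(self) -> bool:
        """Individually positive: eye tracking or at least a half turn."""
        return self.eye_tracking or self.turn_category in POSITIVE_TURNS


@dataclass(frozen=True)
class ChoiceTrial:
    """One 2AFC trial: the grey (rewarded) stimulus is on ``positive_side``."""

    subject: str
    frequency_cpd: float
    positive_side: str  # "left" | "right"
    chosen_side: str

    def __post_init__(self) -> None:
        for side in (self.positive_side, self.chosen_side):
            if side not in ("left", "right"):
                raise ValueError(f"sides must be 'left' or 'right', got {side!r}")
        if self.frequency_cpd <= 0:
            raise ValueError("frequency_cpd must be positive")

    @property
    def correct(self) -> bool:
        return self.chosen_side == self.positive_side


@dataclass
class PsychometricSummary:
    """Per-frequency 2AFC performance with an optional threshold interval."""

    table: pd.DataFrame  # columns: frequency_cpd, n, k, proportion, ci_low, ci_high
    side_balance: float  # fraction of trials with the positive stimulus on the left
    criterion: float | None = None
    last_above: float | None = None
    first_below: float | None = None
    non_monotone: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def interval(self) -> tuple[float | None, float | None]:
        return (self.last_above, self.first_below)


@dataclass
class OptomotorScore:
    """Scored optomotor session for one subject."""

    subject: str
    per_frequency: pd.DataFrame  # frequency_cpd, n_scheduled, n_usable, n_positive, positive, low_confidence
    acuity_limit_cpd: float | None
    valid: bool
    control_positive: bool
    non_monotone: bool
    flags: list[str] = field(default_factory=list)


def _frequency_positive(rotations: Sequence[OptomotorRotation]) -> tuple[int, int, bool | None, bool]:
    """Score one frequency block.

    Returns ``(n_usable, n_positive, positive, low_confidence)``.  ``positive``
    is ``None`` when every rotation was discarded for stress.  With fewer than
    three usable rotations the requirement degrades to "all usable positive"
    and the block is flagged low-confidence.
    """
    usable = [r for r in rotations if not r.stress]
    n_usable = len(usable)
    n_pos = sum(r.positive for r in usable)
    if n_usable == 0:
        return 0, 0, None, True
    required = 3 if n_usable >= 3 else n_usable
    return n_usable, n_pos, n_pos >= required, n_usable < 3


def score_optomotor(rotations: Iterable[OptomotorRotation]) -> dict[str, OptomotorScore]:
    """Score optomotor rotation logs into per-subject acuity limits.

    Stress-flagged rotations are discarded first.  A frequency is positive when
    at least three usable rotations (or all, if fewer than three are usable)
    are individually positive.  The acuity limit is the finest positive
    frequency, applied literally even across non-monotone profiles (which are
    flagged).  Subjects positive on the grey control are marked invalid.
    """
    rotations = list(rotations)
    if not rotations:
        raise ValueError("no rotations supplied")
    by_subject: dict[str, list[OptomotorRotation]] = {}
    for r in rotations:
        by_subject.setdefault(r.subject, []).append(r)

    scores: dict[str, OptomotorScore] = {}
    for subject, rots in by_subject.items():
        test_rots = [r for r in rots if not r.is_control]
        ctrl_rots = [r for r in rots if r.is_control]
        usable_any = [r for r in test_rots if not r.stress]
        if not usable_any:
            scores[subject] = OptomotorScore(
                subject=subject,
                per_frequency=pd.DataFrame(),
                acuity_limit_cpd=None,
                valid=False,
                control_positive=False,
                non_monotone=False,
                flags=["all rotations stressed; subject unusable"],
            )
            continue

        freqs = sorted({r.frequency_cpd for r in test_rots})
        rows = []
        flags: list[str] = []
        for f in freqs:
            block = [r for r in test_rots if r.frequency_cpd == f]
            n_usable, n_pos, positive, low_conf = _frequency_positive(block)
            rows.append(
                dict(
                    frequency_cpd=f,
                    n_scheduled=len(block),
                    n_usable=n_usable,
                    n_positive=n_pos,
                    positive=positive,
                    low_confidence=low_conf,
                )
            )
            if positive is None:
                flags.append(f"frequency {f} cpd excluded: all rotations stressed")
        table = pd.DataFrame(rows)

        scored = table[table["positive"].notna()]
        positives = scored[scored["positive"].astype(bool)]
        limit = float(positives["frequency_cpd"].max()) if len(positives) else None
        non_monotone = False
        if limit is not None:
            below = scored[scored["frequency_cpd"] < limit]
            non_monotone = bool((~below["positive"].astype(bool)).any())
            if non_monotone:
                flags.append("non-monotone response profile below the acuity limit")

        control_positive = False
        if ctrl_rots:
            _, _, ctrl_pos, _ = _frequency_positive(ctrl_rots)
            control_positive = bool(ctrl_pos)
            if control_positive:
                flags.append("positive response to the grey control; subject excluded")

        scores[subject] = OptomotorScore(
            subject=subject,
            per_frequency=table,
            acuity_limit_cpd=limit,
            valid=not control_positive,
            control_positive=control_positive,
            non_monotone=non_monotone,
            flags=flags,
        )
    return scores


def summarize_choices(trials: Iterable[ChoiceTrial]) -> PsychometricSummary:
    """Summarise 2AFC trials into per-frequency proportions correct.

    Confidence limits are exact (Clopper–Pearson) 95% binomial intervals.
    The side-balance statistic is the fraction of trials with the positive
    stimulus shown on the left.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    rows = []
    for f in sorted({t.frequency_cpd for t in trials}):
        block = [t for t in trials if t.frequency_cpd == f]
        n = len(block)
        k = sum(t.correct for t in block)
        ci = _sps.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            dict(
                frequency_cpd=f,
                n=n,
                k=k,
                proportion=k / n,
                ci_low=ci.low,
                ci_high=ci.high,
            )
        )
    table = pd.DataFrame(rows)
    balance = float(np.mean([t.positive_side == "left" for t in trials]))
    return PsychometricSummary(table=table, side_balance=balance)


def binomial_criterion(n: int, alpha: float = 0.05, chance: float = 0.5) -> tuple[int, float]:
    """Smallest ``k`` (and ``k/n``) whose one-tailed exact binomial tail
    probability ``P(X >= k | n, chance)`` is below ``alpha``.

    For ``n=15, alpha=0.05, chance=0.5`` this gives ``k=12`` (0.80): the tail
    at 11/15 is 0.059, just above 0.05.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < chance < 1:
        raise ValueError("chance must be in (0, 1)")
    for k in range(n + 1):
        if _sps.binom.sf(k - 1, n, chance) < alpha:
            return k, k / n
    # even a perfect run is not significant (alpha <= chance**n):
    # the criterion saturates at perfection
    return n, 1.0


def threshold_interval(
    summary: PsychometricSummary, criterion: float
) -> PsychometricSummary:
    """Bracket the acuity limit between tested frequencies.

    ``last_above`` is the last frequency before the first *sustained* drop
    below criterion (a drop at the final tested frequency counts as
    sustained); ``first_below`` is the next tested frequency.  A single
    isolated dip followed by recovery above criterion is skipped and the
    summary flagged non-monotone.  When no frequency meets the criterion the
    interval is ``(None, coarsest tested)``.
    """
    if criterion <= 0 or criterion >= 1:
        raise ValueError("criterion must be in (0, 1)")
    table = summary.table.sort_values("frequency_cpd").reset_index(drop=True)
    freqs = table["frequency_cpd"].to_numpy(dtype=float)
    props = table["proportion"].to_numpy(dtype=float)

    summary.criterion = criterion
    below = props < criterion
    if below.all():
        summary.last_above = None
        summary.first_below = float(freqs[0])
        summary.flags.append("no frequency meets the criterion")
        return summary

    crossing = None
    for i in range(len(freqs)):
        if below[i] and (i == len(freqs) - 1 or below[i + 1]):
            crossing = i
            break
        if below[i]:
            summary.non_monotone = True
            summary.flags.append(
                f"isolated sub-criterion dip at {freqs[i]} cpd skipped"
            )
    if crossing is None:
        summary.last_above = float(freqs[-1])
        summary.first_below = None
        summary.flags.append("performance never drops below criterion; limit beyond tested range")
        return summary
    if crossing == 0:
        summary.last_above = None
        summary.first_below = float(freqs[0])
        summary.flags.append("no frequency meets the criterion before the first drop")
        return summary
    summary.last_above = float(freqs[crossing - 1])
    summary.first_below = float(freqs[crossing])
    return summary


# ---------------------------------------------------------------------------
# CSV interchange

def optomotor_log_to_frame(rotations: Iterable[OptomotorRotation]) -> pd.DataFrame:
    rows = [
        dict(
            subject=r.subject,
            frequency_cpd="" if r.frequency_cpd is None else r.frequency_cpd,
            direction=r.direction,
            eye_tracking=int(r.eye_tracking),
            turn_category=r.turn_category,
            stress=int(r.stress),
        )
        for r in rotations
    ]
    return pd.DataFrame(rows)


def optomotor_log_from_frame(frame: pd.DataFrame) -> list[OptomotorRotation]:
    out = []
    for row in frame.itertuples(index=False):
        f = row.frequency_cpd
        freq = None if (f == "" or pd.isna(f)) else float(f)
        out.append(
            OptomotorRotation(
                subject=str(row.subject),
                frequency_cpd=freq,
                direction=str(row.direction),
                eye_tracking=bool(int(row.eye_tracking)),
                turn_category=str(row.turn_category),
                stress=bool(int(row.stress)),
            )
        )
    return out


def choice_log_to_frame(trials: Iterable[ChoiceTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subject=t.subject,
                frequency_cpd=t.frequency_cpd,
                positive_side=t.positive_side,
                chosen_side=t.chosen_side,
            )
            for t in trials
        ]
    )


def choice_log_from_frame(frame: pd.DataFrame) -> list[ChoiceTrial]:
    return [
        ChoiceTrial(
            subject=str(row.subject),
            frequency_cpd=float(row.frequency_cpd),
            positive_side=str(row.positive_side),
            chosen_side=str(row.chosen_side),
        )
        for row in frame.itertuples(index=False)
    ]
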