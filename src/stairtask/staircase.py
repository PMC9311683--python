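"""Weighted up/down staircase on a tolerance time window.

The task asks a responder to reproduce a 1-s interval; a response is fed back
as *correct* when it lands inside the current tolerance window. After every
trial the window is adapted: widened after an incorrect response, shrunk
after a correct one. Asymmetric step sizes (e.g. widen 3 ms / shrink 12 ms)
drive the long-run proportion of correct feedback toward
``widen / (widen + shrink)`` regardless of the responder's precision — the
classic weighted up/down equilibrium.

This module holds the pure staircase algorithm: response classification,
the window update, running a block of trials, and scored accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class ToleranceWindow:
    """Closed interval of response times (ms) classified as correct."""

    lower_ms: float
    upper_ms: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower_ms) and math.isfinite(self.upper_ms)):
            raise ValueError("window boundaries must be finite")
        if self.lower_ms > self.upper_ms:
            raise ValueError(
                f"lower_ms ({self.lower_ms}) must not exceed upper_ms ({self.upper_ms})"
            )

    @property
    def width_ms(self) -> float:
        return self.upper_ms - self.lower_ms

    @property
    def midpoint_ms(self) -> float:
        return 0.5 * (self.lower_ms + self.upper_ms)

    def contains(self, response_time_ms: float) -> bool:
        return self.lower_ms <= response_time_ms <= self.upper_ms


#: Initial tolerance window of the paradigm (ms).
INITIAL_WINDOW = ToleranceWindow(990.0, 1100.0)


@dataclass(frozen=True)
class StaircaseRule:
    """Step sizes of one difficulty level.

    ``widen_total_ms`` is the total widening applied after an incorrect
    response, ``shrink_total_ms`` the total shrinking after a correct one.
    Both are split symmetrically across the two boundaries.
    """

    widen_total_ms: float
    shrink_total_ms: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.widen_total_ms <= 0 or self.shrink_total_ms <= 0:
            raise ValueError("step sizes must be positive")

    @property
    def equilibrium_hit_rate(self) -> float:
        """Hit rate at which the expected window-width change is zero."""
        return self.widen_total_ms / (self.widen_total_ms + self.shrink_total_ms)


#: High-difficulty rule: widen 3 ms on a miss, shrink 12 ms on a hit (20% equilibrium).
HARD = StaircaseRule(3.0, 12.0, name="hard")
#: Low-difficulty rule: widen 12 ms on a miss, shrink 3 ms on a hit (80% equilibrium).
EASY = StaircaseRule(12.0, 3.0, name="easy")

RULES = {"hard": HARD, "easy": EASY}


class TrialResult(NamedTuple):
    trial_index: int
    response_time_ms: float
    correct: bool
    window_before: ToleranceWindow
    window_after: ToleranceWindow
    scored: bool


def classify_response(response_time_ms: float, window: ToleranceWindow) -> bool:
    """Return True (correct feedback) iff the response lies in the closed window.

    Raises ValueError for non-finite or non-positive response times.
    """
    if not math.isfinite(response_time_ms) or response_time_ms <= 0:
        raise ValueError(f"invalid response time: {response_time_ms!r}")
    return window.contains(response_time_ms)


def apply_update(window: ToleranceWindow, correct: bool, rule: StaircaseRule) -> ToleranceWindow:
    """One staircase step.

    Correct: both boundaries move inward by half the shrink step; if the
    window is narrower than the full shrink step, both boundaries clamp to
    the midpoint (width 0). Incorrect: both boundaries move outward by half
    the widen step. Every non-clamped update preserves the midpoint.
    """
    if correct:
        if window.width_ms < rule.shrink_total_ms:
            mid = window.midpoint_ms
            return ToleranceWindow(mid, mid)
        half = 0.5 * rule.shrink_total_ms
        return ToleranceWindow(window.lower_ms + half, window.upper_ms - half)
    half = 0.5 * rule.widen_total_ms
    return ToleranceWindow(window.lower_ms - half, window.upper_ms + half)


def _scored_flags(n_trials: int, score_policy: str) -> List[bool]:
    if score_policy == "all":
        return [True] * n_trials
    if score_policy == "drop_first":
        return [False] + [True] * (n_trials - 1)
    if score_policy in ("none", "training"):
        return [False] * n_trials
    raise ValueError(f"unknown score_policy: {score_policy!r}")


def run_block(
    participant: "ParticipantParams",
    start_window: ToleranceWindow,
    n_trials: int,
    rule: StaircaseRule,
    score_policy: str = "drop_first",
    rng: np.random.Generator | None = None,
    first_trial_number: int = 0,
    responses: Sequence[float] | None = None,
) -> Tuple[List[TrialResult], ToleranceWindow]:
    """Run one block, threading the window through every trial.

    Responses do not depend on feedback (binary feedback carries no
    directional signal for the responder), so they are drawn up front from
    the participant model unless an explicit ``responses`` sequence is given.
    ``first_trial_number`` offsets the participant's drift clock so that
    drift is continuous across consecutive blocks.
    """
    from .participants import sample_block_responses

    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if responses is None:
        if rng is None:
            raise ValueError("either rng or responses must be provided")
        responses = sample_block_responses(
            participant, n_trials, rng, first_trial_number=first_trial_number
        )
    elif len(responses) != n_trials:
        raise ValueError("responses length must equal n_trials")

    flags = _scored_flags(n_trials, score_policy)
    results: List[TrialResult] = []
    window = start_window
    for i in range(n_trials):
        r = float(responses[i])
        correct = classify_response(r, window)
        after = apply_update(window, correct, rule)
        results.append(TrialResult(i, r, correct, window, after, flags[i]))
        window = after
    return results, window


def scored_accuracy(trials: Iterable[TrialResult]) -> float:
    """Percentage of correct feedback among scored trials."""
    scored = [t for t in trials if t.scored]
    if not scored:
        raise ValueError("no scored trials")
    return 100.0 * sum(t.correct for t in scored) / len(scored)


def raw_accuracy(trials: Sequence[TrialResult]) -> float:
    """Percentage of correct feedback over *all* trials (used for the
    exclusion rule, which pools the training block as well)."""
    if not trials:
        raise ValueError("no trials")
    return 100.0 * sum(t.correct for t in trials) / len(trials)
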