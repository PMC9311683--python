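"""Assemble staircase blocks into the four-condition expectation paradigm.

Every participant runs a 20-trial training block and two 80-trial
experimental blocks. Block 1 always uses the hard staircase (widen 3 /
shrink 12 ms), inducing a low rate of positive feedback. In block 2 the
confirmation condition keeps the hard rule while the three violation
conditions silently switch to the easy rule (widen 12 / shrink 3 ms); the
two instruction conditions differ from plain violation by label only. The
window resets to 990–1100 ms at the start of block 1 and carries over from
block 1 into block 2, preserving the implicit nature of the difficulty
switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .participants import CohortSpec, ParticipantParams, draw_cohort, sample_block_responses
from .staircase import (
    EASY,
    HARD,
    INITIAL_WINDOW,
    StaircaseRule,
    ToleranceWindow,
    TrialResult,
    raw_accuracy,
    run_block,
    scored_accuracy,
)

PHASES = ("training", "block1", "block2")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a label and its block rules."""

    label: str
    block2_rule: StaircaseRule
    block1_rule: StaircaseRule = HARD


CONFIRMATION = Condition("confirmation", HARD)
VIOLATION = Condition("violation", EASY)
VIOLATION_INHIBITING = Condition("violation_inhibiting", EASY)
VIOLATION_ENHANCING = Condition("violation_enhancing", EASY)

#: Canonical condition order: experiment 1 (confirmation, violation) then
#: experiment 2 (instruction conditions, violation feedback in both).
DEFAULT_CONDITIONS: Tuple[Condition, ...] = (
    CONFIRMATION,
    VIOLATION,
    VIOLATION_INHIBITING,
    VIOLATION_ENHANCING,
)

_BY_LABEL = {c.label: c for c in DEFAULT_CONDITIONS}


def condition_from_label(label: str) -> Condition:
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown condition label: {label!r}") from None


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure and window policy of the paradigm.

    Stimulus timing fields (cue, feedback, inter-trial interval) are
    descriptive metadata only; the simulator models trial outcomes, not
    real-time presentation.
    """

    training_trials: int = 20
    block_trials: int = 80
    initial_window: ToleranceWindow = INITIAL_WINDOW
    training_rule: StaircaseRule = HARD
    carry_training_to_block1: bool = False
    carry_block1_to_block2: bool = True
    cue_hz: float = 1000.0
    cue_duration_ms: float = 50.0
    feedback_duration_ms: float = 1000.0
    inter_trial_interval_ms: Tuple[float, float] = (1400.0, 1600.0)

    def __post_init__(self) -> None:
        if self.training_trials < 1 or self.block_trials < 1:
            raise ValueError("trial counts must be positive")


@dataclass
class ParticipantRecord:
    """All trials and summary accuracies of one simulated participant."""

    participant_id: str
    condition: str
    params: ParticipantParams
    seed: int
    trials: Dict[str, List[TrialResult]]
    accuracy_training: float
    accuracy_block1: float
    accuracy_block2: float
    excluded: bool = False
    exclusion_reason: str = ""


def run_participant(
    design: ExperimentDesign,
    condition: Condition,
    params: ParticipantParams,
    seed: int,
    participant_id: str = "p0",
) -> ParticipantRecord:
    """Simulate one participant through training, block 1 and block 2.

    The drift clock is continuous across phases (training trials come
    first). Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    training, w_train = run_block(
        params, design.initial_window, design.training_trials,
        design.training_rule, "none", rng, first_trial_number=0,
    )
    w1_start = w_train if design.carry_training_to_block1 else design.initial_window
    block1, w1_end = run_block(
        params, w1_start, design.block_trials, condition.block1_rule,
        "drop_first", rng, first_trial_number=design.training_trials,
    )
    w2_start = w1_end if design.carry_block1_to_block2 else design.initial_window
    block2, _ = run_block(
        params, w2_start, design.block_trials, condition.block2_rule,
        "drop_first", rng,
        first_trial_number=design.training_trials + design.block_trials,
    )
    return ParticipantRecord(
        participant_id=participant_id,
        condition=condition.label,
        params=params,
        seed=seed,
        trials={"training": training, "block1": block1, "block2": block2},
        accuracy_training=raw_accuracy(training),
        accuracy_block1=scored_accuracy(block1),
        accuracy_block2=scored_accuracy(block2),
    )


def _participant_seeds(master_seed: int, n: int) -> List[int]:
    """Stable per-participant integer seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1, np.uint32)[0]) % (2**31) for child in ss.spawn(n)]


def run_cohort(
    design: ExperimentDesign,
    conditions: Sequence[Condition],
    spec: CohortSpec,
) -> List[ParticipantRecord]:
    """Run a full cohort: ``spec.n_for(label)`` participants per condition.

    Seeds and parameter draws are derived deterministically from the spec's
    master seed, independently per condition (keyed by condition order).
    """
    records: List[ParticipantRecord] = []
    cond_seeds = _participant_seeds(spec.master_seed, 2 * len(conditions))
    for k, cond in enumerate(conditions):
        n = spec.n_for(cond.label)
        params_list = draw_cohort(spec, n=n, seed=cond_seeds[2 * k])
        seeds = _participant_seeds(cond_seeds[2 * k + 1], n)
        for i, (p, s) in enumerate(zip(params_list, seeds)):
            records.append(
                run_participant(
                    design, cond, p, s, participant_id=f"{cond.label}-{i + 1:03d}"
                )
            )
    return records


def apply_exclusions(
    records: Iterable[ParticipantRecord],
    min_accuracy_pct: float = 6.0,
    mode: str = "mean",
) -> Tuple[List[ParticipantRecord], List[Dict[str, str]]]:
    """Flag low-accuracy participants (<6% across all three blocks).

    ``mode="mean"`` (default) excludes when the mean accuracy over
    training, block 1 and block 2 falls below the threshold; ``mode="all"``
    requires every block to be below it. Returns (retained, exclusion log);
    excluded records keep their flag set so retained + excluded = input.
    """
    retained: List[ParticipantRecord] = []
    log: List[Dict[str, str]] = []
    for rec in records:
        accs = (rec.accuracy_training, rec.accuracy_block1, rec.accuracy_block2)
        if mode == "mean":
            low = float(np.mean(accs)) < min_accuracy_pct
        elif mode == "all":
            low = all(a < min_accuracy_pct for a in accs)
        else:
            raise ValueError(f"unknown exclusion mode: {mode!r}")
        if low:
            rec.excluded = True
            rec.exclusion_reason = (
                f"accuracy below {min_accuracy_pct}% across blocks "
                f"(training={accs[0]:.2f}, block1={accs[1]:.2f}, block2={accs[2]:.2f})"
            )
            log.append({"participant_id": rec.participant_id, "reason": rec.exclusion_reason})
        else:
            rec.excluded = False
            rec.exclusion_reason = ""
            retained.append(rec)
    return retained, log


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Per-participant summary table (one row per participant)."""
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "condition": r.condition,
            "accuracy_training": r.accuracy_training,
            "accuracy_block1": r.accuracy_block1,
            "accuracy_block2": r.accuracy_block2,
            "excluded": int(r.excluded),
            "exclusion_reason": r.exclusion_reason,
            "mean_ms": r.params.mean_ms,
            "sd_ms": r.params.sd_ms,
            "lapse_rate": r.params.lapse_rate,
            "lapse_spread_ms": r.params.lapse_spread_ms,
            "drift_ms_per_trial": r.params.drift_ms_per_trial,
            "seed": r.seed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vectorised replicate-study runner.
#
# Responses never depend on feedback, so each participant's full response
# stream can be drawn up front with exactly the RNG protocol of
# run_participant; the window threading is then vectorised across
# participants. The result is bitwise-identical to the per-trial path
# (asserted in the test suite) at a fraction of the cost, which makes
# multi-hundred-cohort replicate studies cheap.
# ---------------------------------------------------------------------------

def _advance_windows(
    lower: np.ndarray, upper: np.ndarray, hits: np.ndarray, rule: StaircaseRule
) -> Tuple[np.ndarray, np.ndarray]:
    half_s = 0.5 * rule.shrink_total_ms
    half_w = 0.5 * rule.widen_total_ms
    clamp = hits & ((upper - lower) < rule.shrink_total_ms)
    mid = 0.5 * (lower + upper)
    new_lower = np.where(hits, np.where(clamp, mid, lower + half_s), lower - half_w)
    new_upper = np.where(hits, np.where(clamp, mid, upper - half_s), upper + half_w)
    return new_lower, new_upper


def simulate_condition_accuracies(
    design: ExperimentDesign,
    condition: Condition,
    params_list: Sequence[ParticipantParams],
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Vectorised equivalent of run_participant for a list of participants.

    Returns a frame with training/block1/block2 accuracies per participant,
    numerically identical to the per-trial path under the same seeds.
    """
    if len(params_list) != len(seeds):
        raise ValueError("params_list and seeds must have equal length")
    n_p = len(params_list)
    nt, nb = design.training_trials, design.block_trials
    resp = np.empty((n_p, nt + 2 * nb))
    for i, (p, s) in enumerate(zip(params_list, seeds)):
        rng = np.random.default_rng(np.random.SeedSequence(s))
        resp[i, :nt] = sample_block_responses(p, nt, rng, first_trial_number=0)
        resp[i, nt:nt + nb] = sample_block_responses(p, nb, rng, first_trial_number=nt)
        resp[i, nt + nb:] = sample_block_responses(p, nb, rng, first_trial_number=nt + nb)

    lower = np.full(n_p, design.initial_window.lower_ms)
    upper = np.full(n_p, design.initial_window.upper_ms)
    accs: Dict[str, np.ndarray] = {}

    segments = (
        ("training", 0, nt, design.training_rule, False),
        ("block1", nt, nt + nb, condition.block1_rule, True),
        ("block2", nt + nb, nt + 2 * nb, condition.block2_rule, True),
    )
    for name, a, b, rule, drop_first in segments:
        if name == "block1" and not design.carry_training_to_block1:
            lower = np.full(n_p, design.initial_window.lower_ms)
            upper = np.full(n_p, design.initial_window.upper_ms)
        if name == "block2" and not design.carry_block1_to_block2:
            lower = np.full(n_p, design.initial_window.lower_ms)
            upper = np.full(n_p, design.initial_window.upper_ms)
        hit_count = np.zeros(n_p)
        n_scored = 0
        for t in range(a, b):
            r = resp[:, t]
            hits = (lower <= r) & (r <= upper)
            if not (drop_first and t == a):
                hit_count += hits
                n_scored += 1
            lower, upper = _advance_windows(lower, upper, hits, rule)
        accs[name] = 100.0 * hit_count / n_scored

    return pd.DataFrame({
        "accuracy_training": accs["training"],
        "accuracy_block1": accs["block1"],
        "accuracy_block2": accs["block2"],
    })


def run_replicate_study(
    design: ExperimentDesign,
    condition: Condition,
    spec: CohortSpec,
    n_cohorts: int,
    master_seed: int,
) -> pd.DataFrame:
    """Simulate many replicate cohorts of one condition.

    Returns one row per participant with a ``cohort`` column; cohort seeds
    are spawned deterministically from ``master_seed``.
    """
    frames = []
    cohort_seeds = _participant_seeds(master_seed, 2 * n_cohorts)
    for c in range(n_cohorts):
        n = spec.n_for(condition.label)
        params_list = draw_cohort(spec, n=n, seed=cohort_seeds[2 * c])
        seeds = _participant_seeds(cohort_seeds[2 * c + 1], n)
        df = simulate_condition_accuracies(design, condition, params_list, seeds)
        df.insert(0, "cohort", c)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
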