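"""Tiny deterministic cohorts for hand verification and unit tests."""

from __future__ import annotations

from typing import List, Tuple

from .experiment import (
    DEFAULT_CONDITIONS,
    ExperimentDesign,
    ParticipantRecord,
    run_participant,
)
from .participants import ParticipantParams

#: Fixture design: 5-trial blocks, small enough to recount by hand.
FIXTURE_DESIGN = ExperimentDesign(training_trials=5, block_trials=5)

#: Three responder archetypes per condition: accurate, noisy, and one whose
#: responses never reach the window (trips the low-accuracy exclusion rule).
_FIXTURE_PARAMS = (
    ParticipantParams(mean_ms=1045.0, sd_ms=30.0, lapse_rate=0.0),
    ParticipantParams(mean_ms=1100.0, sd_ms=120.0, lapse_rate=0.0),
    ParticipantParams(mean_ms=2500.0, sd_ms=10.0, lapse_rate=0.0),
)


def make_fixture(seed: int = 0) -> Tuple[List[ParticipantRecord], ExperimentDesign]:
    """Deterministic 4-condition x 3-participant cohort with 5-trial blocks.

    Stable across releases for a given seed; the third participant of every
    condition responds around 2.5 s and scores ~0%, exercising the <6%
    exclusion rule.
    """
    records: List[ParticipantRecord] = []
    for ci, cond in enumerate(DEFAULT_CONDITIONS):
        for pi, params in enumerate(_FIXTURE_PARAMS):
            records.append(
                run_participant(
                    FIXTURE_DESIGN,
                    cond,
                    params,
                    seed=seed * 1000 + ci * 10 + pi,
                    participant_id=f"{cond.label}-{pi + 1:03d}",
                )
            )
    return records, FIXTURE_DESIGN
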