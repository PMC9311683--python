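import numpy as np
import pandas as pd
import pytest

from stairtask import CohortSpec, ExperimentDesign, ParticipantParams

#: Published group means (block1, block2) of accuracy (%), used as inputs for
#: worked-example contrast checks.
TABLE2_MEANS = {
    "confirmation": (15.73, 16.46),
    "violation": (17.18, 53.66),
    "violation_inhibiting": (17.24, 50.46),
    "violation_enhancing": (15.96, 49.55),
}

TABLE2_NS = {
    "confirmation": 28,
    "violation": 28,
    "violation_inhibiting": 29,
    "violation_enhancing": 28,
}


@pytest.fixture
def table2_means():
    return dict(TABLE2_MEANS)


@pytest.fixture
def default_design():
    return ExperimentDesign()


@pytest.fixture
def small_design():
    return ExperimentDesign(training_trials=5, block_trials=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulated_wide_frame(
    n_per_group=10,
    group_means=((10.0, 12.0), (20.0, 22.0), (15.0, 30.0), (18.0, 25.0)),
    sd=4.0,
    seed=0,
):
    """Synthetic per-participant accuracy frame for ANOVA tests."""
    gen = np.random.default_rng(seed)
    labels = ["confirmation", "violation", "violation_inhibiting", "violation_enhancing"]
    rows = []
    for lab, (m1, m2) in zip(labels, group_means):
        for i in range(n_per_group):
            rows.append({
                "participant_id": f"{lab}-{i}",
                "condition": lab,
                "accuracy_block1": gen.normal(m1, sd),
                "accuracy_block2": gen.normal(m2, sd),
            })
    return pd.DataFrame(rows)
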