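"""Generative models of synthetic interval-reproduction responders.

Each responder produces interval reproductions around 1 s following a
truncated-normal law with an optional lapse mixture: with probability
``lapse_rate`` the response is drawn from a much wider distribution centred
on the same mean, emulating off-task key presses. ``sd_ms`` around 10% of
the interval reflects the scalar-timing (Weber fraction) regularity of human
interval production. Binary feedback carries no directional information, so
the model has no feedback-driven recalibration; a linear drift term is the
only non-stationarity offered.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import List, Mapping, Tuple, Union

import numpy as np

FieldSpec = Union[float, Tuple[float, float]]


@dataclass(frozen=True)
class ParticipantParams:
    """Parameters of one synthetic responder (all times in ms)."""

    mean_ms: float = 1000.0
    sd_ms: float = 100.0
    lapse_rate: float = 0.02
    lapse_spread_ms: float = 500.0
    drift_ms_per_trial: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_ms <= 0:
            raise ValueError("mean_ms must be positive")
        if self.sd_ms < 0:
            raise ValueError("sd_ms must be non-negative")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must be in [0, 1)")
        if self.lapse_rate > 0 and self.lapse_spread_ms < 0:
            raise ValueError("lapse_spread_ms must be non-negative")


def sample_block_responses(
    params: ParticipantParams,
    n: int,
    rng: np.random.Generator,
    first_trial_number: int = 0,
) -> np.ndarray:
    """Draw ``n`` responses (ms) for trials ``first_trial_number ...``.

    Draw order is fixed (base normals, lapse uniforms, lapse normals,
    truncation redraws) so that any caller using the same generator state
    reproduces the identical stream. Responses are truncated at > 0 by
    redrawing the offending elements from their own mixture component.
    """
    means = params.mean_ms + (first_trial_number + np.arange(n)) * params.drift_ms_per_trial
    out = rng.normal(means, params.sd_ms)
    sds = np.full(n, params.sd_ms)
    if params.lapse_rate > 0:
        lapse = rng.random(n) < params.lapse_rate
        lapse_vals = rng.normal(means, params.lapse_spread_ms)
        out = np.where(lapse, lapse_vals, out)
        sds = np.where(lapse, params.lapse_spread_ms, sds)
    bad = out <= 0
    while bad.any():
        # redraw offending elements from their own component; terminates a.s. for mean > 0
        out = np.where(bad, rng.normal(means, sds), out)
        bad = out <= 0
    return out


def sample_response(
    params: ParticipantParams, trial_number: int, rng: np.random.Generator
) -> float:
    """One response (ms) for the given trial number."""
    return float(sample_block_responses(params, 1, rng, first_trial_number=trial_number)[0])


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a cohort of responders.

    Each parameter field is either a fixed value or a ``(low, high)``
    interval sampled uniformly per participant. ``n_per_condition`` is an
    int, or a mapping from condition label to int for unbalanced designs
    (e.g. 28/28/29/28).
    """

    n_per_condition: Union[int, Mapping[str, int]] = 28
    mean_ms: FieldSpec = 1000.0
    sd_ms: FieldSpec = 100.0
    lapse_rate: FieldSpec = 0.02
    lapse_spread_ms: FieldSpec = 500.0
    drift_ms_per_trial: FieldSpec = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        ns = (
            [self.n_per_condition]
            if isinstance(self.n_per_condition, int)
            else list(self.n_per_condition.values())
        )
        if any(n < 1 for n in ns):
            raise ValueError("n_per_condition must be >= 1")

    def n_for(self, condition_label: str) -> int:
        if isinstance(self.n_per_condition, int):
            return self.n_per_condition
        return self.n_per_condition[condition_label]

    def param_spec(self) -> Mapping[str, FieldSpec]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(ParticipantParams)
        }


def draw_cohort(
    spec: CohortSpec,
    n: int | None = None,
    seed: int | None = None,
) -> List[ParticipantParams]:
    """Sample participant parameter sets from a cohort spec.

    Fixed-valued fields are copied verbatim; interval fields are sampled
    uniformly. Reproducible from the seed (defaults to the spec's
    master_seed).
    """
    if n is None:
        if not isinstance(spec.n_per_condition, int):
            raise ValueError("n must be given when n_per_condition is a mapping")
        n = spec.n_per_condition
    rng = np.random.default_rng(np.random.SeedSequence(
        spec.master_seed if seed is None else seed
    ))
    out = []
    for _ in range(n):
        kwargs = {}
        for name, fs in spec.param_spec().items():
            if isinstance(fs, tuple):
                lo, hi = fs
                kwargs[name] = float(rng.uniform(lo, hi))
            else:
                kwargs[name] = float(fs)
        out.append(ParticipantParams(**kwargs))
    return out
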