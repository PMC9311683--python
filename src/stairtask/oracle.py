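"""Exact dynamics of the staircase: closed forms and Markov forward pass.

Because a response never depends on earlier feedback, the tolerance window
follows a Markov chain on window states: at each trial the current window is
hit with a probability given in closed form by the responder's response law,
and the two outcomes map deterministically to the widened/shrunk child
windows. Propagating a probability distribution over reachable windows
therefore yields the *exact* expected per-trial hit probability — an
independent oracle for the Monte-Carlo simulator — and supports calibrating
responder parameters to a target block accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import ndtr

from .participants import ParticipantParams
from .staircase import HARD, INITIAL_WINDOW, StaircaseRule, ToleranceWindow, apply_update

_KEY_DECIMALS = 6  # merge floating-point-identical window states


class StateExplosionError(RuntimeError):
    """Raised when the forward pass exceeds its state cap."""


class CalibrationError(ValueError):
    """Raised when no parameter setting reaches the calibration target."""


def _window_key(w: ToleranceWindow) -> Tuple[float, float]:
    return (round(w.lower_ms, _KEY_DECIMALS), round(w.upper_ms, _KEY_DECIMALS))


@dataclass
class WindowStateDistribution:
    """Probability mass over reachable tolerance-window states."""

    states: Dict[Tuple[float, float], float]
    pruned_mass: float = 0.0

    @classmethod
    def from_window(cls, window: ToleranceWindow) -> "WindowStateDistribution":
        return cls(states={_window_key(window): 1.0})

    @property
    def total_mass(self) -> float:
        return sum(self.states.values())

    def expected_width(self) -> float:
        m = self.total_mass
        return sum(p * (u - l) for (l, u), p in self.states.items()) / m


def _truncated_normal_window_prob(
    mean: float, sd: float, lower: float, upper: float
) -> float:
    """P(lower <= X <= upper) for X ~ Normal(mean, sd) truncated at X > 0."""
    if sd == 0:
        return 1.0 if lower <= mean <= upper else 0.0
    z_lo = (lower - mean) / sd
    z_hi = (upper - mean) / sd
    denom = 1.0 - ndtr(-mean / sd)
    if denom <= 0:  # mean > 0 is enforced upstream; guard anyway
        return 0.0
    return float(max(0.0, ndtr(z_hi) - ndtr(max(z_lo, -mean / sd))) / denom)


def hit_probability(
    params: ParticipantParams,
    window: ToleranceWindow,
    trial_number: int = 0,
) -> float:
    """Closed-form probability that a response lands in the window.

    Mixture of the base truncated-normal law and the lapse law, both centred
    on the (possibly drifted) mean. A zero-width window has probability 0
    under any continuous component; sd = 0 degenerates to a point mass.
    """
    mean = params.mean_ms + trial_number * params.drift_ms_per_trial
    base = _truncated_normal_window_prob(mean, params.sd_ms, window.lower_ms, window.upper_ms)
    if params.lapse_rate == 0:
        return base
    lapse = _truncated_normal_window_prob(
        mean, params.lapse_spread_ms, window.lower_ms, window.upper_ms
    )
    return (1.0 - params.lapse_rate) * base + params.lapse_rate * lapse


def equilibrium_hit_rate(rule: StaircaseRule) -> float:
    """Hit rate at which the expected window-width change vanishes:
    ``widen / (widen + shrink)``."""
    return rule.equilibrium_hit_rate


@dataclass
class TrajectoryResult:
    """Output of a forward pass over one block."""

    per_trial_hit_probability: np.ndarray
    expected_scored_accuracy_pct: Optional[float]
    final_distribution: WindowStateDistribution

    @property
    def pruned_mass(self) -> float:
        return self.final_distribution.pruned_mass


def forward_accuracy_trajectory(
    params: ParticipantParams,
    start: Union[ToleranceWindow, WindowStateDistribution],
    rule: StaircaseRule,
    n_trials: int,
    drop_first: bool = True,
    first_trial_number: int = 0,
    prune_threshold: float = 1e-12,
    max_states: int = 1_000_000,
) -> TrajectoryResult:
    """Propagate the window-state distribution trial by trial.

    Each state branches into its hit/miss children weighted by the
    closed-form hit probability. Expected scored accuracy is the mean
    per-trial hit probability over scored trials (None if none are scored).
    ``start`` may be a window or a distribution, so block 2 can continue
    from block 1's final distribution. States with mass below the pruning
    threshold are dropped and their mass accounted in ``pruned_mass``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(start, ToleranceWindow):
        dist = WindowStateDistribution.from_window(start)
    else:
        dist = WindowStateDistribution(states=dict(start.states),
                                       pruned_mass=start.pruned_mass)

    stationary = params.drift_ms_per_trial == 0
    hit_cache: Dict[Tuple[float, float], float] = {}
    probs: List[float] = []

    for t in range(n_trials):
        trial_no = first_trial_number + t
        new_states: Dict[Tuple[float, float], float] = {}
        p_hit_total = 0.0
        for key, mass in dist.states.items():
            if stationary and key in hit_cache:
                h = hit_cache[key]
            else:
                h = hit_probability(params, ToleranceWindow(*key), trial_no)
                if stationary:
                    hit_cache[key] = h
            p_hit_total += mass * h
            w = ToleranceWindow(*key)
            k_hit = _window_key(apply_update(w, True, rule))
            k_miss = _window_key(apply_update(w, False, rule))
            if h > 0:
                new_states[k_hit] = new_states.get(k_hit, 0.0) + mass * h
            if h < 1:
                new_states[k_miss] = new_states.get(k_miss, 0.0) + mass * (1.0 - h)
        total = sum(new_states.values()) + dist.pruned_mass
        kept = {k: v for k, v in new_states.items() if v >= prune_threshold}
        pruned = dist.pruned_mass + (total - dist.pruned_mass - sum(kept.values()))
        if len(kept) > max_states:
            raise StateExplosionError(
                f"{len(kept)} window states exceed cap {max_states}; "
                "raise prune_threshold for a coarser pass"
            )
        probs.append(p_hit_total / dist.total_mass)
        dist = WindowStateDistribution(states=kept, pruned_mass=pruned)

    arr = np.asarray(probs)
    scored = arr[1:] if drop_first else arr
    acc = float(100.0 * scored.mean()) if scored.size else None
    return TrajectoryResult(arr, acc, dist)


def predicted_block_accuracy(
    params: ParticipantParams,
    start: Union[ToleranceWindow, WindowStateDistribution] = INITIAL_WINDOW,
    rule: StaircaseRule = HARD,
    n_trials: int = 80,
    drop_first: bool = True,
) -> float:
    """Oracle-predicted scored accuracy (%) of one block."""
    res = forward_accuracy_trajectory(params, start, rule, n_trials, drop_first=drop_first)
    assert res.expected_scored_accuracy_pct is not None
    return res.expected_scored_accuracy_pct


def predicted_condition_accuracies(
    params: ParticipantParams,
    design: "ExperimentDesign",
    condition: "Condition",
) -> Tuple[float, float]:
    """Oracle-predicted (block 1, block 2) scored accuracies for a condition,
    chaining block 2 from block 1's final window distribution."""
    b1 = forward_accuracy_trajectory(
        params, design.initial_window, condition.block1_rule, design.block_trials,
        drop_first=True, first_trial_number=design.training_trials,
    )
    start2: Union[ToleranceWindow, WindowStateDistribution]
    start2 = b1.final_distribution if design.carry_block1_to_block2 else design.initial_window
    b2 = forward_accuracy_trajectory(
        params, start2, condition.block2_rule, design.block_trials,
        drop_first=True,
        first_trial_number=design.training_trials + design.block_trials,
    )
    return b1.expected_scored_accuracy_pct, b2.expected_scored_accuracy_pct  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    params: ParticipantParams
    achieved_accuracy_pct: float
    target_accuracy_pct: float


DEFAULT_BOUNDS = {
    "mean_ms": (1045.0, 1345.0),  # window midpoint upward (late-response bias)
    "sd_ms": (50.0, 200.0),
}


def _solve_1d(
    objective,
    target: float,
    bounds: Tuple[float, float],
    tol: float,
    n_grid: int = 25,
) -> Optional[Tuple[float, float]]:
    """Find x with |objective(x) - target| <= tol via grid bracket + brentq.

    Returns (x, achieved) or None. The objective need not be monotone; the
    first sign-change bracket on the grid is refined.
    """
    from scipy.optimize import brentq

    xs = np.linspace(bounds[0], bounds[1], n_grid)
    fs = np.array([objective(x) for x in xs])
    # direct grid hit
    best = int(np.argmin(np.abs(fs - target)))
    if abs(fs[best] - target) <= tol * 0.1:
        return float(xs[best]), float(fs[best])
    for i in range(n_grid - 1):
        if (fs[i] - target) * (fs[i + 1] - target) <= 0:
            root = brentq(lambda x: objective(x) - target, xs[i], xs[i + 1], xtol=1e-6)
            achieved = objective(root)
            if abs(achieved - target) <= tol:
                return float(root), float(achieved)
    if abs(fs[best] - target) <= tol:
        return float(xs[best]), float(fs[best])
    return None


def calibrate_params(
    target_accuracy_pct: float,
    free_fields: Sequence[str] = ("mean_ms", "sd_ms"),
    base: ParticipantParams = ParticipantParams(),
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    start_window: ToleranceWindow = INITIAL_WINDOW,
    rule: StaircaseRule = HARD,
    n_trials: int = 80,
    drop_first: bool = True,
    tol_pct: float = 0.5,
    preferred_sd_ms: float = 100.0,
) -> CalibrationResult:
    """Find responder parameters whose oracle-predicted block accuracy
    matches the target within ``tol_pct`` percentage points.

    With both ``mean_ms`` and ``sd_ms`` free the problem is
    under-determined; ``sd_ms`` candidates are tried in order of closeness
    to ``preferred_sd_ms`` (scalar-timing convention: ~10% of the 1-s
    interval) and the mean solved by root finding. Raises CalibrationError
    with the attainable range if the target cannot be reached.
    """
    if not 0.0 < target_accuracy_pct < 100.0:
        raise ValueError("target accuracy must be in (0, 100)")
    if not free_fields:
        raise ValueError("at least one free field required")
    for f in free_fields:
        if f not in ("mean_ms", "sd_ms"):
            raise ValueError(f"unsupported free field: {f!r}")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}

    def acc(p: ParticipantParams) -> float:
        return predicted_block_accuracy(p, start_window, rule, n_trials, drop_first)

    observed: List[float] = []

    def objective_over(field: str, fixed: ParticipantParams):
        def f(x: float) -> float:
            a = acc(replace(fixed, **{field: float(x)}))
            observed.append(a)
            return a
        return f

    solutions: List[CalibrationResult] = []
    if set(free_fields) == {"mean_ms", "sd_ms"}:
        lo, hi = bounds["sd_ms"]
        sd_grid = sorted(
            np.unique(np.append(np.linspace(lo, hi, 9), np.clip(preferred_sd_ms, lo, hi))),
            key=lambda s: abs(s - preferred_sd_ms),
        )
        for sd in sd_grid:
            fixed = replace(base, sd_ms=float(sd))
            hit = _solve_1d(objective_over("mean_ms", fixed), target_accuracy_pct,
                            bounds["mean_ms"], tol_pct)
            if hit is not None:
                x, achieved = hit
                solutions.append(CalibrationResult(
                    replace(fixed, mean_ms=x), achieved, target_accuracy_pct))
                break
    else:
        field_name = free_fields[0]
        hit = _solve_1d(objective_over(field_name, base), target_accuracy_pct,
                        bounds[field_name], tol_pct)
        if hit is not None:
            x, achieved = hit
            solutions.append(CalibrationResult(
                replace(base, **{field_name: x}), achieved, target_accuracy_pct))

    if solutions:
        return solutions[0]
    lo_a, hi_a = (min(observed), max(observed)) if observed else (math.nan, math.nan)
    raise CalibrationError(
        f"target {target_accuracy_pct}% unattainable within bounds; "
        f"attainable range over the search grid was [{lo_a:.2f}%, {hi_a:.2f}%]"
    )
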