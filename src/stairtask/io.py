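"""CSV interchange and declarative run configuration.

CSV is the single interchange format: trial-level logs, per-participant
summaries, group summaries and analysis outputs. Every file starts with a
schema-tag comment line (``# schema=stairtask.<kind>.v1``); readers reject
unknown tags loudly so silent schema drift cannot happen. Writes are atomic
(tempfile + rename). Run configurations are YAML with a lossless
dict round trip.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .experiment import (
    DEFAULT_CONDITIONS,
    Condition,
    ExperimentDesign,
    ParticipantRecord,
    condition_from_label,
    records_to_frame,
)
from .participants import CohortSpec
from .staircase import ToleranceWindow

TRIALS_SCHEMA = "stairtask.trials.v1"
PARTICIPANTS_SCHEMA = "stairtask.participants.v1"
GROUP_SUMMARY_SCHEMA = "stairtask.group_summary.v1"
CONTRASTS_SCHEMA = "stairtask.contrasts.v1"
ANOVA_SCHEMA = "stairtask.anova.v1"


class SchemaError(ValueError):
    """Unknown or missing schema tag in a CSV file."""


def _atomic_write_text(path: Union[str, Path], text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: Union[str, Path], schema: str) -> None:
    """Write a schema-tagged CSV atomically (UTF-8, '.' decimal separator)."""
    text = f"# schema={schema}\n" + df.to_csv(index=False)
    _atomic_write_text(path, text)


def read_csv(path: Union[str, Path], schema: str) -> pd.DataFrame:
    """Read a schema-tagged CSV, rejecting unknown tags."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != f"# schema={schema}":
            raise SchemaError(
                f"{path}: expected tag '# schema={schema}', found {first!r}"
            )
        return pd.read_csv(fh)


def trials_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Trial-level long table: one row per trial, window bounds are the
    window the response was judged against."""
    rows = []
    for rec in records:
        for phase, trials in rec.trials.items():
            for t in trials:
                rows.append({
                    "participant_id": rec.participant_id,
                    "condition": rec.condition,
                    "phase": phase,
                    "trial_index": t.trial_index,
                    "scored": int(t.scored),
                    "response_time_ms": t.response_time_ms,
                    "lower_ms": t.window_before.lower_ms,
                    "upper_ms": t.window_before.upper_ms,
                    "feedback": int(t.correct),
                    "seed": rec.seed,
                })
    return pd.DataFrame(rows)


def write_trials_csv(records: Iterable[ParticipantRecord], path: Union[str, Path]) -> None:
    write_csv(trials_frame(records), path, TRIALS_SCHEMA)


def read_trials_csv(path: Union[str, Path]) -> pd.DataFrame:
    return read_csv(path, TRIALS_SCHEMA)


def write_participants_csv(records: Iterable[ParticipantRecord], path: Union[str, Path]) -> None:
    write_csv(records_to_frame(records), path, PARTICIPANTS_SCHEMA)


def read_participants_csv(path: Union[str, Path]) -> pd.DataFrame:
    return read_csv(path, PARTICIPANTS_SCHEMA)


def participants_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-participant block accuracies from a trial-level table."""
    rows = []
    for (pid, cond), sub in trials.groupby(["participant_id", "condition"], sort=False):
        row = {"participant_id": pid, "condition": cond, "excluded": 0}
        for phase in ("training", "block1", "block2"):
            ph = sub[sub["phase"] == phase]
            if ph.empty:
                raise ValueError(f"participant {pid!r}: missing phase {phase!r}")
            if phase == "training":
                row["accuracy_training"] = 100.0 * ph["feedback"].mean()
            else:
                scored = ph[ph["scored"] == 1]
                if scored.empty:
                    raise ValueError(f"participant {pid!r}: no scored trials in {phase!r}")
                row[f"accuracy_{phase}"] = 100.0 * scored["feedback"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of one simulation run."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    conditions: Tuple[str, ...] = tuple(c.label for c in DEFAULT_CONDITIONS)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    exclusion_min_accuracy_pct: float = 6.0
    exclusion_mode: str = "mean"

    def condition_objects(self) -> List[Condition]:
        return [condition_from_label(lab) for lab in self.conditions]

    def to_dict(self) -> Dict:
        d = self.design
        n = self.cohort.n_per_condition
        return {
            "design": {
                "training_trials": d.training_trials,
                "block_trials": d.block_trials,
                "initial_window": [d.initial_window.lower_ms, d.initial_window.upper_ms],
                "training_rule": d.training_rule.name,
                "carry_training_to_block1": d.carry_training_to_block1,
                "carry_block1_to_block2": d.carry_block1_to_block2,
            },
            "conditions": list(self.conditions),
            "cohort": {
                "n_per_condition": dict(n) if isinstance(n, Mapping) else n,
                "mean_ms": _field_to_yaml(self.cohort.mean_ms),
                "sd_ms": _field_to_yaml(self.cohort.sd_ms),
                "lapse_rate": _field_to_yaml(self.cohort.lapse_rate),
                "lapse_spread_ms": _field_to_yaml(self.cohort.lapse_spread_ms),
                "drift_ms_per_trial": _field_to_yaml(self.cohort.drift_ms_per_trial),
                "master_seed": self.cohort.master_seed,
            },
            "exclusion": {
                "min_accuracy_pct": self.exclusion_min_accuracy_pct,
                "mode": self.exclusion_mode,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        try:
            dd = d.get("design", {})
            win = dd.get("initial_window", [990.0, 1100.0])
            from .staircase import RULES
            design = ExperimentDesign(
                training_trials=int(dd.get("training_trials", 20)),
                block_trials=int(dd.get("block_trials", 80)),
                initial_window=ToleranceWindow(float(win[0]), float(win[1])),
                training_rule=RULES[dd.get("training_rule", "hard")],
                carry_training_to_block1=bool(dd.get("carry_training_to_block1", False)),
                carry_block1_to_block2=bool(dd.get("carry_block1_to_block2", True)),
            )
            cd = d.get("cohort", {})
            cohort = CohortSpec(
                n_per_condition=cd.get("n_per_condition", 28),
                mean_ms=_field_from_yaml(cd.get("mean_ms", 1000.0)),
                sd_ms=_field_from_yaml(cd.get("sd_ms", 100.0)),
                lapse_rate=_field_from_yaml(cd.get("lapse_rate", 0.02)),
                lapse_spread_ms=_field_from_yaml(cd.get("lapse_spread_ms", 500.0)),
                drift_ms_per_trial=_field_from_yaml(cd.get("drift_ms_per_trial", 0.0)),
                master_seed=int(cd.get("master_seed", 0)),
            )
            ed = d.get("exclusion", {})
            return cls(
                design=design,
                conditions=tuple(d.get("conditions", [c.label for c in DEFAULT_CONDITIONS])),
                cohort=cohort,
                exclusion_min_accuracy_pct=float(ed.get("min_accuracy_pct", 6.0)),
                exclusion_mode=str(ed.get("mode", "mean")),
            )
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise ValueError(f"invalid config: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _field_to_yaml(v):
    return list(v) if isinstance(v, tuple) else v


def _field_from_yaml(v):
    return tuple(float(x) for x in v) if isinstance(v, (list, tuple)) else float(v)


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig.from_yaml(fh.read())


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    _atomic_write_text(path, cfg.to_yaml())


def write_manifest(path: Union[str, Path], cfg: RunConfig, seed: int) -> None:
    """Provenance record of a run: config hash, seed, package version."""
    from . import __version__

    manifest = {
        "schema": "stairtask.manifest.v1",
        "config_hash": cfg.config_hash(),
        "master_seed": seed,
        "stairtask_version": __version__,
        "config": cfg.to_dict(),
    }
    _atomic_write_text(path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
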