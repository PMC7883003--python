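"""Tidy-CSV trial schema and config serialization.

One row per trial; the column set is the stable on-disk contract shared by
the task simulator, the synthetic cohort generator, and every analysis
stage (and is the shape an OSF-style tidy export of the original data
would be massaged into).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .task import ExperimentConfig, config_to_dict

#: canonical column order of the tidy trial table
TRIAL_COLUMNS = [
    "participant_id",
    "experiment_id",
    "trial_index",
    "is_practice",
    "pump_value",
    "n_pumps",
    "limit",
    "outcome",
    "points",
    "info_sought",
    "info_received",
    "try_harder",
    "outcome_rating",
    "emotion_change",
    "cost_type",
    "cost_amount",
    "time_penalty_s",
]

_BOOL_COLUMNS = ["is_practice", "info_sought", "info_received", "try_harder"]
_INT_COLUMNS = ["trial_index", "pump_value", "n_pumps", "limit", "points"]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    return trials[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trials(trials).to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    trials = validate_trials(trials)
    for c in _BOOL_COLUMNS:
        trials[c] = trials[c].astype(bool)
    for c in _INT_COLUMNS:
        trials[c] = trials[c].astype(int)
    return trials


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not hold a mapping")
    return ExperimentConfig(**data)


def dump_experiment_config(config: ExperimentConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
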