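"""File formats, configuration, and run manifests.

CSV dialect everywhere: UTF-8, comma delimiter, '.' decimal, mandatory
header row, empty field = missing value. Trial tables use the canonical
column order from :mod:`rlwmlba.task`; indices (actions, trials) are
0-based.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import PARAM_NAMES
from .task import TRIAL_COLUMNS


class SchemaError(ValueError):
    """A file violated the declared schema; the message names the location."""


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

_INT_COLUMNS = ["action", "reward", "iteration", "delay", "reward_history"]


def write_trials(trials: pd.DataFrame, path) -> None:
    df = trials[TRIAL_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")


def _validate_trials(df: pd.DataFrame, path) -> None:
    answered = df[df["action"].notna()]
    mismatch = answered["reward"] != (
        answered["action"] == answered["correct_action"]
    ).astype(int)
    if mismatch.any():
        row = int(answered.index[mismatch][0]) + 2  # header + 1-based
        raise SchemaError(
            f"{path}, row {row}: reward inconsistent with deterministic feedback "
            "(reward must be 1 iff action == correct_action)"
        )
    delays = df["delay"].dropna()
    if len(delays):
        bounds = df.loc[delays.index, "set_size"] * 2
        bad = (delays < 1) | (delays > bounds)
        if bad.any():
            row = int(delays.index[bad][0]) + 2
            raise SchemaError(
                f"{path}, row {row}: delay outside [1, 2 * set_size]"
            )


def read_trials(path, validate: bool = True) -> pd.DataFrame:
    """Read a trial CSV; round-trip stable with :func:`write_trials`."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unexpected columns {extra}")
    df = df[TRIAL_COLUMNS]
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    for col in (
        "subject_id", "block", "trial_in_block", "set_size",
        "stimulus_id", "correct_action",
    ):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2
            raise SchemaError(f"{path}, row {row}: column {col!r} must not be empty")
        df[col] = df[col].astype(np.int64)
    df["rt"] = df["rt"].astype(float)
    if validate and len(df):
        _validate_trials(df, path)
    return df


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------


def write_params(params: pd.DataFrame, path) -> None:
    params[["subject_id", *PARAM_NAMES]].to_csv(path, index=False)


def read_params(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *PARAM_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: fixed model constants; overriding them requires the explicit escape hatch
FIXED_CONSTANTS = {"beta": 50.0, "tau": 0.15, "s": 1.0}

DEFAULTS = {
    "task": {"uniformity_alpha": 0.01, "max_attempts": 10_000},
    "model": {"beta": 50.0, "tau": 0.15, "s": 1.0, "h_floor": 0.01},
    "fit": {"restarts": 4, "max_iter": 2000, "tol": 1e-8, "jitter": 0.25},
    "cohort": {
        "age_mean": 17.76,
        "age_sd": 2.42,
        "age_min": 12.35,
        "age_max": 24.31,
        "male_prob": 0.28,
        "group_sd": 0.5,
    },
    "regression": {"chains": 4, "draws": 5000, "warmup": 1000},
    "prediction": {"n_repeats": 100, "test_frac": 0.2, "k_folds": 10, "n_bins": 5},
    "allow_fixed_override": False,
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        full = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {full!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"configuration key {full!r} must be a mapping")
            out[key] = _merge(defaults[key], value, full)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: Optional[dict] = None) -> dict:
    """Load JSON/YAML configuration, fill defaults, and reject unknown keys.

    The fixed constants (beta, tau, s) may only be changed when
    ``allow_fixed_override`` is set explicitly.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
    if overrides:
        for key, value in overrides.items():
            node = user
            parts = key.split(".")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = value
    config = _merge(DEFAULTS, user)
    if not config["allow_fixed_override"]:
        for name, fixed_value in FIXED_CONSTANTS.items():
            if config["model"][name] != fixed_value:
                raise ConfigError(
                    f"model.{name} is a fixed constant ({fixed_value}); "
                    "set allow_fixed_override to change it"
                )
    return config


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path,
    command: str,
    config: dict,
    seeds: dict,
    inputs: Optional[list] = None,
    outputs: Optional[list] = None,
) -> dict:
    """Write the per-run manifest: command, config echo, seeds, checksums."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seeds": seeds,
        "config": config,
        "inputs": {str(p): _checksum(p) for p in (inputs or []) if Path(p).exists()},
        "outputs": {str(p): _checksum(p) for p in (outputs or []) if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
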