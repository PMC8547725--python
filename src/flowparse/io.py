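"""CSV schemas, configuration, and run manifests.

All tables are plain UTF-8 comma-delimited CSV with a header row; the trial
table carries one 2IFC trial per row, the rating table one self-motion
rating per row.  ``RunManifest`` records the config snapshot, seeds, and a
SHA-256 digest of every artifact a pipeline run writes, so each numeric
output is traceable to (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "TRIAL_COLUMNS",
    "RATING_COLUMNS",
    "read_trials",
    "write_trials",
    "read_ratings",
    "write_ratings",
    "load_config",
    "RunManifest",
]

TRIAL_COLUMNS = {
    "subject_id": str,
    "condition": ("main", "blank_wall", "moving_wall"),
    "motion_profile": ("static", "same", "opposite"),
    "standard_speed_mps": float,
    "comparison_speed_mps": float,
    "response": (0, 1),
    "staircase_id": str,
    "thread": ("high", "low"),
    "trial_index": int,
}

RATING_COLUMNS = {
    "subject_id": str,
    "condition": ("regular", "blank_wall", "moving_wall"),
    "rating": float,
}


class SchemaError(ValueError):
    pass


def _validate(df: pd.DataFrame, schema: dict, path) -> pd.DataFrame:
    unknown = set(df.columns) - set(schema)
    missing = set(schema) - set(df.columns)
    if unknown or missing:
        raise SchemaError(
            f"{path}: unexpected columns {sorted(unknown)}, missing {sorted(missing)}"
        )
    for col, kind in schema.items():
        if isinstance(kind, tuple):
            allowed = set(kind)
            bad = ~df[col].isin(allowed)
            if bad.any():
                row = int(df.index[bad][0])
                raise SchemaError(
                    f"{path}: invalid value {df[col][bad].iloc[0]!r} in column "
                    f"{col!r} at row {row}"
                )
        elif kind in (float, int):
            try:
                df[col] = df[col].astype(kind)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}: column {col!r} is not {kind.__name__}: {exc}")
        else:
            df[col] = df[col].astype(str)
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; raises SchemaError on violations."""
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty trial table")
    df = _validate(df, TRIAL_COLUMNS, path)
    if (df["comparison_speed_mps"] <= 0).any():
        raise SchemaError(f"{path}: comparison speeds must be positive")
    return df


def write_trials(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))
    return path


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty rating table")
    df = _validate(df, RATING_COLUMNS, path)
    if ((df["rating"] < -1) | (df["rating"] > 1)).any():
        raise SchemaError(f"{path}: ratings must lie in [-1, 1]")
    return df


def write_ratings(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=list(RATING_COLUMNS))
    return path


def load_config(path) -> dict:
    """Load a (nestable key-value) YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    package_version: str = "0.1.0"
    artifacts: dict = field(default_factory=dict)
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def record(self, path) -> None:
        path = Path(path)
        self.artifacts[str(path)] = _sha256(path)

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "package_version": self.package_version,
                    "started": self.started,
                    "artifacts": self.artifacts,
                },
                fh,
                indent=2,
                default=str,
            )
        return path
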