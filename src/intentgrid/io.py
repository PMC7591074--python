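"""CSV readers/writers and run configuration.

The interchange formats are plain CSV: a long trial table (one row per
trial, 18 per participant) and a parameter table (one row per
participant).  ``read_trials`` validates everything the model assumes --
18 trials in 3 recognised blocks, ratings on 1-100, GPTS totals on
32-160 -- and raises errors that name the offending participant, row or
column.  Run configuration is a flat YAML file that round-trips
losslessly; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import (
    DICTATOR_TYPES,
    N_BLOCKS,
    N_TRIALS,
    PARAM_NAMES,
    TRIALS_PER_BLOCK,
    SessionData,
)

__all__ = [
    "TRIAL_COLUMNS",
    "PARAM_COLUMNS",
    "read_trials",
    "write_trials",
    "read_param_table",
    "write_param_table",
    "RunConfig",
]

TRIAL_COLUMNS = (
    "participant_id",
    "gpts",
    "block_index",
    "dictator_type",
    "trial",
    "return_bin",
    "hi_rating",
    "si_rating",
    "order_label",
)

PARAM_COLUMNS = ("participant_id", "gpts", *PARAM_NAMES)


def read_trials(path) -> list:
    """Read and validate a long-format trial CSV into sessions.

    Rows are normalised to (participant, block, trial) order before
    assembly, so the on-disk row order does not matter.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "order_label"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("gpts", "block_index", "trial", "return_bin", "hi_rating", "si_rating"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValueError(f"{path}: missing value in column {col!r} at row {row}")
    for col, lo, hi in (
        ("return_bin", 1, 9),
        ("hi_rating", 1, 100),
        ("si_rating", 1, 100),
        ("gpts", 32, 160),
    ):
        bad = df.index[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r} out of range [{lo}, {hi}] at row {int(bad[0])}"
            )
    df = df.sort_values(["participant_id", "block_index", "trial"], kind="stable")
    sessions = []
    for pid, grp in df.groupby("participant_id", sort=True):
        if len(grp) != N_TRIALS:
            raise ValueError(
                f"{path}: participant {pid!r} has {len(grp)} trials, expected {N_TRIALS}"
            )
        blocks = grp["block_index"].to_numpy()
        expected_blocks = np.repeat(np.arange(1, N_BLOCKS + 1), TRIALS_PER_BLOCK)
        if not np.array_equal(blocks, expected_blocks):
            raise ValueError(
                f"{path}: participant {pid!r} must have blocks 1..3 with 6 trials each"
            )
        dtypes = tuple(grp["dictator_type"].iloc[b * TRIALS_PER_BLOCK] for b in range(N_BLOCKS))
        for d in dtypes:
            if d not in DICTATOR_TYPES:
                raise ValueError(f"{path}: participant {pid!r} has unknown dictator type {d!r}")
        sessions.append(
            SessionData(
                participant_id=str(pid),
                gpts=int(grp["gpts"].iloc[0]),
                dictator_types=dtypes,
                returns=grp["return_bin"].to_numpy(int),
                hi_ratings=grp["hi_rating"].to_numpy(int),
                si_ratings=grp["si_rating"].to_numpy(int),
                order_label=str(grp["order_label"].iloc[0]) if "order_label" in grp else "",
            )
        )
    return sessions


def write_trials(sessions, path) -> None:
    from .simulator import sessions_to_frame

    sessions_to_frame(sessions).to_csv(path, index=False)


def read_param_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_param_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat run configuration; round-trips through YAML losslessly."""

    seed: int = 0
    n_participants: int = 200
    out_dir: str = "results"
    score_pre_update: bool = False
    replay_returns: bool = True
    fit: dict = field(default_factory=dict)  # FitConfig overrides
    population: dict = field(default_factory=dict)  # PopulationSpec overrides
    n_boot: int = 1000
    gpts_quantiles: int = 4
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
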