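"""Plain-CSV interchange.

All files are human-auditable CSV.  External convention: trial/event and
deck indices are 1-based; fields that do not apply to a row (e.g. deck on
a probe row) are left empty.  Internally everything is 0-based with -1
sentinels (see :mod:`membandit.data`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CHOICE_COLUMNS, ChoiceDataset, MSTResponseSet
from .task import ExperimentConfig, RewardSeries, RewardWalkConfig, TaskSchedule

__all__ = [
    "SchemaError",
    "write_choice_csv",
    "read_choice_csv",
    "write_mst_csv",
    "read_mst_csv",
    "write_task_csv",
    "write_config_yaml",
    "read_config_yaml",
]

_ONE_BASED = ("event", "choice_index", "room", "context", "deck", "probe_ref")


class SchemaError(ValueError):
    """Malformed tabular input; message names the offending row/column."""


def write_choice_csv(dataset: ChoiceDataset, path: str | Path) -> None:
    df = dataset.trials.copy()
    for c in _ONE_BASED:
        df[c] = df[c].where(df[c] < 0, df[c] + 1)
    for c in (*_ONE_BASED, "reward", "probe_novel"):
        df[c] = df[c].astype("object").where(df[c] >= 0, "")
    df.insert(0, "agent_id", dataset.agent_id)
    df.insert(1, "experiment_variant", dataset.experiment_variant)
    df.insert(2, "room_length", dataset.room_length)
    df.to_csv(path, index=False)


def _to_int(value, row: int, column: str, allowed=None) -> int:
    if value == "" or (isinstance(value, float) and np.isnan(value)):
        return -1
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: column {column!r} has non-integer value {value!r}")
    if allowed is not None and out not in allowed:
        raise SchemaError(f"row {row}: column {column!r} value {out} not in {sorted(allowed)}")
    return out


def read_choice_csv(path: str | Path) -> ChoiceDataset:
    raw = pd.read_csv(path, dtype="object", keep_default_na=False)
    required = ["agent_id", "experiment_variant", "room_length", *CHOICE_COLUMNS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if len(raw) == 0:
        empty = pd.DataFrame(
            {
                c: pd.Series(dtype=(object if c in ("kind", "probe_response") else int))
                for c in CHOICE_COLUMNS
            }
        )
        return ChoiceDataset(trials=empty)
    rows = []
    for i, rec in raw.iterrows():
        row = {
            "phase": _to_int(rec["phase"], i, "phase", allowed={1, 2}),
            "kind": rec["kind"],
            "probe_response": rec["probe_response"],
        }
        for c in _ONE_BASED:
            v = _to_int(rec[c], i, c)
            row[c] = v - 1 if v > 0 else -1
        row["deck"] = row["deck"] if row["deck"] >= 0 else -1
        if row["deck"] > 2:
            raise SchemaError(f"row {i}: deck index {row['deck'] + 1} out of range 1..3")
        row["reward"] = _to_int(rec["reward"], i, "reward", allowed={-1, 0, 1})
        row["probe_novel"] = _to_int(rec["probe_novel"], i, "probe_novel", allowed={-1, 0, 1})
        rows.append(row)
    trials = pd.DataFrame(rows)
    ds = ChoiceDataset(
        trials=trials,
        agent_id=str(raw["agent_id"].iloc[0]),
        experiment_variant=int(raw["experiment_variant"].iloc[0]),
        room_length=int(raw["room_length"].iloc[0]),
    )
    ds.validate()
    return ds


def write_mst_csv(mst_sets: list[MSTResponseSet], path: str | Path) -> None:
    frames = []
    for m in mst_sets:
        df = m.responses.copy()
        df.insert(0, "agent_id", m.agent_id)
        df.insert(1, "n_study_items", m.n_study_items)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mst_csv(path: str | Path) -> list[MSTResponseSet]:
    raw = pd.read_csv(path, dtype="object", keep_default_na=False)
    for c in ("agent_id", "condition", "response"):
        if c not in raw.columns:
            raise SchemaError(f"missing column {c!r}")
    out = []
    for agent_id, grp in raw.groupby("agent_id", sort=False):
        n_study = int(grp["n_study_items"].iloc[0]) if "n_study_items" in grp else 128
        out.append(
            MSTResponseSet(
                responses=grp[["condition", "response"]].reset_index(drop=True),
                agent_id=str(agent_id),
                n_study_items=n_study,
            )
        )
    return out


def write_task_csv(
    series: RewardSeries, schedule: TaskSchedule, path: str | Path
) -> None:
    """One row per choice trial: phase, room, context, payouts, centers."""
    n = series.n_trials
    rows = []
    for t in range(n):
        phase = 1 if t < schedule.n_learning_trials else 2
        room = schedule.room_of_trial(t) if phase == 1 else -1
        ctx = int(schedule.context_ids[room]) if phase == 1 else -1
        cat = (
            int(schedule.context_category[room])
            if phase == 1 and schedule.context_category is not None
            else -1
        )
        rows.append(
            {
                "trial": t + 1,
                "phase": phase,
                "room": room + 1 if room >= 0 else "",
                "context": ctx + 1 if ctx >= 0 else "",
                "category": cat + 1 if cat >= 0 else "",
                **{f"payout_deck{i + 1}": series.payout_prob[i, t] for i in range(3)},
                **{f"center_deck{i + 1}": series.target_center[i, t] for i in range(3)},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_config_yaml(config: ExperimentConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["walk"]["initial_targets"] = list(config.walk.initial_targets)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_config_yaml(path: str | Path) -> ExperimentConfig:
    payload = yaml.safe_load(Path(path).read_text())
    walk = payload.pop("walk", {})
    walk["initial_targets"] = tuple(walk.get("initial_targets", (60.0, 30.0, 10.0)))
    cfg = ExperimentConfig(walk=RewardWalkConfig(**walk), **payload)
    cfg.validate()
    return cfg
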