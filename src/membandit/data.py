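"""Trial-level data containers.

A :class:`ChoiceDataset` holds one agent's (or participant's) task run as a
tidy event table: every Phase-1 choice trial and every Phase-2 event
(choice or probe) is one row, in presentation order.  Decks are 0-based
internally; CSV round-trips (see :mod:`membandit.io`) are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

__all__ = ["CHOICE_COLUMNS", "ChoiceDataset", "MSTResponseSet"]

CHOICE_COLUMNS = [
    "phase",          # 1 or 2
    "event",          # 0-based event index within the phase
    "kind",           # "choice" | "probe"
    "choice_index",   # global walk step for choice rows, -1 for probes
    "room",           # 0-based room for phase-1 rows, -1 otherwise
    "context",        # context id for phase-1 rows, -1 otherwise
    "deck",           # 0..2 chosen deck, -1 for probes / missing responses
    "reward",         # 0/1 for choice rows, -1 otherwise
    "probe_ref",      # 0-based learning trial referenced by a probe, -1
    "probe_novel",    # 1 for novel probes, 0 for old probes, -1 otherwise
    "probe_response", # "old" | "new" | ""
]

_INT_COLUMNS = [c for c in CHOICE_COLUMNS if c not in ("kind", "probe_response")]


@dataclass
class ChoiceDataset:
    """One agent's trial-level record of choices, rewards, and probes."""

    trials: pd.DataFrame
    agent_id: str = "agent"
    experiment_variant: int = 1
    room_length: int = 30

    def __post_init__(self) -> None:
        missing = [c for c in CHOICE_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"ChoiceDataset missing columns: {missing}")
        self.trials = self.trials[CHOICE_COLUMNS].reset_index(drop=True)
        for c in _INT_COLUMNS:
            self.trials[c] = self.trials[c].astype(int)

    # -- selectors ---------------------------------------------------------
    def learning_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == 1]

    def phase2_events(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == 2]

    def phase2_choice_trials(self) -> pd.DataFrame:
        p2 = self.phase2_events()
        return p2[p2["kind"] == "choice"]

    def probe_events(self) -> pd.DataFrame:
        p2 = self.phase2_events()
        return p2[p2["kind"] == "probe"]

    def learning_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Choices and rewards over Phase-1 trials (-1 = missing)."""
        p1 = self.learning_trials()
        return p1["deck"].to_numpy(), p1["reward"].to_numpy()

    def all_choice_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Choices and rewards over all choice trials, walk order."""
        ch = self.trials[self.trials["kind"] == "choice"].sort_values("choice_index")
        return ch["deck"].to_numpy(), ch["reward"].to_numpy()

    @property
    def n_learning_trials(self) -> int:
        return len(self.learning_trials())

    def equals(self, other: "ChoiceDataset") -> bool:
        return (
            self.agent_id == other.agent_id
            and self.experiment_variant == other.experiment_variant
            and self.room_length == other.room_length
            and self.trials.equals(other.trials)
        )

    def validate(self) -> None:
        df = self.trials
        bad = df[~df["kind"].isin(["choice", "probe"])]
        if len(bad):
            raise ValueError(f"invalid event kind at rows {bad.index.tolist()[:5]}")
        ch = df[df["kind"] == "choice"]
        if not ch["deck"].isin([-1, 0, 1, 2]).all():
            raise ValueError("choice rows must have deck in {0,1,2} or -1 (missing)")
        responded = ch[ch["deck"] >= 0]
        if not responded["reward"].isin([0, 1]).all():
            raise ValueError("responded choice rows must have reward in {0,1}")
        pr = df[df["kind"] == "probe"]
        old = pr[pr["probe_novel"] == 0]
        n_learn = self.n_learning_trials
        refs = old["probe_ref"]
        if ((refs < 0) | (refs >= n_learn)).any():
            raise ValueError("old probes must reference a valid learning trial")
        if ((refs % self.room_length) >= 10).any():
            raise ValueError("old probes must reference a room's first ten trials")


@dataclass
class MSTResponseSet:
    """Mnemonic Similarity Task test-phase responses for one participant.

    ``responses`` has columns ``condition`` (repetition / lure / foil) and
    ``response`` ("old" / "similar" / "new", or "" for no response).
    ``n_study_items`` records the size of the incidental encoding list.
    """

    responses: pd.DataFrame
    agent_id: str = "agent"
    n_study_items: int = 128

    CONDITIONS = ("repetition", "lure", "foil")
    RESPONSES = ("old", "similar", "new")

    def __post_init__(self) -> None:
        for c in ("condition", "response"):
            if c not in self.responses.columns:
                raise ValueError(f"MSTResponseSet missing column {c!r}")
        if not self.responses["condition"].isin(self.CONDITIONS).all():
            raise ValueError("invalid MST condition label")
        ok = list(self.RESPONSES) + [""]
        if not self.responses["response"].isin(ok).all():
            raise ValueError("invalid MST response label")

    @property
    def n_test_items(self) -> int:
        return len(self.responses)

    def condition_counts(self) -> pd.Series:
        return self.responses["condition"].value_counts()
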