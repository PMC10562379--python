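"""Mnemonic Similarity Task scoring.

The Lure Discrimination Index is the difference between the rate of
"similar" responses to perceptually similar lures and to never-studied
foils, LDI = P("similar" | lure) - P("similar" | foil).  Proportions are
taken over responded trials of each condition; repetition-condition
responses do not enter the index.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import MSTResponseSet

__all__ = ["MSTSummary", "compute_ldi"]


@dataclass
class MSTSummary:
    """Condition-by-response counts and the derived LDI in [-1, 1]."""

    counts: pd.DataFrame  # conditions x responses
    p_similar_given_lure: float
    p_similar_given_foil: float
    ldi: float


def compute_ldi(responses: MSTResponseSet | pd.DataFrame) -> MSTSummary:
    """Score one participant's MST responses into the LDI."""
    df = responses.responses if isinstance(responses, MSTResponseSet) else responses
    answered = df[df["response"].isin(MSTResponseSet.RESPONSES)]
    counts = (
        answered.groupby(["condition", "response"])
        .size()
        .unstack(fill_value=0)
        .reindex(
            index=MSTResponseSet.CONDITIONS,
            columns=MSTResponseSet.RESPONSES,
            fill_value=0,
        )
    )
    n_lure = counts.loc["lure"].sum()
    n_foil = counts.loc["foil"].sum()
    if n_lure == 0 or n_foil == 0:
        raise ValueError("LDI undefined: no responded lure or foil trials")
    p_lure = counts.loc["lure", "similar"] / n_lure
    p_foil = counts.loc["foil", "similar"] / n_foil
    return MSTSummary(
        counts=counts,
        p_similar_given_lure=float(p_lure),
        p_similar_given_foil=float(p_foil),
        ldi=float(p_lure - p_foil),
    )
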