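"""Ensemble voting over member classifiers' class probabilities.

Three schemes:

* hard — per-drug majority of member predicted labels; an exact tie falls
  back to the soft vote for that drug;
* soft — per-class unweighted mean probability, argmax;
* weighted — each member's probabilities are scaled by its AUC odds,
  w / (1 - w), before averaging, so better-performing members dominate:

      score_c = (1/m) * sum_i  w_i * p_ic / (1 - w_i)

  The printed form of this rule divides by (w - 1), which is negative for
  any AUC below 1 and would invert the argmax; division by (1 - w) is the
  normative reading and ``literal_denominator=True`` exposes the literal
  form for comparison.

Ties in aggregated scores resolve to the negative class, keeping blinded
style evaluation reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class EnsembleInput:
    """Member probability tables and AUC weights for voting.

    ``probabilities`` is a list of per-member DataFrames indexed by drug with
    columns (p_negative, p_positive); ``weights`` the members' AUCs in (0, 1).
    Weights at or above 1 - 1e-6 are clamped. All members must cover the same
    drugs, and each probability pair must sum to 1.
    """

    probabilities: list[pd.DataFrame]
    weights: list[float]
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.probabilities) != len(self.weights):
            raise ValueError("one weight per member required")
        if not self.member_ids:
            self.member_ids = [f"member{i}" for i in range(len(self.probabilities))]
        base = self.probabilities[0].index
        for p in self.probabilities[1:]:
            if not p.index.equals(base):
                raise ValueError("members cover different drug sets")
        for p in self.probabilities:
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("probability pairs must sum to 1")
        ws = []
        for w in self.weights:
            if not 0 < w <= 1:
                raise ValueError(f"weight {w} outside (0, 1]")
            ws.append(min(w, 1 - _EPS))
        self.weights = ws

    @property
    def m(self) -> int:
        return len(self.probabilities)

    @property
    def drugs(self) -> pd.Index:
        return self.probabilities[0].index


@dataclass
class VotePrediction:
    """Per-drug predicted labels and aggregated class scores."""

    labels: pd.Series  # 0/1 per drug
    scores: pd.DataFrame  # columns p_negative / p_positive (aggregated)
    method: str


def _argmax_negative_ties(scores: pd.DataFrame) -> pd.Series:
    """Positive only when its aggregated score strictly exceeds the negative's."""
    return (scores["p_positive"] > scores["p_negative"]).astype(int)


def soft_vote(inp: EnsembleInput) -> VotePrediction:
    """Unweighted mean of member probabilities; argmax, ties negative."""
    mean = sum(p[["p_negative", "p_positive"]] for p in inp.probabilities) / inp.m
    labels = _argmax_negative_ties(mean)
    n_ties = int((mean["p_positive"] == mean["p_negative"]).sum())
    if n_ties:
        log.info("soft vote: %d drugs tied; resolved to negative", n_ties)
    return VotePrediction(labels=labels, scores=mean, method="soft")


def hard_vote(inp: EnsembleInput) -> VotePrediction:
    """Majority of member predicted labels; exact ties fall back to soft voting."""
    if inp.m < 2:
        raise ValueError("hard voting needs at least 2 members")
    member_labels = pd.DataFrame(
        {mid: (p["p_positive"] > p["p_negative"]).astype(int)
         for mid, p in zip(inp.member_ids, inp.probabilities)}
    )
    pos_votes = member_labels.sum(axis=1)
    neg_votes = inp.m - pos_votes
    labels = (pos_votes > neg_votes).astype(int)
    tied = pos_votes == neg_votes
    scores = pd.DataFrame(
        {"p_negative": neg_votes / inp.m, "p_positive": pos_votes / inp.m}, index=inp.drugs
    )
    if tied.any():
        log.info("hard vote: %d drugs tied; falling back to soft vote", int(tied.sum()))
        soft = soft_vote(inp)
        labels[tied] = soft.labels[tied]
    return VotePrediction(labels=labels, scores=scores, method="hard")


def weighted_vote(inp: EnsembleInput, literal_denominator: bool = False) -> VotePrediction:
    """AUC-odds-weighted mean of member probabilities.

    score_c = (1/m) * sum_i w_i * p_ic / (1 - w_i); argmax, ties negative.
    With ``literal_denominator`` the denominator is (w_i - 1) as printed,
    flipping every score's sign.
    """
    total = None
    for p, w in zip(inp.probabilities, inp.weights):
        denom = (w - 1.0) if literal_denominator else (1.0 - w)
        term = p[["p_negative", "p_positive"]] * (w / denom)
        total = term if total is None else total + term
    scores = total / inp.m
    labels = _argmax_negative_ties(scores)
    return VotePrediction(labels=labels, scores=scores, method="weighted")
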