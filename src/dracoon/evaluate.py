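"""Scoring a predicted differential network against a ground-truth edge set.

Predictions and truth are compared over the candidate-edge universe that
was actually tested, with the Matthews correlation coefficient as the
headline score (balanced for the typically truth-sparse edge universe).
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

from .data_io import CandidateEdgeSet

__all__ = ["ConfusionCounts", "confusion", "mcc", "precision", "recall"]


class ConfusionCounts(NamedTuple):
    """Edge-level confusion table over the candidate universe."""

    tp: int
    fp: int
    tn: int
    fn: int


def confusion(
    predicted: Iterable[tuple[str, str]],
    truth: Iterable[tuple[str, str]],
    universe: CandidateEdgeSet,
) -> ConfusionCounts:
    """Confusion counts of predicted vs true differential edges.

    Mode-1 (undirected) edges are compared after canonical ordering;
    mode-2 edges as directed pairs.  Predictions or truth outside the
    universe are an error.
    """
    uni = {universe.canonical(e) for e in universe.edges}
    pred = {universe.canonical(tuple(e)) for e in predicted}
    tru = {universe.canonical(tuple(e)) for e in truth}
    stray = pred - uni
    if stray:
        raise ValueError(f"predicted edges outside the universe: {sorted(stray)}")
    stray = tru - uni
    if stray:
        raise ValueError(f"truth edges outside the universe: {sorted(stray)}")
    tp = len(pred & tru)
    fp = len(pred - tru)
    fn = len(tru - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, fp, tn, fn = (int(c.tp), int(c.fp), int(c.tn), int(c.fn))
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
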