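"""The two differential co-expression metrics.

``delta_r`` is the absolute difference in association between conditions,

    delta_r = |r_a - r_b|

and captures changes in the strength or sign of a pairwise association
(rewiring).  ``shift_s`` measures how far the pooled-sample association
departs from the per-condition associations and is the metric sensitive to
rewiring driven by condition-specific expression shifts.  Two variants are
available:

``"scaled"``
    ``s = r_ab - 2 * (r_a + r_b)``.  The published form of the statistic.
``"centered"``
    ``s = r_ab - (r_a + r_b) / 2``, the pooled association minus the mean
    of the per-condition associations.  This is the form that is
    null-calibrated: for a pair whose association is identical in both
    conditions, r_a = r_b = r_ab and s = 0, so homogeneous data scores s
    near zero for every pair.  Under the scaled form the same pair scores
    s = -3 r, far outside a permutation null centred at zero, and every
    strongly co-expressed (but non-differential) pair would be flagged.
    The pipeline therefore defaults to the centered variant; see
    docs/methods.md for the full argument.
"""

from __future__ import annotations

__all__ = ["delta_r", "shift_s", "S_VARIANTS", "DEFAULT_S_VARIANT"]

S_VARIANTS = ("scaled", "centered")

#: Variant of s used by the pipeline (background model and edge scoring).
DEFAULT_S_VARIANT = "centered"


def delta_r(r_a: float, r_b: float) -> float:
    """Absolute difference in co-expression between the two conditions."""
    return abs(r_a - r_b)


def shift_s(r_ab: float, r_a: float, r_b: float, variant: str = "scaled") -> float:
    """Degree of association shift between pooled and per-condition values.

    The default ``variant="scaled"`` evaluates the statistic exactly as
    published, ``r_ab - 2 * (r_a + r_b)``; ``variant="centered"`` evaluates
    ``r_ab - (r_a + r_b) / 2`` (see module docstring).
    """
    if variant == "scaled":
        return r_ab - 2.0 * (r_a + r_b)
    if variant == "centered":
        return r_ab - (r_a + r_b) / 2.0
    raise ValueError(f"unknown s variant {variant!r}; choose from {S_VARIANTS}")
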