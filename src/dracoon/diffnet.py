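"""The differential network pipeline.

Four steps: (1) compute per-condition and pooled associations for every
candidate edge; (2) build the pooled permutation background; (3) score each
edge with delta_r and s and assign empirical p-values; (4) correct for
multiple testing per metric family and flag significant edges.  Edges
passing the significance rule constitute the differential co-expression
network (mode 1) or the differential GRN (mode 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import AssociationTriple, association_triple
from .background import BackgroundModel, build_background, empirical_p
from .data_io import NETWORK_COLUMNS, CandidateEdgeSet, ExpressionDataset
from .metrics import DEFAULT_S_VARIANT, delta_r, shift_s

__all__ = [
    "DifferentialEdge",
    "DifferentialNetwork",
    "adjust_pvalues",
    "run_dracoon",
    "SIGNIFICANCE_RULES",
]

SIGNIFICANCE_RULES = ("delta_r", "s", "either", "both")

#: Multiple-testing corrections handled natively; any other name is passed
#: through to statsmodels.stats.multitest.multipletests.
_STATSMODELS_METHODS = (
    "bonferroni", "sidak", "holm-sidak", "holm", "simes-hochberg",
    "hommel", "fdr_by", "fdr_tsbh", "fdr_tsbky",
)


@dataclass(frozen=True)
class DifferentialEdge:
    """Scores, p-values and significance flags of one tested gene pair."""

    source: str
    target: str
    triple: AssociationTriple
    delta_r: float
    s: float
    p_delta_r: float
    p_s: float
    padj_delta_r: float
    padj_s: float
    sig_delta_r: bool
    sig_s: bool


@dataclass
class DifferentialNetwork:
    """All tested edges plus the run configuration that produced them."""

    edges: list[DifferentialEdge]
    mode: int
    metric: str
    alpha: float
    correction: str
    n_perm: int
    seed: int | None
    significance_rule: str = "either"
    s_variant: str = DEFAULT_S_VARIANT
    background: BackgroundModel | None = field(default=None, repr=False)

    def significance_mask(self, rule: str | None = None) -> np.ndarray:
        """Boolean mask over tested edges for a significance rule."""
        rule = self.significance_rule if rule is None else rule
        if rule not in SIGNIFICANCE_RULES:
            raise ValueError(
                f"unknown significance rule {rule!r}; choose from {SIGNIFICANCE_RULES}"
            )
        dr = np.array([e.sig_delta_r for e in self.edges], dtype=bool)
        s = np.array([e.sig_s for e in self.edges], dtype=bool)
        if rule == "delta_r":
            return dr
        if rule == "s":
            return s
        if rule == "either":
            return dr | s
        return dr & s

    def significant_edges(self, rule: str | None = None) -> list[tuple[str, str]]:
        mask = self.significance_mask(rule)
        return [(e.source, e.target) for e, m in zip(self.edges, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "r_a": e.triple.r_a,
                "r_b": e.triple.r_b,
                "r_ab": e.triple.r_ab,
                "delta_r": e.delta_r,
                "s": e.s,
                "p_delta_r": e.p_delta_r,
                "p_s": e.p_s,
                "padj_delta_r": e.padj_delta_r,
                "padj_s": e.padj_s,
                "sig_delta_r": e.sig_delta_r,
                "sig_s": e.sig_s,
                "degenerate": e.triple.degenerate,
            }
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=NETWORK_COLUMNS)


def adjust_pvalues(
    p, method: str = "fdr_bh", alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing correction of one p-value family.

    The default is the Benjamini-Hochberg step-up FDR procedure,
    implemented directly:  adj_i = min_{j: rank(j) >= rank(i)} p_j * E / rank(j),
    capped at 1.  Other standard corrections are delegated to statsmodels.
    Returns ``(adjusted, significant)`` with ``significant = adjusted < alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size and ((p <= 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "fdr_bh":
        m = p.size
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        adjusted = np.empty(m)
        adjusted[order] = adj_sorted
    elif method in _STATSMODELS_METHODS:
        adjusted = multipletests(p, alpha=alpha, method=method)[1]
    else:
        raise ValueError(
            f"unknown correction method {method!r}; supported: "
            f"{('fdr_bh',) + _STATSMODELS_METHODS}"
        )
    return adjusted, adjusted < alpha


def run_dracoon(
    dataset: ExpressionDataset,
    candidates: CandidateEdgeSet,
    metric: str = "entropy",
    n_perm: int = 10_000,
    seed: int | None = 42,
    alpha: float = 0.01,
    correction: str = "fdr_bh",
    significance_rule: str = "either",
    s_variant: str = DEFAULT_S_VARIANT,
    bins: int | str = "auto",
) -> DifferentialNetwork:
    """Run the full differential-network pipeline on a labeled dataset.

    Builds one pooled background of ``n_perm`` permutations, scores every
    candidate edge with delta_r and s, assigns empirical p-values from the
    shared null, corrects each metric family separately across all tested
    edges, and returns the network with all tested edges and their flags.
    Deterministic for a fixed seed.

    Degenerate edges (a constant gene in either condition) are kept in the
    output with both p-values set to 1 and the ``degenerate`` flag raised.
    """
    if significance_rule not in SIGNIFICANCE_RULES:
        raise ValueError(
            f"unknown significance rule {significance_rule!r}; "
            f"choose from {SIGNIFICANCE_RULES}"
        )
    if len(candidates) == 0:
        raise ValueError("candidate edge set is empty")
    model = build_background(
        dataset, candidates, metric=metric, n_perm=n_perm, seed=seed,
        s_variant=s_variant, bins=bins,
    )
    triples = [
        association_triple(dataset, pair, metric=metric, bins=bins)
        for pair in candidates.edges
    ]
    dr_obs = np.array([delta_r(t.r_a, t.r_b) for t in triples])
    s_obs = np.array(
        [shift_s(t.r_ab, t.r_a, t.r_b, variant=s_variant) for t in triples]
    )
    degen = np.array([t.degenerate for t in triples], dtype=bool)
    p_dr = np.asarray(empirical_p(dr_obs, model, "delta_r"))
    p_s = np.asarray(empirical_p(s_obs, model, "s"))
    p_dr[degen] = 1.0
    p_s[degen] = 1.0
    padj_dr, sig_dr = adjust_pvalues(p_dr, method=correction, alpha=alpha)
    padj_s, sig_s = adjust_pvalues(p_s, method=correction, alpha=alpha)
    edges = [
        DifferentialEdge(
            source=src,
            target=tgt,
            triple=t,
            delta_r=float(dr_obs[i]),
            s=float(s_obs[i]),
            p_delta_r=float(p_dr[i]),
            p_s=float(p_s[i]),
            padj_delta_r=float(padj_dr[i]),
            padj_s=float(padj_s[i]),
            sig_delta_r=bool(sig_dr[i]),
            sig_s=bool(sig_s[i]),
        )
        for i, ((src, tgt), t) in enumerate(zip(candidates.edges, triples))
    ]
    return DifferentialNetwork(
        edges=edges,
        mode=candidates.mode,
        metric=metric,
        alpha=alpha,
        correction=correction,
        n_perm=n_perm,
        seed=seed,
        significance_rule=significance_rule,
        s_variant=s_variant,
        background=model,
    )
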