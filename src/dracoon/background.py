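"""Pooled permutation background model for the differential metrics.

A single null distribution of delta_r and one of s are built once per run
and shared by every tested edge, instead of one permutation test per edge.
Each permutation draw picks one candidate pair at random, shuffles each
gene's values *within* each condition (preserving the per-condition
marginals while destroying the gene-gene coupling) to obtain null r_a and
r_b, and shuffles the pooled vectors across all samples for null r_ab.
Empirical p-values are then read off the pooled null with a +1 pseudocount,
right-tailed for delta_r and two-tailed (doubled smaller tail, capped at 1)
for s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .association import get_metric, is_degenerate
from .metrics import DEFAULT_S_VARIANT, delta_r as _delta_r, shift_s as _shift_s

__all__ = ["BackgroundModel", "permute_once", "build_background", "empirical_p"]


@dataclass
class BackgroundModel:
    """Pooled null samples of delta_r and s.

    ``null_delta_r`` and ``null_s`` each hold one value per permutation;
    regeneration with the same seed, dataset and candidate set reproduces
    them exactly.
    """

    null_delta_r: np.ndarray
    null_s: np.ndarray
    n_perm: int
    metric: str
    seed: int | None = None
    s_variant: str = DEFAULT_S_VARIANT
    _sorted_delta_r: np.ndarray = field(init=False, repr=False)
    _sorted_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.null_delta_r = np.asarray(self.null_delta_r, dtype=float)
        self.null_s = np.asarray(self.null_s, dtype=float)
        if self.null_delta_r.shape != (self.n_perm,) or self.null_s.shape != (
            self.n_perm,
        ):
            raise ValueError("null vectors must have length n_perm")
        if not (
            np.isfinite(self.null_delta_r).all() and np.isfinite(self.null_s).all()
        ):
            raise ValueError("background model contains non-finite values")
        if (self.null_delta_r < 0).any():
            raise ValueError("null delta_r values must be >= 0")
        if self.n_perm < 1000:
            warnings.warn(
                f"background model built from only {self.n_perm} permutations; "
                "p-value resolution will be coarse",
                UserWarning,
                stacklevel=3,
            )
        self._sorted_delta_r = np.sort(self.null_delta_r)
        self._sorted_s = np.sort(self.null_s)


def _permuted_association(x, y, idx_a, idx_b, metric_fn, rng):
    """One within/pooled shuffle of a gene pair; returns (r_a, r_b, r_ab)."""
    # each gene is shuffled independently; shuffling either member already
    # destroys the coupling, shuffling both matches the stated scheme
    xa = rng.permutation(x[idx_a])
    ya = rng.permutation(y[idx_a])
    xb = rng.permutation(x[idx_b])
    yb = rng.permutation(y[idx_b])
    x_all = rng.permutation(x)
    y_all = rng.permutation(y)
    return metric_fn(xa, ya), metric_fn(xb, yb), metric_fn(x_all, y_all)


def permute_once(
    dataset,
    pair: tuple[str, str],
    metric: str = "pearson",
    rng: np.random.Generator | None = None,
    s_variant: str = DEFAULT_S_VARIANT,
    bins: int | str = "auto",
) -> tuple[float, float]:
    """Draw one pooled-null sample (delta_r~, s~) for one gene pair.

    Values of each gene are permuted among the A samples and among the B
    samples (null r_a, r_b), and across all samples (null r_ab).
    """
    if rng is None:
        rng = np.random.default_rng()
    fn = get_metric(metric)
    if metric == "nmi":
        metric_fn = lambda u, v: fn(u, v, bins=bins)  # noqa: E731
    else:
        metric_fn = fn
    # canonical order so the draw stream (hence the null and the p-values)
    # is invariant to the orientation of the pair
    g1, g2 = sorted(pair)
    x = dataset.expression_of(g1)
    y = dataset.expression_of(g2)
    label_a, label_b = dataset.condition_labels
    idx_a = dataset.sample_mask(label_a)
    idx_b = dataset.sample_mask(label_b)
    r_a, r_b, r_ab = _permuted_association(x, y, idx_a, idx_b, metric_fn, rng)
    return _delta_r(r_a, r_b), _shift_s(r_ab, r_a, r_b, variant=s_variant)


def build_background(
    dataset,
    candidates,
    metric: str = "pearson",
    n_perm: int = 10_000,
    seed: int | None = 42,
    s_variant: str = DEFAULT_S_VARIANT,
    bins: int | str = "auto",
    rng: np.random.Generator | None = None,
) -> BackgroundModel:
    """Build the pooled background model shared by all tested edges.

    For each of the ``n_perm`` draws one candidate pair is sampled uniformly
    with replacement, so the null reflects the marginal distributions of the
    genes actually under test.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(candidates) == 0:
        raise ValueError("candidate edge set is empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    pair_idx = rng.integers(0, len(candidates), size=n_perm)
    null_dr = np.empty(n_perm)
    null_s = np.empty(n_perm)
    for i, k in enumerate(pair_idx):
        null_dr[i], null_s[i] = permute_once(
            dataset, candidates.edges[k], metric=metric, rng=rng,
            s_variant=s_variant, bins=bins,
        )
    return BackgroundModel(
        null_delta_r=null_dr,
        null_s=null_s,
        n_perm=n_perm,
        metric=metric,
        seed=seed,
        s_variant=s_variant,
    )


def empirical_p(observed, model: BackgroundModel, which: str):
    """Empirical p-value(s) of observed metric value(s) against the pooled null.

    ``which="delta_r"`` is right-tailed: p = (1 + #{null >= obs}) / (1 + N_p).
    ``which="s"`` is two-tailed: the smaller of the left and right tail
    probabilities (each with the +1 pseudocount) is doubled and capped at 1.
    Scalar input yields a scalar; vector input a vector.
    """
    obs = np.asarray(observed, dtype=float)
    scalar = obs.ndim == 0
    obs = np.atleast_1d(obs)
    n = model.n_perm
    if which == "delta_r":
        ge = n - np.searchsorted(model._sorted_delta_r, obs, side="left")
        p = (1.0 + ge) / (1.0 + n)
    elif which == "s":
        ge = n - np.searchsorted(model._sorted_s, obs, side="left")
        le = np.searchsorted(model._sorted_s, obs, side="right")
        p = 2.0 * np.minimum((1.0 + le) / (1.0 + n), (1.0 + ge) / (1.0 + n))
        p = np.minimum(p, 1.0)
    else:
        raise ValueError(f"which must be 'delta_r' or 's', got {which!r}")
    return float(p[0]) if scalar else p
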