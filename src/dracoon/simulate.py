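"""Benchmark simulator: perturbed GRN expression data with known ground truth.

The generator emulates a tree-structured transcription-factor / target-gene
network.  Expression is drawn from a multivariate normal whose correlation
between two genes decays with their distance in the network
(Sigma_ij = rho ** d(i, j)), the canonical graph-to-covariance construction
for simulating expression from a regulatory graph.  Samples are split into
a control group, drawn from the unperturbed model, and a case group drawn
from a modified model carrying one of four perturbation types (or a random
mix of them) on a chosen subset of genes:

* ``knockdown``       -- the case mean of a perturbed gene is multiplied by
                         a factor < 1;
* ``diff_expr``       -- an additive shift of the case mean;
* ``inversion``       -- every network edge incident to a perturbed gene has
                         its case correlation negated, and the sign change
                         propagates along all paths through that edge;
* ``loss_of_coexpr``  -- those edges are cut: correlations along paths
                         through them drop to zero.

Sign flips and cuts both keep the case covariance exactly positive
definite on a tree (a flip is a diagonal-sign similarity, a cut makes the
matrix block-diagonal over tree components), so no covariance repair is
normally needed; a nearest-positive-definite fallback exists for future
non-tree graphs.  Gaussian observation noise is added to every entry of
both groups.  The ground-truth differential edges are all network edges
incident to at least one perturbed gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import CandidateEdgeSet, ExpressionDataset
from .metrics import DEFAULT_S_VARIANT

__all__ = [
    "SimulatedBenchmark",
    "generate_tree_grn",
    "graph_covariance",
    "nearest_positive_definite",
    "simulate_expression",
    "start_benchmark",
    "apply_perturbation",
    "simulate_benchmark",
    "score_benchmark",
    "sweep",
    "PERTURBATIONS",
    "DEFAULTS",
]

PERTURBATIONS = ("knockdown", "diff_expr", "inversion", "loss_of_coexpr", "mixed")

#: Default simulation conditions (see docs/methods.md for rationale).
DEFAULTS = dict(
    n_tf=20,
    n_tg=80,
    m_samples=100,
    case_ratio=0.5,
    perturb_fraction=0.1,
    rho=0.8,
    mu=6.0,
    sigma=1.0,
    noise_sd=0.1,
    knockdown_factor=0.1,
    de_shift=2.0,
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_tree_grn(n_tf: int, n_tg: int, seed=None) -> list[tuple[str, str]]:
    """Grow a random directed tree of ``n_tf`` TFs and ``n_tg`` target genes.

    TF2..TFn and then every TG attach to a uniformly chosen existing TF, so
    TFs may regulate both TFs and TGs while TGs are always leaves.  Edges
    are directed parent -> child; TF1 is the root.
    """
    if n_tf < 1 or n_tg < 1:
        raise ValueError("need at least one TF and one TG")
    rng = _as_rng(seed)
    tfs = [f"TF{i + 1}" for i in range(n_tf)]
    tgs = [f"TG{i + 1}" for i in range(n_tg)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_tf):
        parent = tfs[int(rng.integers(0, i))]
        edges.append((parent, tfs[i]))
    for tg in tgs:
        parent = tfs[int(rng.integers(0, n_tf))]
        edges.append((parent, tg))
    return edges


def _natural_key(name: str):
    prefix = name.rstrip("0123456789")
    suffix = name[len(prefix):]
    return (prefix, int(suffix) if suffix else 0, name)


def network_genes(edges: Iterable[tuple[str, str]]) -> list[str]:
    """Deterministically ordered node list of a network (TFs before TGs)."""
    nodes = set()
    for s, t in edges:
        nodes.add(s)
        nodes.add(t)
    return sorted(nodes, key=_natural_key)


def _tree_sigma(
    edges: Sequence[tuple[str, str]],
    rho: float,
    flipped: frozenset = frozenset(),
    cut: frozenset = frozenset(),
    genes: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Correlation matrix of a (possibly sign-flipped / cut) tree.

    Sigma_ij is the product of edge weights along the unique i-j path,
    where an intact edge weighs rho, a flipped edge -rho and a cut edge 0.
    """
    genes = list(genes) if genes is not None else network_genes(edges)
    index = {g: i for i, g in enumerate(genes)}
    adj: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for s, t in edges:
        key = frozenset((s, t))
        w = 0.0 if key in cut else (-rho if key in flipped else rho)
        adj[s].append((t, w))
        adj[t].append((s, w))
    n = len(genes)
    sigma = np.eye(n)
    for src in genes:
        i = index[src]
        stack = [(src, 1.0)]
        seen = {src}
        while stack:
            node, val = stack.pop()
            for nxt, w in adj[node]:
                if nxt in seen:
                    continue
                seen.add(nxt)
                v = val * w
                sigma[i, index[nxt]] = v
                stack.append((nxt, v))
    return genes, sigma


def graph_covariance(
    edges: Sequence[tuple[str, str]], rho: float
) -> tuple[list[str], np.ndarray]:
    """Distance-decaying correlation matrix Sigma_ij = rho ** d(i, j).

    ``d`` is the shortest-path distance on the undirected network.  For a
    connected tree and rho in (0, 1) the result is symmetric positive
    definite.  Returns the gene order alongside the matrix.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    return _tree_sigma(edges, rho)


def nearest_positive_definite(
    matrix: np.ndarray, eps: float = 1e-8
) -> np.ndarray:
    """Repair a symmetric matrix to the nearest correlation-like PD matrix.

    Eigenvalues are clipped at ``eps`` and the diagonal re-normalized to 1.
    Only needed for non-tree graphs; tree-derived matrices are PD as built.
    """
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    repaired = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _draw_mvn(
    rng: np.random.Generator,
    mean: np.ndarray,
    sigma_mat: np.ndarray,
    n: int,
) -> np.ndarray:
    """n samples from MVN(mean, sigma_mat), returned genes x samples."""
    try:
        chol = np.linalg.cholesky(sigma_mat)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(nearest_positive_definite(sigma_mat))
    z = rng.standard_normal((n, mean.size))
    return (z @ chol.T + mean).T


def simulate_expression(
    edges: Sequence[tuple[str, str]],
    m_samples: int,
    rho: float = DEFAULTS["rho"],
    mu: float = DEFAULTS["mu"],
    sigma: float = DEFAULTS["sigma"],
    seed=None,
) -> ExpressionDataset:
    """Draw an unlabeled expression matrix from the network's MVN model."""
    if m_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = _as_rng(seed)
    genes, corr = graph_covariance(edges, rho)
    mean = np.full(len(genes), mu)
    values = _draw_mvn(rng, mean, sigma**2 * corr, m_samples)
    return ExpressionDataset(
        gene_ids=genes,
        sample_ids=[f"s{j + 1}" for j in range(m_samples)],
        values=values,
    )


@dataclass
class BenchmarkDraft:
    """A benchmark before perturbation: network, base model and sample split."""

    edges: list[tuple[str, str]]
    genes: list[str]
    tfs: list[str]
    tgs: list[str]
    rho: float
    mu: float
    sigma: float
    noise_sd: float
    n_control: int
    n_case: int
    rng: np.random.Generator
    params: dict


@dataclass
class SimulatedBenchmark:
    """A labeled simulated dataset with its ground-truth differential edges."""

    network: list[tuple[str, str]]
    dataset: ExpressionDataset
    truth_edges: set[tuple[str, str]]
    perturbed_genes: set[str]
    perturbation: str
    params: dict

    def candidate_set(self) -> CandidateEdgeSet:
        """The mode-2 candidate set over the simulated network's edges."""
        return CandidateEdgeSet.from_edges(self.network, self.dataset)


def start_benchmark(
    n_tf: int = DEFAULTS["n_tf"],
    n_tg: int = DEFAULTS["n_tg"],
    m_samples: int = DEFAULTS["m_samples"],
    case_ratio: float = DEFAULTS["case_ratio"],
    rho: float = DEFAULTS["rho"],
    mu: float = DEFAULTS["mu"],
    sigma: float = DEFAULTS["sigma"],
    noise_sd: float = DEFAULTS["noise_sd"],
    seed=None,
) -> BenchmarkDraft:
    """Generate the network and fix the case/control split (no data yet)."""
    if not 0.0 < case_ratio < 1.0:
        raise ValueError(f"case_ratio must lie in (0, 1), got {case_ratio}")
    n_case = int(round(case_ratio * m_samples))
    n_control = m_samples - n_case
    if n_case < 2 or n_control < 2:
        raise ValueError(
            f"split {n_control}+{n_case} leaves fewer than 2 samples in a group"
        )
    rng = _as_rng(seed)
    edges = generate_tree_grn(n_tf, n_tg, seed=rng)
    genes = network_genes(edges)
    tfs = [g for g in genes if g.startswith("TF")]
    tgs = [g for g in genes if g.startswith("TG")]
    params = dict(
        n_tf=n_tf, n_tg=n_tg, m_samples=m_samples, case_ratio=case_ratio,
        rho=rho, mu=mu, sigma=sigma, noise_sd=noise_sd,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )
    return BenchmarkDraft(
        edges=edges, genes=genes, tfs=tfs, tgs=tgs, rho=rho, mu=mu,
        sigma=sigma, noise_sd=noise_sd, n_control=n_control, n_case=n_case,
        rng=rng, params=params,
    )


def _pick_perturbed(draft: BenchmarkDraft, k: int) -> list[str]:
    # TFs are perturbed first so that perturbations propagate through
    # regulation; TGs are only drawn once all TFs are exhausted
    rng = draft.rng
    n_from_tf = min(k, len(draft.tfs))
    chosen = list(rng.choice(draft.tfs, size=n_from_tf, replace=False))
    if k > n_from_tf:
        chosen += list(rng.choice(draft.tgs, size=k - n_from_tf, replace=False))
    return chosen


def apply_perturbation(
    draft: BenchmarkDraft,
    perturbation: str,
    perturb_fraction: float = DEFAULTS["perturb_fraction"],
    knockdown_factor: float = DEFAULTS["knockdown_factor"],
    de_shift: float = DEFAULTS["de_shift"],
) -> SimulatedBenchmark:
    """Perturb the case group's generative model and draw both groups.

    ``perturbation="none"`` draws case and control from the identical model
    (a null benchmark; the ground-truth edge set is empty).
    """
    if perturbation not in PERTURBATIONS + ("none",):
        raise ValueError(
            f"unknown perturbation {perturbation!r}; "
            f"choose from {PERTURBATIONS + ('none',)}"
        )
    rng = draft.rng
    genes = draft.genes
    mean_base = np.full(len(genes), draft.mu)
    _, sigma_base = _tree_sigma(draft.edges, draft.rho, genes=genes)

    perturbed: list[str] = []
    type_of: dict[str, str] = {}
    if perturbation != "none":
        if not 0.0 < perturb_fraction < 1.0:
            raise ValueError(
                f"perturb_fraction must lie in (0, 1), got {perturb_fraction}"
            )
        if not 0.0 < knockdown_factor < 1.0:
            raise ValueError(
                f"knockdown_factor must lie in (0, 1), got {knockdown_factor}"
            )
        k = int(round(perturb_fraction * len(genes)))
        k = max(1, k)
        perturbed = _pick_perturbed(draft, k)
        if perturbation == "mixed":
            kinds = rng.choice(PERTURBATIONS[:4], size=len(perturbed))
            type_of = {g: str(t) for g, t in zip(perturbed, kinds)}
        else:
            type_of = {g: perturbation for g in perturbed}

    mean_case = mean_base.copy()
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, kind in type_of.items():
        if kind == "knockdown":
            mean_case[gene_index[g]] *= knockdown_factor
        elif kind == "diff_expr":
            mean_case[gene_index[g]] += de_shift

    cut = frozenset(
        frozenset(e) for e in draft.edges
        if type_of.get(e[0]) == "loss_of_coexpr"
        or type_of.get(e[1]) == "loss_of_coexpr"
    )
    flipped = frozenset(
        frozenset(e) for e in draft.edges
        if (type_of.get(e[0]) == "inversion" or type_of.get(e[1]) == "inversion")
        and frozenset(e) not in cut
    )
    if cut or flipped:
        _, sigma_case = _tree_sigma(
            draft.edges, draft.rho, flipped=flipped, cut=cut, genes=genes
        )
        if np.linalg.eigvalsh(sigma_case).min() < 1e-8:
            sigma_case = nearest_positive_definite(sigma_case)
    else:
        sigma_case = sigma_base

    s2 = draft.sigma**2
    control = _draw_mvn(rng, mean_base, s2 * sigma_base, draft.n_control)
    case = _draw_mvn(rng, mean_case, s2 * sigma_case, draft.n_case)
    values = np.hstack([control, case])
    values = values + rng.normal(0.0, draft.noise_sd, size=values.shape)

    sample_ids = [f"ctrl{j + 1}" for j in range(draft.n_control)] + [
        f"case{j + 1}" for j in range(draft.n_case)
    ]
    condition_of = {s: ("control" if s.startswith("ctrl") else "case")
                    for s in sample_ids}
    dataset = ExpressionDataset(
        gene_ids=genes, sample_ids=sample_ids, values=values,
        condition_of=condition_of,
    )
    pset = set(perturbed)
    truth = {e for e in draft.edges if e[0] in pset or e[1] in pset}
    params = dict(
        draft.params,
        perturbation=perturbation,
        perturb_fraction=perturb_fraction if perturbation != "none" else 0.0,
        knockdown_factor=knockdown_factor,
        de_shift=de_shift,
        perturbation_types=type_of,
    )
    return SimulatedBenchmark(
        network=list(draft.edges),
        dataset=dataset,
        truth_edges=truth,
        perturbed_genes=pset,
        perturbation=perturbation,
        params=params,
    )


def simulate_benchmark(
    perturbation: str = "knockdown",
    perturb_fraction: float = DEFAULTS["perturb_fraction"],
    knockdown_factor: float = DEFAULTS["knockdown_factor"],
    de_shift: float = DEFAULTS["de_shift"],
    seed=None,
    **draft_kwargs,
) -> SimulatedBenchmark:
    """One-call benchmark generation (network + data + ground truth)."""
    draft = start_benchmark(seed=seed, **draft_kwargs)
    return apply_perturbation(
        draft, perturbation, perturb_fraction=perturb_fraction,
        knockdown_factor=knockdown_factor, de_shift=de_shift,
    )


def score_benchmark(
    benchmark: SimulatedBenchmark,
    metric: str = "entropy",
    significance_rule: str = "s",
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | None = 42,
    s_variant: str = DEFAULT_S_VARIANT,
):
    """Run the pipeline on a benchmark and score it against the ground truth.

    Returns ``(mcc, counts, network)`` where counts is the confusion table
    over the benchmark's candidate edges.
    """
    from .diffnet import run_dracoon
    from .evaluate import confusion, mcc

    candidates = benchmark.candidate_set()
    network = run_dracoon(
        benchmark.dataset, candidates, metric=metric, n_perm=n_perm,
        seed=seed, alpha=alpha, significance_rule=significance_rule,
        s_variant=s_variant,
    )
    predicted = network.significant_edges()
    counts = confusion(predicted, benchmark.truth_edges, candidates)
    return mcc(counts), counts, network


def sweep(
    case_ratios: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    perturb_fractions: Sequence[float] = (DEFAULTS["perturb_fraction"],),
    perturbations: Sequence[str] = PERTURBATIONS,
    n_sims: int = 5,
    n_runs: int = 5,
    seed: int = 42,
    metric: str = "entropy",
    significance_rule: str = "s",
    n_perm: int = 1000,
    alpha: float = 0.01,
    s_variant: str = DEFAULT_S_VARIANT,
    **sim_kwargs,
) -> pd.DataFrame:
    """Grid evaluation: MCC per scenario, simulation and algorithm run.

    For every (perturbation, case_ratio, perturb_fraction) grid point,
    ``n_sims`` independent benchmarks are generated and each is scored by
    ``n_runs`` independent pipeline executions.  Fully deterministic for a
    fixed seed.
    """
    master = np.random.default_rng(seed)
    rows = []
    for pert in perturbations:
        for ratio in case_ratios:
            for frac in perturb_fractions:
                for sim in range(n_sims):
                    sim_seed = int(master.integers(2**31))
                    bench = simulate_benchmark(
                        perturbation=pert, perturb_fraction=frac,
                        case_ratio=ratio, seed=sim_seed, **sim_kwargs,
                    )
                    for run in range(n_runs):
                        run_seed = int(master.integers(2**31))
                        value, counts, _ = score_benchmark(
                            bench, metric=metric,
                            significance_rule=significance_rule,
                            n_perm=n_perm, alpha=alpha, seed=run_seed,
                            s_variant=s_variant,
                        )
                        rows.append(
                            dict(
                                perturbation=pert, case_ratio=ratio,
                                perturb_fraction=frac, sim=sim, run=run,
                                mcc=value, tp=counts.tp, fp=counts.fp,
                                tn=counts.tn, fn=counts.fn,
                            )
                        )
    return pd.DataFrame(rows)


def write_benchmark(benchmark: SimulatedBenchmark, out_dir: str | Path) -> None:
    """Save a benchmark as plain-text files (the saved-details contract).

    Writes ``expr.tsv``, ``cond.tsv``, ``grn.tsv``, ``truth_edges.tsv`` and
    ``params.json`` into ``out_dir``.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    benchmark.dataset.to_frame().to_csv(out / "expr.tsv", sep="\t")
    pd.DataFrame(
        {
            "sample": benchmark.dataset.sample_ids,
            "condition": [
                benchmark.dataset.condition_of[s]
                for s in benchmark.dataset.sample_ids
            ],
        }
    ).to_csv(out / "cond.tsv", sep="\t", index=False)
    pd.DataFrame(benchmark.network, columns=["tf", "tg"]).to_csv(
        out / "grn.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(benchmark.truth_edges), columns=["tf", "tg"]).to_csv(
        out / "truth_edges.tsv", sep="\t", index=False
    )
    (out / "params.json").write_text(json.dumps(benchmark.params, indent=2))
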