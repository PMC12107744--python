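# Methods

This note documents the statistical model behind `dracoon`, the design
choices made where the construction was genuinely open, the defaults and
their rationale, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Setting and notation

M samples are measured over G genes under exactly two conditions, A and B.
The input matrix is assumed normalized and complete; missing values are
rejected rather than imputed, since the method defines no missing-data
model. For a candidate gene pair, `r_a`, `r_b` and `r_ab` denote the
association computed on the A samples, the B samples, and all samples
pooled, with one of the metrics below. The two differential metrics are

* `delta_r = |r_a - r_b|`, the magnitude of association change, and
* `s`, the degree of association shift between the pooled and the
  per-condition associations (next section).

Mode 1 tests all G(G−1)/2 unordered pairs; mode 2 only a user-supplied
directed TF→TG list, filtered to genes present in the data. At least about
10 samples per condition are recommended (a warning is emitted below
that): with fewer samples the within-condition permutation space is so
small that the empirical null becomes coarse and unstable.

## The shift metric and its two functional forms

`shift_s` supports two variants:

* `scaled`: `s = r_ab − 2(r_a + r_b)` — the form in which the statistic
  is usually written;
* `centered`: `s = r_ab − (r_a + r_b)/2` — the pooled association minus
  the mean per-condition association.

The pipeline default is `centered`, and the reason is calibration against
the permutation null. The background model (below) shuffles data, so its
null values of `r_a`, `r_b`, `r_ab` all concentrate near the no-association
point. A non-differential but strongly co-expressed pair has
`r_a ≈ r_b ≈ r_ab = r`; under the centered form its observed `s ≈ 0`, i.e.
exactly where the null is centred, and only pairs whose pooled association
genuinely departs from the per-condition mean score away from zero. Under
the scaled form the same non-differential pair scores `s ≈ −3r`, far
outside a null centred at zero, so every strongly co-expressed pair would
be declared differential regardless of any condition difference. The
package's own benchmark quantifies this: with the scaled form the pipeline
flags essentially the whole candidate set on both perturbed *and*
homogeneous data (MCC ≈ 0 everywhere), while the centered form recovers
perturbed edges nearly perfectly at the default conditions (see
`scripts/acceptance.py` output). The scaled form is retained as the
default of the standalone `shift_s` function and as a pipeline variant
(`--s-variant scaled`) for comparability.

## Association metrics

**pearson / spearman.** Standard product–moment and rank correlation, in
[−1, 1]. Zero-variance input yields 0 with a `degenerate` flag that
propagates to the output table (p-values of degenerate edges are set to 1
rather than dropping the edge or poisoning the null with NaNs).

**entropy.** The randomness of the pair's joint expression distribution,
computed from the correlation coefficient:

    E(r) = H2((1 + r) / 2) / ln 2,   r = pearson(x, y),

where `H2` is the binary entropy function. `E` lives in [0, 1]: 0 for a
perfectly co-ordered pair (|r| = 1, either sign), 1 for an uncorrelated
one; for a bivariate normal pair it is a monotone transform of the joint
differential entropy. Two properties matter:

* because the underlying `r` is Pearson's, the *pooled* value reacts to
  condition-specific mean shifts — a shifted case group inflates pooled
  variance, attenuates `r_ab`, and drives `E(r_ab)` toward 1 while the
  within-condition values are unchanged. This is precisely the signal the
  `s` metric needs to detect rewiring driven by differential expression.
* `H2` is flat at r = 0 (quadratic) and steep near |r| = 1, so the
  permutation null — whose shuffled correlations sit near 0 — is
  *compressed*, while changes among strongly co-expressed pairs are
  *amplified*. This gives entropy + s its detection power, and is also the
  source of a limitation noted below.

An alternative entropy construction, `nmi`, is kept behind the same metric
interface: equal-frequency binning of each margin into
`B = max(2, floor(sqrt(n)))` bins (average-tied ranks, deterministic),
plug-in mutual information and marginal entropies in nats, magnitude
`I/sqrt(H(X)H(Y))`, signed by the Spearman direction. It is rank-based and
invariant to monotone transforms of either margin — which also means it is
*provably blind* to purely mean-driven differential signal (mutual
information is unchanged by marginal shifts), and its plug-in bias at
typical group sizes is large relative to the signal. It is therefore not
the default; it is the right choice only when associations are strongly
non-linear and mean shifts are not of interest.

**Degenerate-input convention.** Constant vectors give association 0 for
the correlation-type metrics and 1 (maximal randomness) for `entropy`;
under both conventions a fully degenerate pair yields null contributions
`delta_r = 0` and `s = 0`.

## The pooled permutation background

Per-edge permutation tests cost N_p permutations *per edge*. Instead, one
background is built per run and shared by all edges: for each of N_p
draws, one candidate pair is sampled uniformly with replacement (so the
null reflects the marginal distributions of the genes actually tested),
each gene's values are shuffled independently within condition A and
within condition B (preserving per-condition marginals, destroying the
gene–gene coupling) to give null `r̃_a`, `r̃_b`, and both genes' pooled
vectors are shuffled across all M samples for null `r̃_ab`. The draw
stream is keyed to the lexicographically ordered pair, so results are
invariant to edge orientation; the whole model is reproducible from one
seed.

Empirical p-values use a +1 pseudocount, guaranteeing p ∈ (0, 1] and a
conservative bias of order 1/N_p:

* `delta_r` (right-tailed): `p = (1 + #{null ≥ obs}) / (1 + N_p)`;
* `s` (two-tailed): the smaller of the left and right tail probabilities,
  doubled and capped at 1. The doubled-smaller-tail rule was chosen over a
  centred |s| statistic because the null of `s` need not be symmetric.

One deliberate property of this scheme: the pooled shuffle for `r̃_ab` is
drawn independently of the within-condition shuffles. In the *observed*
statistic on homogeneous data the three estimates are strongly coupled
(`r_ab ≈ (r_a + r_b)/2`, so their errors cancel and observed `s` is very
tight around 0); in the null they are decoupled, so the null of `s` is
wider than the observed-null distribution. The s-test is therefore
conservative on homogeneous data — the test suite checks that the two
distributions agree in location and that the null is the wider one, and
that the realized type-I error is controlled.

Both metric families are corrected separately across all E tested edges
with Benjamini–Hochberg step-up FDR by default (implemented natively; any
other statsmodels correction is selectable), and an edge is significant
when its adjusted p-value is strictly below α (default 0.01). Both
families are always computed; the significance rule (`delta_r`, `s`,
`either`, `both`; default `either`) only filters at output time, so a
single run serves all configurations.

## The benchmark simulator

The generator emulates the situation the method is designed for: a known
regulatory network in which a subset of genes is perturbed in the case
group.

1. **Network.** A random directed tree over `n_tf` TFs and `n_tg` target
   genes: each new TF and every TG attaches to a uniformly chosen existing
   TF. TFs may regulate TFs and TGs; TGs are leaves; every non-root node
   has exactly one regulator.
2. **Expression model.** Correlations decay along graph paths,
   `Σ_ij = ρ^d(i,j)` with d the tree distance — the canonical
   graph-to-covariance construction for expression simulation. For a tree
   and ρ ∈ (0, 1) this matrix is exactly positive definite. Expression is
   drawn i.i.d. per sample from MVN(μ·1, σ²Σ).
3. **Perturbation.** Samples are split into control and case
   (`case_ratio`); `round(perturb_fraction · G)` genes are perturbed, TFs
   first (so perturbations propagate through regulation), then TGs. The
   case group is re-drawn from a modified model:
   * *knockdown* — case mean of perturbed genes × `knockdown_factor`;
   * *diff_expr* — case mean + `de_shift`;
   * *inversion* — every network edge incident to a perturbed gene has its
     correlation negated, and the sign change propagates along all paths
     through that edge. On a tree this equals a diagonal ±1 similarity
     transform, so the matrix stays exactly positive definite;
   * *loss_of_coexpr* — those edges are cut; correlations along paths
     through them become 0. The matrix becomes block-diagonal over tree
     components and again stays positive definite;
   * *mixed* — each perturbed gene is assigned one of the four types
     uniformly at random (cut takes precedence over flip on shared edges).

   A nearest-positive-definite repair (eigenvalue clipping at 1e−8,
   re-normalization to unit diagonal) exists for future non-tree networks
   but is never triggered on trees; correlations among genes whose
   connecting paths avoid perturbed edges are preserved exactly, which the
   tests verify empirically to ±0.05 at m = 10,000.
4. **Noise and truth.** Gaussian observation noise N(0, `noise_sd`²) is
   added to every entry of both groups. The ground truth is every network
   edge incident to at least one perturbed gene — including for the
   mean-only perturbations, since a shifted regulator changes its
   detectable relation to its neighbours (this is exactly what the `s`
   metric targets).

`perturbation="none"` produces a homogeneous null benchmark (empty truth
set) used for the type-I checks.

**Defaults** (the study conditions used throughout the tests and the
acceptance script): `n_tf = 20`, `n_tg = 80`, `m_samples = 100`,
`case_ratio = 0.5`, `perturb_fraction = 0.1`, `ρ = 0.8`, `μ = 6`,
`σ = 1` (arbitrary normalized log-like expression units),
`noise_sd = 0.1`, `knockdown_factor = 0.1` (a strong, 90% knockdown),
`de_shift = 2σ` (a clearly differentially expressed gene). ρ = 0.8 makes
adjacent regulator–target pairs strongly but not deterministically
coupled, with correlation decaying to ~0.1 five steps away.

The `sweep` driver evaluates a grid of `case_ratio` ×
`perturb_fraction` × perturbation type, with `n_sims` independent
benchmarks per cell and `n_runs` pipeline executions per benchmark
(defaults 5 × 5, ratios 0.1–0.9 in steps of 0.1), emitting one tidy row
per run with the confusion counts and MCC over the tested edge universe
(MCC is defined 0 when a denominator factor vanishes).

## What the simulator does and does not capture

The generator produces homogeneous within-condition populations,
multivariate-normal expression, tree-shaped regulation and
noise-free condition labels. Real transcriptomes have within-condition
substructure (subtypes, cell-type composition), non-Gaussian marginals,
feedback and convergent regulation (non-tree graphs), and label noise.
Passing benchmarks therefore demonstrates correctness of the machinery and
the detection geometry of the metrics — not performance on any particular
real dataset. In particular the homogeneity contract matters: the method
assumes samples within a condition are exchangeable, and heterogeneous
conditions will inflate the background model.

## Numerical and reproducibility choices

* All randomness flows through one `numpy` Generator seeded from the
  run's `seed`; the sweep derives child seeds from a master generator, so
  every layer is deterministic. Two runs with the same seed and inputs
  produce byte-identical output tables.
* Correlations are clipped to [−1, 1]; mode-1 pairs are stored in
  lexicographic canonical order; output rows follow input edge order.
* MVN sampling uses the Cholesky factor of the (exactly PD) covariance.
* Delimiters are auto-detected (tab/comma) on input; output is TSV with
  full-precision floats (round-trip exact).

## Known limitations

* **Entropy + delta_r is anti-conservative.** The `H2` transform
  compresses the permutation null near r = 0 but amplifies ordinary
  sampling noise among strongly co-expressed pairs, so the `delta_r`
  family under the entropy metric over-rejects on homogeneous data (the
  `s` family does not — its coupled errors cancel as described above).
  Strict type-I control holds for the correlation metrics; with entropy,
  the `s` rule is the recommended configuration and `delta_r`-based
  entropy results should be treated as exploratory.
* The pooled background assumes the candidate set is reasonably
  homogeneous in its marginals; a candidate set mixing wildly different
  variance structures dilutes the null.
* Heavily imbalanced designs (case fraction far from 0.5) shrink the
  within-condition permutation space of the smaller group and weaken both
  power and calibration; the benchmark trends quantify this.
* No missing data, no more than two conditions, no covariate adjustment.
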