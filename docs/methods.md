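# Methods

`hierconn` analyzes cohorts of symmetric, non-negative, zero-diagonal
connectivity matrices — one N×N matrix per subject, with N regions of
interest (ROIs) as nodes and tractography-style connection strengths as
edge weights. This note records the statistical model behind each stage,
the tunable parameters and their defaults, the numerical choices, and what
the synthetic benchmark does and does not establish about real data.

## Synthetic cohorts with a planted hierarchy

The generator produces the study conditions used throughout the tests: S
subjects (default 14) over N nodes (default 90, labeled with the 90
cerebral AAL regions).

**Planted structure.** Nodes are split recursively into balanced halves to
`tree_depth` tiers (default 3, giving 8 leaf communities; remainders go to
the left child). The tree distance t between two nodes is the number of
tiers between their deepest common cluster and the leaves; the mean weight
of an edge is `base_weight / decay_ratio**t` (defaults 10.0 and 3.8), so
mean connectivity decays geometrically up the hierarchy.

**Sampling.** Edge support is Bernoulli per node pair (`edge_density`) and
shared by the whole cohort; each realized edge draws one cohort-level
weight from an exponential distribution with the planted mean. Subjects
observe that weight times independent gamma noise with mean 1 and
coefficient of variation `subject_cv` (default 0.3, a realistic
inter-subject spread for tract strengths). Spurious edges — the target of
pruning — appear independently per subject on absent pairs
(`spurious_rate` 0.004 per pair and subject) with exponential weights of
mean `spurious_scale` (0.5, well below typical true weights), so their
cross-subject mean is small relative to their variance.

**Why density 0.3.** Real structural connectomes of this size have on the
order of 10% of possible edges, but their sparsity is anatomically
structured. Uniform Bernoulli thinning at equal edge count is spectrally
far noisier: below roughly a quarter of the pairs, the half-split
eigenvector of the normalized connectivity operator drowns in sampling
noise at N = 90 and no spectral method can recover the planted tree. The
default of 0.3 keeps the generator useful as a recovery benchmark while
staying sparse; it is a deliberate compromise between matching the raw
edge count and matching the recoverability of the hierarchy.

**What the generator does not emulate.** Pooled nonzero weights are a
mixture of exponentials whose means span a 3.8³ ≈ 55-fold range — strongly
right-skewed but not itself exponential. Weighted degrees are homogeneous
relative to the weight dispersion yet not closely Gaussian (the shared
exponential draws dominate their variance). Real networks' integrated
topology (strong long-range shortcuts) is absent: strong edges live inside
leaf communities, which lengthens shortest paths relative to shuffled
nulls. Passing the recovery tests therefore shows the pipeline works on
hierarchically ordered weighted networks of this geometry, not that it
reproduces every marginal statistic of a measured connectome.

## Edge pruning by iterative z-testing

Let σ² be the population variance of all strictly positive upper-triangle
entries pooled over subjects. For each edge, the S per-subject weights
(zeros included for subjects lacking the edge) are tested against the null
that they are noise centered at zero with variance σ²:
`z = mean · sqrt(S) / σ`, kept iff `z > Φ⁻¹(1 − p)`. Failures are zeroed
in every subject, σ² is recomputed on the survivors' nonzero entries, and
the sweep repeats until the surviving edge set is exactly stable (the set
is monotone non-increasing, so termination is guaranteed; a 100-iteration
guard exists but is unreachable in practice).

Conventions the procedure fixes, logged on every run: the test is
one-sided toward positive means (weights are non-negative; a two-sided
test would halve power with no interpretational gain); zeros enter the
per-edge sample but not the pooled variance; σ² = 0 (all surviving weights
identical) keeps all nonzero edges and stops, since a zero-mean zero-
variance null is untenable against a positive mean; `p = 1` gives a
critical value of −∞ and returns the input unchanged. No further
multiplicity correction is applied beyond the recompute-and-retest loop —
`p` itself is the swept input parameter.

**Behavior to expect.** The threshold on an edge's cross-subject mean is
`Φ⁻¹(1−p)·σ/√S ≈ 0.83·σ` at p = 0.001, S = 14, and σ is the pooled spread
of surviving weights. On exponential-type weight distributions this is
aggressive: iteration settles on the strong, subject-consistent backbone
and removes essentially all spurious edges, but also most weak true edges
(measured sensitivity on all planted edges is ~5% at the generator
defaults, concentrated in the weakest hierarchy classes). This is a
property of the scheme, not a defect of the implementation: the same
mechanism is what makes the surviving network stable across subjects.

## Degree distributions and model comparison

The weighted degree of a node is its row sum; degrees are pooled
subject-major into an S·N sample with zeros retained. Four families are
fitted by maximum likelihood and ranked by the Kolmogorov–Smirnov (KS)
distance between the sample ECDF and the fitted CDF:

- **normal** — full sample, population MLE (μ, σ);
- **gamma** — full positive sample (zeros excluded: they carry no gamma
  density and break the MLE; `n_used` records the restriction);
- **exponential** — shifted-exponential on the sample right of the
  histogram mode (Freedman–Diaconis bins, most populated bin's center,
  ties toward the smaller center); rate = 1/mean-excess;
- **power law** — continuous Pareto above `x_min`,
  `α = 1 + n_tail / Σ log(x/x_min)`, with `x_min` chosen by exhaustively
  scanning the sorted unique values (tails of at least 10 points) and
  minimizing the tail KS distance.

Tail fits are scored on the tail-restricted sample against the conditional
fitted CDF, and every fit carries its support bound and `n_used`, because
a ranking across families fitted on different supports is only meaningful
with that context. Two estimator properties worth knowing: the KS-optimal
`x_min` drifts upward on data that is Pareto-compatible above the bound
(all larger bounds stay admissible, so noise decides), and a histogram
mode is only accurate to a few bin widths where the density is flat.

## Weighted graph metrics

Weights are normalized by the network maximum (ŵ = w/max w) for both
clustering coefficients, making them scale-invariant and confined to
[0, 1]. The Onnela coefficient averages (ŵ_ij ŵ_ih ŵ_jh)^(1/3) over
neighbor pairs and divides by k(k−1)/2 (k = number of nonzero neighbors);
the Grindrod–Zhang–Horvath (GZH) coefficient is
`Σ_{j≠h} ŵ_ij ŵ_jh ŵ_hi / [(Σ_j ŵ_ij)² − Σ_j ŵ_ij²]` and depends on
weights only. Connection weights are potential-flow quantities, so
distances are d = 1/w (stronger = closer); shortest paths use Johnson's
algorithm; the mean path length L is taken over connected pairs, with the
number of disconnected pairs reported separately rather than penalized.
Betweenness centrality is the standard fractional-credit form normalized
by (N−1)(N−2)/2.

The null model shuffles the complete multiset of N(N−1)/2 upper-triangle
values (zeros included) over positions — the same overall weight histogram
with the structure destroyed. The small-world index is
σ = (C/C_rand)/(L/L_rand) with the null means over `n_rand` shuffles
(default 1000 in the CLI; σ moves by well under a percent between a few
hundred and a few thousand shuffles). A constant matrix is a fixed point
of the shuffle, so σ = 1 exactly — a useful calibration check. On the
synthetic cohorts σ sits near 1 (γ ≈ 2 against λ ≈ 2, see the generator
caveats above), with the GZH variant systematically higher than Onnela
because weak edges inflate the Onnela k(k−1) denominator.

## Self-tuning spectral hierarchy detection

The operator is the symmetric normalization `L = D^{-1/2} W D^{-1/2}`
(D = diagonal strengths); it keeps the eigenproblem symmetric, bounds the
spectrum in [−1, 1], and — importantly for nested weighted structure —
orders split eigenvectors coarse-first, because the weight a split
separates accumulates everything below it in the hierarchy. Zero-degree
nodes are split off as singleton leaves before the eigendecomposition.

For each candidate group number C (2 up to `c_max`, default 8, capped by
cluster size) the top-C eigenvectors X are rotated by a product of
C(C−1)/2 Givens rotations toward one-nonzero-per-row structure,
minimizing `J = Σ_i Σ_j Z_ij² / max_j Z_ij²`. J provably lies in [n, nC],
so quality is `q = 1 − (J − n)/(n(C − 1))` ∈ [0, 1] with 1 best. The
minimization is a bounded gradient descent (analytic gradient with row
maxima held fixed; step 0.1, halved on cost increase and cautiously
re-grown; stop at ΔJ < 1e-6 or 200 iterations) run from the all-zero
angles plus four seeded random starts in (−π/4, π/4)^K — the zero start
alone is a stationary point for exactly symmetric embeddings (rows midway
between two axes), where descent would stall at the cost *maximum*.

The bounded descent is part of the criterion, not a shortcut. An exact
minimizer was tried and rejected: with sparse heavy-tailed noise, large
coordinated rotations can align localized noise eigenvectors almost
perfectly, so exact optimization flattens the quality curve and the group
number selection loses its meaning. Measuring the alignment reachable by
modest rotations preserves the contrast between block structure (already
near-aligned) and noise.

The selected C\* is the largest C whose quality ties the maximum within a
relative 1e-3 — on noiseless nested data, 2, 4 and 8 parts tie at quality
1 and the rule picks 8; any realistic noise breaks the deeper ties and
the curve peaks at the true split. Labels are `argmax_j Z_ij²` per row
(ties to the lowest index). An independent discretization (iterative
row-wise maximum suppression with SVD-based orthogonal alignment of the
row-normalized embedding) cross-checks the rotation-based labels.

Recursion applies the same procedure to each induced submatrix, stopping
at `max_tiers` (default 3), below `min_cluster_size` (4) members, when the
best quality falls under 0.5 (no convincing substructure), or when a
cluster's off-diagonal weights are exactly constant (every balanced cut is
then equally good and a split would be arbitrary — the same degeneracy
makes a constant matrix's shuffled-null comparison meaningless, and both
are flagged). Third-tier results are computed but should be treated as
indicative only: at leaf sizes near 10, split eigenvalues sit at the edge
of the sampling-noise floor.

## Inter-cluster connectivity and decay

For a partition, connectivity from cluster X to Y sums w_ij over ordered
pairs (i ∈ X, j ∈ Y, i ≠ j) and divides by X's total outgoing weight —
rows of the resulting `b` matrix are stochastic, within-cluster edges
count from both endpoints (self-connectivity), and `b` is invariant to
global rescaling. `b` values at one tier are grouped by tree distance
(0 = same cluster, 1 = siblings, …) and averaged with equal weight per
ordered cluster pair.

The per-level decay ratio is exp(−slope) of a least-squares line through
log mean-connectivity versus distance. Self-connectivity at coarse tiers
aggregates every deeper hierarchy level, so it sits far above the
between-cluster trend; the fit therefore uses the strictly between-cluster
distances (t ≥ 1) whenever at least two are available, falling back to the
full profile otherwise. Distances with zero mean are dropped with a
warning rather than pseudocounted. The full vector of adjacent-distance
ratios (including t = 0 → 1) is reported alongside the fitted ratio.

At the generator defaults, clustering a cohort's group-average matrix to
two tiers and profiling tier 2 recovers the planted 3.8-fold decay with a
cohort-to-cohort spread of about ±0.35 and a 20-cohort mean within a few
percent — the quantity `scripts/acceptance.py` recomputes.

## Pipeline

`run_pipeline` sweeps the pruning levels (default 1e-9, 1e-5, 0.001, 1),
runs the enabled stages at each level, and writes per-stage artifacts (KS
table, small-world summary, quality curves, Newick tree, distance profile)
plus a JSON manifest with the configuration and seeds, so every stochastic
stage is exactly reproducible. Clustering and the profile run on the group
average at `cluster_pruning_level` (default: unpruned — on these cohorts
pruning removes the weak between-community edges that carry the coarse
hierarchy signal); a degenerate small-world ratio (no triangles in the
nulls) is recorded as NaN with a warning rather than aborting the sweep.

## Known limitations

- Pruning sensitivity to weak true edges is intrinsically low on
  exponential-type weights (see above); use `p = 1` when the full weighted
  topology matters.
- The small-world index of the synthetic cohorts is near 1, not ≫ 1; the
  generator is not a positive control for small-worldness.
- The spectral recursion needs edge support denser than ~25% of pairs at
  N = 90 under uniform random thinning; real structured sparsity is
  expected to behave better at equal edge count, but that regime is not
  represented by this generator.
- The KS-optimal power-law `x_min` is upward-noisy on Pareto-compatible
  data; compare `n_used` across fits before interpreting a tail ranking.
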