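# hierconn

Statistics of weighted brain networks: robust edge pruning, weighted-degree
distribution comparison, small-world metrics, and self-tuning spectral
detection of hierarchical organization.

## The problem

Structural connectomes derived from diffusion MRI tractography are weighted
graphs — N cortical regions with real-valued connection strengths per
subject — and they are noisy: weak edges may be hallucinated, real ones
obliterated. Most analyses binarize the weights at an arbitrary threshold
and inherit that arbitrariness in every downstream claim (degree
distributions, small-worldness, hubs). `hierconn` implements a pipeline
that works on the weights themselves, for researchers who want
statistically defensible answers to three questions:

1. **Which edges are real?** A cohort-level hypothesis test replaces ad hoc
   thresholding: each edge's per-subject weights `w_ij^(s)` are z-tested
   against the null of zero-mean noise with the pooled variance σ² of all
   nonzero weights, `z = mean_s(w_ij) · √S / σ`, at significance `p`;
   failing edges are zeroed everywhere, σ² is recomputed on the survivors,
   and the test iterates to a fixed point.
2. **How are weighted degrees distributed?** Node strengths
   `k_i = Σ_j w_ij`, pooled over subjects, are fitted by maximum likelihood
   with normal, gamma, shifted-exponential (above the histogram mode) and
   Pareto (above a KS-optimal bound x_min) families, ranked by
   Kolmogorov–Smirnov distance with explicit support bookkeeping.
3. **Is the network hierarchically organized?** Normalized-cuts spectral
   clustering with automatic group-number selection: the top-C eigenvectors
   of `D^{-1/2} W D^{-1/2}` are rotated by Givens rotations toward
   one-nonzero-per-row structure; the alignment cost J ∈ [n, nC] maps to a
   quality `q = 1 − (J−n)/(n(C−1))`, the best C is selected, and the
   procedure recurses. Inter-cluster connectivity
   `b_XY = Σ_{i∈X,j∈Y} w_ij / Σ_{i∈X,j} w_ij` is then profiled against
   tree distance to quantify the per-level connectivity decay.

Weighted clustering coefficients (Onnela and Grindrod–Zhang–Horvath),
1/w shortest paths, betweenness centrality, and a weight-shuffled null
model for the small-world index `σ = (C/C_rand)/(L/L_rand)` round out the
toolkit. Because the matrices such studies analyze are rarely deposited, a
first-class synthetic generator produces cohorts with a planted base-2
hierarchy (default: 90 nodes, 14 subjects, 3.8-fold connectivity decay per
tier, exponential edge weights, per-subject noise, spurious edges) together
with the ground truth needed to score recovery.

## Worked example

Recover a planted hierarchy and its connectivity decay
(`examples/05_hierarchy.py` and `examples/06_cluster_decay.py`):

```python
from hierconn import (GeneratorConfig, generate_cohort, cluster_recursive,
                      distance_profile)

stack, truth = generate_cohort(GeneratorConfig(seed=9))
tree = cluster_recursive(stack.average(), max_tiers=2)
profile = distance_profile(stack.average(), tree, tier=2)
```

```
root quality curve (group number -> quality):
  C = 2:  q = 0.9935  <- selected
  C = 3:  q = 0.8303
  C = 4:  q = 0.8942
  ...
tier 1: 2 clusters, sizes [45, 45]
tier 2: 4 clusters, sizes [23, 22, 24, 21]

tree distance   mean connectivity   ordered cluster pairs
            0              0.8666               4
            1              0.0851               4
            2              0.0241               8
fitted per-level decay ratio: 3.53 (planted: 3.8)
```

The alignment quality peaks decisively at two groups, the recursion
reproduces the planted halves and quarters, and sibling clusters are ~3.5×
more strongly connected than clusters one tier further apart — a single
cohort's estimate of the planted 3.8-fold decay (the 20-cohort mean is
within a few percent; see below). The other examples cover cohort
generation, pruning sweeps, degree fitting, and small-world statistics:

```bash
python examples/01_generate_cohort.py
python examples/02_prune_cohort.py
...
```

A thin CLI mirrors the library for shell use:

```bash
hierconn generate --out cohort/ --seed 1
hierconn prune --cohort cohort/ --p 0.001 --out pruned/
hierconn run-all --out run/ --seed 1
```

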