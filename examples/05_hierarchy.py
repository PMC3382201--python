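"""Recover the planted hierarchy by recursive self-tuning spectral clustering.

At each cluster the group number is chosen by the eigenvector-alignment
quality (1 is perfect one-nonzero-per-row alignment), the cluster is split,
and the procedure recurses on the induced submatrices.
"""

from hierconn import GeneratorConfig, generate_cohort, cluster_recursive
from hierconn.io import tree_to_newick

stack, truth = generate_cohort(GeneratorConfig(seed=9))
tree = cluster_recursive(stack.average(), max_tiers=2)

root_curve = tree.root.quality
print("root quality curve (group number -> quality):")
for c, q in zip(root_curve.group_numbers, root_curve.qualities):
    marker = "  <- selected" if c == root_curve.selected else ""
    print(f"  C = {c}:  q = {q:.4f}{marker}")

for tier in (1, 2):
    sizes = [len(c.members) for c in tree.partition_at(tier)]
    print(f"tier {tier}: {len(sizes)} clusters, sizes {sizes}")

truth_sets = {frozenset(c.members) for c in truth.tree.partition_at(2)}
found_sets = {frozenset(c.members) for c in tree.partition_at(2)}
print(f"tier-2 clusters identical to planted: "
      f"{len(truth_sets & found_sets)} of {len(truth_sets)}")
print("newick (tier labels as 1-based node lists):")
print(tree_to_newick(tree)[:100] + "...")
# The quality curve peaks at C = 2 and the recursion reproduces the planted
# halves (always, at these conditions) and quarters (most cohorts) — the
# base-2 structure is discovered, not assumed.
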