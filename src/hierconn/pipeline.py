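"""End-to-end orchestration: generate/load -> prune -> fit -> metrics ->
cluster -> inter-cluster profile, across a sweep of pruning levels.

Every stage writes its artifacts to disk so stages can be rerun
independently, and a machine-readable manifest (config, seeds, stage list)
makes stochastic stages exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hierconn import cluster_connectivity as cc
from hierconn import degrees, hierarchy, metrics, pruning
from hierconn.io import (
    SubjectStack,
    read_cohort,
    write_cohort,
    write_matrix,
    write_tree_newick,
)
from hierconn.synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_PRUNING_LEVELS = (1e-9, 1e-5, 0.001, 1.0)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``cohort_dir`` (pre-existing cohort on disk) or
    ``generator`` (synthetic cohort parameters) must be provided.
    """

    output_dir: str | Path = "hierconn_run"
    cohort_dir: str | Path | None = None
    generator: GeneratorConfig | None = None
    pruning_levels: tuple[float, ...] = DEFAULT_PRUNING_LEVELS
    n_rand: int = 100
    seed: int = 0
    max_tiers: int = 3
    c_max: int = 8
    #: pruning level for the clustering/profile stage; None clusters the
    #: unpruned group average (pruning at conventional levels removes the
    #: weak between-community edges that carry the coarse hierarchy signal)
    cluster_pruning_level: float | None = None
    stages: tuple[str, ...] = ("prune", "fit", "metrics", "cluster", "profile")
    cc_formulas: tuple[str, ...] = ("onnela", "gzh")
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.cohort_dir is None) == (self.generator is None):
            raise ValueError("provide exactly one of cohort_dir or generator")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")
        for p in self.pruning_levels:
            if not (0 < p <= 1):
                raise ValueError(f"pruning level {p} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            raw["generator"] = GeneratorConfig(**gen)
        for key in ("pruning_levels", "stages", "cc_formulas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages at every pruning level; return the report paths.

    Emits: a KS-by-family-by-level table, a small-world summary per level and
    clustering formula, per-tier quality curves, the hierarchy tree in
    Newick, and the tree-distance connectivity profile with its fitted decay
    ratio. Partial outputs are retained if a later stage fails.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        stack, truth = generate_cohort(config.generator)
        write_cohort(stack, out / "cohort", manifest_extra={
            "generator": config.generator.to_dict()})
        write_tree_newick(truth.tree, stack.roi_labels, out / "planted_tree.nwk")
    else:
        stack = read_cohort(config.cohort_dir)

    manifest = {
        "seed": config.seed,
        "pruning_levels": [float(p) for p in config.pruning_levels],
        "n_rand": config.n_rand,
        "stages": list(config.stages),
        "n_subjects": stack.n_subjects,
        "n_nodes": stack.n_nodes,
    }
    if config.generator is not None:
        manifest["generator"] = config.generator.to_dict()

    report: dict = {"output_dir": str(out)}
    ks_rows, sw_rows = [], []
    stage = "prune"
    try:
        for p in config.pruning_levels:
            tag = f"p{p:g}"
            if "prune" in config.stages:
                stage = "prune"
                result = pruning.prune_iterative(stack, p)
                level_stack = result.pruned_stack
                write_matrix(result.average_matrix, out / f"average_{tag}.tsv")
                np.savetxt(out / f"keep_mask_{tag}.tsv",
                           result.keep_mask.astype(int), fmt="%d", delimiter="\t")
                with open(out / f"prune_log_{tag}.json", "w") as fh:
                    json.dump({
                        "p": p,
                        "n_iterations": result.n_iterations,
                        "joint_variance_trace": result.joint_variance_trace,
                        "n_edges_kept": int(result.keep_mask.sum() // 2),
                    }, fh, indent=2)
            else:
                level_stack = stack

            if "fit" in config.stages:
                stage = "fit"
                sample = degrees.weighted_degrees(level_stack)
                for fit in degrees.compare_fits(sample):
                    ks_rows.append({
                        "p": p, "family": fit.family,
                        "ks_distance": fit.ks_distance,
                        "tail_only": fit.tail_only,
                        "support_bound": fit.support_bound,
                        "n_used": fit.n_used,
                    })

            if "metrics" in config.stages:
                stage = "metrics"
                avg = level_stack.average()
                for formula in config.cc_formulas:
                    try:
                        rep = metrics.small_world_index(
                            avg, n_rand=config.n_rand, seed=config.seed,
                            cc_formula=formula)
                        sw_rows.append({
                            "p": p, "cc_formula": formula, "C": rep.cc_mean,
                            "L": rep.path_mean, "gamma": rep.gamma,
                            "lambda": rep.lambda_, "sw_index": rep.sw_index,
                            "n_infinite_pairs": rep.n_infinite_pairs,
                        })
                    except ValueError as exc:
                        logger.warning(
                            "small-world index degenerate at p=%g (%s): %s",
                            p, formula, exc)
                        sw_rows.append({
                            "p": p, "cc_formula": formula, "C": np.nan,
                            "L": np.nan, "gamma": np.nan, "lambda": np.nan,
                            "sw_index": np.nan, "n_infinite_pairs": -1,
                        })

        if ks_rows:
            pd.DataFrame(ks_rows).to_csv(out / "ks_by_family.tsv", sep="\t", index=False)
            report["ks_table"] = str(out / "ks_by_family.tsv")
        if sw_rows:
            pd.DataFrame(sw_rows).to_csv(out / "small_world.tsv", sep="\t", index=False)
            report["small_world"] = str(out / "small_world.tsv")

        if "cluster" in config.stages:
            stage = "cluster"
            p_ref = config.cluster_pruning_level
            ref_stack = (pruning.prune_iterative(stack, p_ref).pruned_stack
                         if p_ref is not None else stack)
            avg = ref_stack.average()
            tree = hierarchy.cluster_recursive(
                avg, max_tiers=config.max_tiers, c_max=config.c_max)
            write_tree_newick(tree, stack.roi_labels, out / "hierarchy.nwk")
            report["tree"] = str(out / "hierarchy.nwk")
            q_rows = []
            for node in tree.nodes():
                if node.quality is None:
                    continue
                for c, j, q in zip(node.quality.group_numbers,
                                   node.quality.costs, node.quality.qualities):
                    q_rows.append({
                        "tier": node.tier, "cluster_size": len(node.members),
                        "C": c, "cost": j, "quality": q,
                        "selected": node.quality.selected,
                    })
            pd.DataFrame(q_rows).to_csv(out / "quality_curves.tsv", sep="\t", index=False)
            report["quality_curves"] = str(out / "quality_curves.tsv")

            membership = []
            for tier in range(1, tree.depth + 1):
                for ci, cluster in enumerate(tree.partition_at(tier)):
                    for i in cluster.members:
                        membership.append({
                            "tier": tier, "cluster": ci,
                            "roi_index": i + 1, "roi": stack.roi_labels[i],
                        })
            pd.DataFrame(membership).to_csv(out / "membership.tsv", sep="\t", index=False)

            if "profile" in config.stages and tree.depth >= 1:
                stage = "profile"
                tier = min(2, tree.depth)
                profile = cc.distance_profile(avg, tree, tier)
                pd.DataFrame({
                    "tree_distance": profile.distances,
                    "mean_connectivity": profile.mean_connectivity,
                    "log_mean_connectivity": np.log(
                        np.where(profile.mean_connectivity > 0,
                                 profile.mean_connectivity, np.nan)),
                    "n_pairs": profile.n_pairs,
                }).to_csv(out / "distance_profile.tsv", sep="\t", index=False)
                manifest["decay_ratio"] = (
                    None if np.isnan(profile.decay_ratio) else float(profile.decay_ratio))
                report["profile"] = str(out / "distance_profile.tsv")
                report["decay_ratio"] = profile.decay_ratio
    except Exception:
        logger.exception("pipeline failed in stage %r; partial outputs kept in %s",
                         stage, out)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = str(out / "manifest.json")
    return report
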