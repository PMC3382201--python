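"""Statistically robust edge pruning by iterative z-testing.

Rather than thresholding connection weights at an arbitrary cost, every edge
is tested against the null hypothesis that its per-subject weights are noise
centered at zero, with variance given by the pooled variance of all nonzero
weights in the cohort. Edges whose cross-subject mean fails to refute that
null at significance level ``p`` are zeroed in every subject; the pooled
variance is then recomputed on the surviving weights and the test repeated
until the surviving edge set stops changing. The survivor set is monotone
non-increasing, so termination is guaranteed.

Two conventions the procedure fixes (logged at INFO level on every run):
the test is one-sided toward positive means, because weights are
non-negative; and the per-edge sample includes zeros from subjects lacking
the edge, while the pooled variance uses nonzero entries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from hierconn.io import SubjectStack

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 100


@dataclass
class PruneResult:
    """Outcome of iterative pruning.

    Attributes
    ----------
    keep_mask
        Symmetric boolean (N, N); True on surviving edges, False on the
        diagonal and wherever the post-pruning average matrix is zero.
    pruned_stack
        The cohort with pruned edges zeroed in every subject.
    average_matrix
        Entrywise mean of the pruned matrices over subjects.
    per_edge_z
        Symmetric matrix of the last z statistic computed for each edge.
    joint_variance_trace
        Pooled variance sigma^2 per iteration.
    n_iterations
        Number of test sweeps performed.
    significance
        The input level p.
    """

    keep_mask: np.ndarray
    pruned_stack: SubjectStack
    average_matrix: np.ndarray
    per_edge_z: np.ndarray
    joint_variance_trace: list[float]
    n_iterations: int
    significance: float


def joint_nonzero_variance(stack: SubjectStack) -> float:
    """Pooled (population-form) variance of all strictly positive
    upper-triangle entries across every subject, about the pooled mean."""
    iu, ju = np.triu_indices(stack.n_nodes, k=1)
    pooled = stack.matrices[:, iu, ju].ravel()
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        raise ValueError("all-zero stack: no nonzero entries to pool")
    return float(pooled.var(ddof=0))


def edge_z_test(
    values_across_subjects: np.ndarray, sigma2: float, p: float
) -> tuple[bool, float]:
    """One-sided upper-tail z-test of a single edge against the zero-mean null.

    The statistic is ``z = mean(values) * sqrt(S) / sigma``; the edge is kept
    iff ``z`` exceeds the upper-tail critical value at level ``p``.
    """
    values = np.asarray(values_across_subjects, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two subjects")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive; the zero-variance case is "
                         "handled by the iterative caller")
    z = float(values.mean() * np.sqrt(values.size) / np.sqrt(sigma2))
    return z > stats.norm.ppf(1.0 - p), z


def prune_iterative(stack: SubjectStack, p: float) -> PruneResult:
    """Prune a cohort at significance level ``p``.

    At ``p = 1`` the critical value is -inf, so every edge is kept and the
    stack is returned unchanged after a single sweep. Dropped edges never
    return: the test is only re-run on current survivors.
    """
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    logger.info(
        "pruning at p=%g: one-sided upper-tail z-test; per-edge samples "
        "include zeros, pooled variance uses nonzero survivors only", p,
    )
    s, n = stack.n_subjects, stack.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    values = stack.matrices[:, iu, ju]  # (S, E)
    crit = stats.norm.ppf(1.0 - p)

    keep = np.ones(iu.size, dtype=bool)
    z_last = np.zeros(iu.size)
    trace: list[float] = []
    n_iter = 0
    while True:
        n_iter += 1
        if n_iter > MAX_ITERATIONS:
            raise RuntimeError(f"pruning did not converge in {MAX_ITERATIONS} iterations")
        surviving = values[:, keep]
        pooled = surviving[surviving > 0]
        if pooled.size == 0:
            raise ValueError("all-zero stack: no nonzero entries to pool")
        sigma2 = float(pooled.var(ddof=0))
        trace.append(sigma2)
        if sigma2 == 0.0:
            # Identical surviving weights: a zero-mean noise null with zero
            # variance is untenable for any positive mean, so keep all
            # nonzero edges and stop.
            new_keep = keep & (values.sum(axis=0) > 0)
            z_last[keep] = np.inf
            if np.array_equal(new_keep, keep):
                keep = new_keep
                break
            keep = new_keep
            break
        z = values[:, keep].mean(axis=0) * np.sqrt(s) / np.sqrt(sigma2)
        z_last[keep] = z
        new_keep = keep.copy()
        new_keep[keep] = z > crit
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep

    # an edge with no weight anywhere carries no connection even if p = 1
    keep_final = keep & (values.sum(axis=0) > 0)

    pruned = stack.matrices.copy()
    dropped = ~keep
    pruned[:, iu[dropped], ju[dropped]] = 0.0
    pruned[:, ju[dropped], iu[dropped]] = 0.0

    keep_mask = np.zeros((n, n), dtype=bool)
    keep_mask[iu[keep_final], ju[keep_final]] = True
    keep_mask |= keep_mask.T

    per_edge_z = np.zeros((n, n))
    per_edge_z[iu, ju] = z_last
    per_edge_z[ju, iu] = z_last

    pruned_stack = SubjectStack(pruned, list(stack.roi_labels), list(stack.subject_ids))
    return PruneResult(
        keep_mask=keep_mask,
        pruned_stack=pruned_stack,
        average_matrix=pruned_stack.average(),
        per_edge_z=per_edge_z,
        joint_variance_trace=trace,
        n_iterations=n_iter,
        significance=p,
    )
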