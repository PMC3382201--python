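"""Weighted node degrees and parametric distribution fitting.

The weighted degree of a node is the sum of the weights of all edges incident
to it. Degrees are pooled across subjects and nodes (S x N values, zeros
retained) and compared against four parametric families by maximum
likelihood: normal and gamma on the full sample, shifted exponential on the
portion of the sample to the right of the histogram mode, and continuous
Pareto (power law) above an automatically selected left bound ``x_min``
chosen, in the Clauset style, to minimize the Kolmogorov-Smirnov distance
between the tail empirical CDF and the fitted tail CDF. The KS distance is
the goodness-of-fit yardstick throughout.

Tail fits are scored on the tail-restricted sample against the conditional
fitted CDF; every fit records its support bound and the number of values it
actually used, so that rankings across families fitted on different supports
can be interpreted accordingly. Zeros are retained for the normal fit but
excluded from the gamma fit (zero has no density under a gamma with shape
above 1, and the MLE is undefined if zeros are included); this restriction is
reflected in ``n_used``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from hierconn.io import SubjectStack


@dataclass
class DegreeSample:
    """Pooled per-subject, per-node weighted degrees (subject-major order)."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if (self.values < 0).any():
            raise ValueError("degrees must be non-negative")


@dataclass
class DistributionFit:
    """A fitted parametric family with its goodness of fit.

    ``support_bound`` is 0 for full-sample fits and the left bound (histogram
    mode or ``x_min``) for tail fits; ``n_used`` counts the values the fit
    was actually computed on.
    """

    family: str
    params: dict
    support_bound: float
    loglik: float
    ks_distance: float
    n_used: int
    tail_only: bool
    error: str | None = None


def weighted_degrees(stack: SubjectStack) -> DegreeSample:
    """Per-subject, per-node weighted degree (row sums), pooled subject-major."""
    degrees = stack.matrices.sum(axis=2)  # (S, N)
    return DegreeSample(
        degrees.ravel(),
        provenance={"n_subjects": stack.n_subjects, "n_nodes": stack.n_nodes},
    )


def ks_distance(sample: np.ndarray, cdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """Supremum gap between the sample ECDF and a fitted CDF."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    f = cdf(x)
    upper = np.arange(1, n + 1) / n
    lower = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(f - upper), np.abs(f - lower))))


def fit_full(sample: DegreeSample, family: str) -> DistributionFit:
    """Full-sample MLE fit of the normal or gamma family."""
    x = sample.values
    if x.size == 0:
        raise ValueError("empty sample")
    if family == "normal":
        mu, sigma = float(x.mean()), float(x.std(ddof=0))
        dist = stats.norm(loc=mu, scale=sigma)
        return DistributionFit(
            family="normal",
            params={"mu": mu, "sigma": sigma},
            support_bound=0.0,
            loglik=float(dist.logpdf(x).sum()),
            ks_distance=ks_distance(x, dist.cdf),
            n_used=int(x.size),
            tail_only=False,
        )
    if family == "gamma":
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError("gamma fit requires strictly positive values")
        shape, _, scale = stats.gamma.fit(pos, floc=0)
        dist = stats.gamma(shape, loc=0, scale=scale)
        return DistributionFit(
            family="gamma",
            params={"shape": float(shape), "scale": float(scale)},
            support_bound=0.0,
            loglik=float(dist.logpdf(pos).sum()),
            ks_distance=ks_distance(pos, dist.cdf),
            n_used=int(pos.size),
            tail_only=False,
        )
    raise ValueError(f"fit_full supports 'normal' and 'gamma', not {family!r}")


def sample_mode(sample: DegreeSample | np.ndarray) -> float:
    """Histogram mode: center of the most populated Freedman-Diaconis bin.

    Ties are broken toward the smaller bin center. A constant sample returns
    the constant.
    """
    x = sample.values if isinstance(sample, DegreeSample) else np.asarray(sample, float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.ptp(x) == 0:
        return float(x[0])
    edges = np.histogram_bin_edges(x, bins="fd")
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[int(np.argmax(counts))])  # argmax takes first (smallest) on ties


def fit_exponential_tail(
    sample: DegreeSample | np.ndarray, left_bound: float
) -> DistributionFit:
    """Shifted-exponential MLE on the values above ``left_bound``.

    The rate is the reciprocal mean excess over the bound; the KS distance is
    computed on the restricted sample against the conditional fitted CDF.
    """
    x = sample.values if isinstance(sample, DegreeSample) else np.asarray(sample, float)
    tail = x[x > left_bound]
    if tail.size < 10:
        raise ValueError(
            f"insufficient data: only {tail.size} values above {left_bound}"
        )
    scale = float((tail - left_bound).mean())
    dist = stats.expon(loc=left_bound, scale=scale)
    return DistributionFit(
        family="exponential",
        params={"rate": 1.0 / scale, "left_bound": float(left_bound)},
        support_bound=float(left_bound),
        loglik=float(dist.logpdf(tail).sum()),
        ks_distance=ks_distance(tail, dist.cdf),
        n_used=int(tail.size),
        tail_only=True,
    )


def _pareto_scan(x: np.ndarray, min_tail: int = 10) -> tuple[float, float, float, int]:
    """Scan candidate x_min over the sorted unique values; return
    (alpha, x_min, ks, n_tail) minimizing the tail KS distance."""
    xs = np.sort(x)
    n = xs.size
    log_xs = np.log(xs)
    # suffix sums of log x for O(1) alpha at each candidate
    suffix_log = np.concatenate([np.cumsum(log_xs[::-1])[::-1], [0.0]])
    uniq, first_idx = np.unique(xs, return_index=True)
    best = None
    for xmin, start in zip(uniq, first_idx):
        n_tail = n - start
        if n_tail < min_tail:
            break
        sum_log_ratio = suffix_log[start] - n_tail * np.log(xmin)
        if sum_log_ratio <= 0:  # degenerate tail (all values equal)
            continue
        alpha = 1.0 + n_tail / sum_log_ratio
        tail = xs[start:]
        cdf = 1.0 - (xmin / tail) ** (alpha - 1.0)
        upper = np.arange(1, n_tail + 1) / n_tail
        lower = np.arange(0, n_tail) / n_tail
        ks = float(np.max(np.maximum(np.abs(cdf - upper), np.abs(cdf - lower))))
        if best is None or ks < best[2]:
            best = (float(alpha), float(xmin), ks, int(n_tail))
    if best is None:
        raise ValueError("degenerate tail: no candidate x_min with a valid Pareto fit")
    return best


def fit_powerlaw(
    sample: DegreeSample | np.ndarray, x_min: float | None = None
) -> DistributionFit:
    """Continuous-Pareto MLE with automatic ``x_min`` selection.

    ``alpha = 1 + n_tail / sum(log(x / x_min))`` over the tail ``x >= x_min``;
    when ``x_min`` is not forced it is chosen by exhaustively scanning the
    sorted unique sample values and minimizing the KS distance between the
    tail ECDF and the fitted Pareto CDF.
    """
    x = sample.values if isinstance(sample, DegreeSample) else np.asarray(sample, float)
    pos = x[x > 0]
    if x_min is None:
        if np.unique(pos).size < 25:
            raise ValueError("need at least 25 distinct positive values")
        alpha, x_min, ks, n_tail = _pareto_scan(pos)
    else:
        tail = np.sort(pos[pos >= x_min])
        if tail.size < 2 or np.ptp(tail) == 0:
            raise ValueError("degenerate tail above the forced x_min")
        sum_log_ratio = float(np.log(tail / x_min).sum())
        alpha = 1.0 + tail.size / sum_log_ratio
        cdf = lambda v: 1.0 - (x_min / v) ** (alpha - 1.0)
        ks = ks_distance(tail, cdf)
        n_tail = tail.size
    tail = pos[pos >= x_min]
    loglik = float(
        np.sum(np.log(alpha - 1.0) - np.log(x_min) - alpha * np.log(tail / x_min))
    )
    return DistributionFit(
        family="powerlaw",
        params={"alpha": float(alpha), "x_min": float(x_min)},
        support_bound=float(x_min),
        loglik=loglik,
        ks_distance=float(ks),
        n_used=int(n_tail),
        tail_only=True,
    )


def compare_fits(sample: DegreeSample) -> list[DistributionFit]:
    """Fit all four families and rank them by KS distance (ascending).

    Normal and gamma are fitted to the full sample; the exponential to the
    tail right of the histogram mode; the power law above its own ``x_min``.
    A family whose fit fails is reported with ``error`` set and sorts last.
    """
    fits: list[DistributionFit] = []
    mode = sample_mode(sample)
    for family, fitter in (
        ("normal", lambda: fit_full(sample, "normal")),
        ("gamma", lambda: fit_full(sample, "gamma")),
        ("exponential", lambda: fit_exponential_tail(sample, mode)),
        ("powerlaw", lambda: fit_powerlaw(sample)),
    ):
        try:
            fits.append(fitter())
        except ValueError as exc:
            fits.append(
                DistributionFit(
                    family=family,
                    params={},
                    support_bound=float("nan"),
                    loglik=float("nan"),
                    ks_distance=float("inf"),
                    n_used=0,
                    tail_only=family in ("exponential", "powerlaw"),
                    error=str(exc),
                )
            )
    return sorted(fits, key=lambda f: f.ks_distance)


def quantile_report(sample: DegreeSample, fit: DistributionFit) -> pd.DataFrame:
    """Empirical vs fitted-normal quantiles at percentiles 1..99 (Q-Q table)."""
    if fit.family != "normal":
        raise ValueError("quantile_report expects a fitted normal")
    q = np.arange(1, 100)
    empirical = np.percentile(sample.values, q)
    fitted = stats.norm.ppf(q / 100.0, loc=fit.params["mu"], scale=fit.params["sigma"])
    return pd.DataFrame(
        {"percentile": q, "empirical": empirical, "fitted_normal": fitted}
    )
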