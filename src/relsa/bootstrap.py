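"""Bias-corrected and accelerated (BCa) bootstrap intervals.

Group means of per-animal maximum severity scores, and the centroids of
the severity clusters, are typically estimated from small cohorts; BCa
intervals adjust the plain percentile bootstrap for median bias (z0) and
for skewness of the statistic (acceleration a, from the jackknife), which
matters because maximum-score distributions are bounded below and often
right-skewed.

The implementation follows Efron's construction: with ``B`` resamples and
point estimate ``t0``,

    z0 = Phi^-1( #{t*_b < t0} / B ),
    a  = sum d_i^3 / (6 (sum d_i^2)^(3/2)),   d_i = mean(t_(i)) - t_(i),

where ``t_(i)`` are the leave-one-out (jackknife) values, and the interval
endpoints are the bootstrap quantiles at

    alpha_j = Phi( z0 + (z0 + z_alpha_j) / (1 - a (z0 + z_alpha_j)) ).

When the jackknife is degenerate (all leave-one-out values equal) or every
replicate falls on one side of the estimate, the plain percentile interval
is returned with a warning and the fallback is recorded in the result.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .containers import BootstrapResult, SeverityLevels

__all__ = ["bootstrap_bca", "bootstrap_cluster_centroids"]

_NAMED_STATS: dict[str, Callable] = {"mean": np.mean, "median": np.median}


def _resolve_statistic(statistic) -> tuple[str, Callable]:
    if callable(statistic):
        return getattr(statistic, "__name__", "statistic"), statistic
    try:
        return str(statistic), _NAMED_STATS[str(statistic)]
    except KeyError:
        raise ValueError(
            f"unknown statistic {statistic!r}; use one of {sorted(_NAMED_STATS)} "
            "or a callable"
        ) from None


def bootstrap_bca(
    data,
    statistic="mean",
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    label: str | None = None,
) -> BootstrapResult:
    """BCa confidence interval for a statistic of a 1-D sample.

    Parameters
    ----------
    data : array-like, length >= 2
        Observations (e.g. per-animal maximum severity scores of a group).
    statistic : "mean", "median" or callable
        Deterministic aggregator applied to each resample.
    B : int
        Number of bootstrap replicates (default 10,000).
    seed : int
        Seed of the single generator driving all resampling.
    level : float
        Coverage probability of the two-sided interval.
    """
    x = np.asarray(data, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations for the jackknife acceleration")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    name, fn = _resolve_statistic(statistic)
    label = label if label is not None else name
    t0 = float(fn(x))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(int(B), n))
    if fn is np.mean:
        reps = x[idx].mean(axis=1)
    else:
        reps = np.array([fn(x[row]) for row in idx], dtype=float)

    alpha = (1.0 - level) / 2.0
    fallback = False
    prop_below = float(np.mean(reps < t0))
    if prop_below <= 0.0 or prop_below >= 1.0:
        fallback = True
        z0 = float("nan")
        a = float("nan")
    else:
        z0 = float(ndtri(prop_below))
        # jackknife leave-one-out values for the acceleration
        if fn is np.mean:
            loo = (x.sum() - x) / (n - 1)
        else:
            loo = np.array(
                [fn(np.delete(x, i)) for i in range(n)], dtype=float
            )
        d = loo.mean() - loo
        denom = np.sum(d**2)
        if denom <= 0.0:
            fallback = True
            a = float("nan")
        else:
            a = float(np.sum(d**3) / (6.0 * denom**1.5))

    if fallback:
        if np.ptp(reps) > 0:
            warnings.warn(
                "degenerate BCa correction (flat jackknife or one-sided "
                "replicates); falling back to the percentile interval",
                RuntimeWarning,
                stacklevel=2,
            )
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    else:
        z_lo, z_hi = ndtri(alpha), ndtri(1.0 - alpha)
        a1 = float(ndtr(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo))))
        a2 = float(ndtr(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi))))
        lo, hi = np.quantile(reps, [a1, a2])

    return BootstrapResult(
        statistic_label=label,
        point_estimate=t0,
        B=int(B),
        ci_low=float(lo),
        ci_high=float(hi),
        level=float(level),
        seed=int(seed),
        z0=z0,
        acceleration=a,
        fallback_percentile=fallback,
    )


def bootstrap_cluster_centroids(
    values,
    levels: SeverityLevels,
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> list[BootstrapResult]:
    """BCa intervals for each severity-cluster centroid.

    Cluster memberships are held fixed at the fitted assignment; within
    each cluster the member values (one per animal) are resampled with
    replacement and the cluster mean recomputed, so the interval reflects
    sampling variability of the centroid given the identified levels.
    Clusters with a single member are skipped (no jackknife is defined).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size != levels.assignments.size:
        raise ValueError("values and fitted assignments differ in length")
    out: list[BootstrapResult] = []
    for j in range(levels.k):
        members = x[levels.assignments == j]
        if members.size < 2:
            continue
        out.append(
            bootstrap_bca(
                members,
                statistic="mean",
                B=B,
                seed=seed + j,
                level=level,
                label=f"centroid_L{j + 1}",
            )
        )
    return out
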