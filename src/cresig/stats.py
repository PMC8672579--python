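"""Significance of region-set overlap and simple set enrichment.

The Monte-Carlo null draws, in each iteration, as many *distinct*
regions from a background pool as there are query regions ("without
resampling": sampling without replacement within an iteration;
iterations are independent), and counts overlaps with a validated
region set.  Two p-values are reported: the add-one empirical estimate
``(#{null >= observed} + 1) / (n_iter + 1)`` and a one-sided normal
approximation from the null mean and SD.

``count_mode`` controls what is counted:

* ``"validated"`` (default) — validated regions hit by >= 1 query
  region ("4 of the 22 validated enhancers were recovered"),
* ``"query"`` — query regions hitting >= 1 validated region.

Poisson enrichment gives the upper-tail probability P(X >= k) for an
observed count against a Poisson expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .intervals import IntervalSet

COUNT_MODES = ("validated", "query")


@dataclass(frozen=True)
class MonteCarloResult:
    observed: int
    n_iter: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_normal: float | None  # None when the null is degenerate (SD = 0)
    seed: int
    count_mode: str

    @property
    def degenerate_null(self) -> bool:
        return self.p_normal is None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_iter": self.n_iter,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_empirical": self.p_empirical,
            "p_normal": self.p_normal,
            "seed": self.seed,
            "count_mode": self.count_mode,
        }


@dataclass(frozen=True)
class EnrichmentResult:
    k_observed: int
    lambda_expected: float
    p_poisson: float


def count_overlap(query: IntervalSet, validated: IntervalSet, count_mode: str = "validated") -> int:
    """Overlap count between two region sets under ``count_mode``."""
    if count_mode == "validated":
        return len(validated.overlaps_any(query))
    if count_mode == "query":
        return len(query.overlaps_any(validated))
    raise ValueError(f"count_mode must be one of {COUNT_MODES}, got {count_mode!r}")


def monte_carlo_overlap(
    query: IntervalSet,
    validated: IntervalSet,
    pool: IntervalSet,
    n_iter: int = 1000,
    seed: int = 0,
    count_mode: str = "validated",
) -> MonteCarloResult:
    """Monte-Carlo overlap test of ``query`` vs ``validated`` against a
    null of random draws from ``pool``.

    Random regions are whole pool intervals (peak resampling, not
    coordinate shuffling).  Identical seeds give bit-identical results.
    """
    if count_mode not in COUNT_MODES:
        raise ValueError(f"count_mode must be one of {COUNT_MODES}, got {count_mode!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pool_intervals = list(pool)
    n_query = len(query)
    if len(pool_intervals) < n_query:
        raise ValueError(f"pool has {len(pool_intervals)} regions but query needs {n_query}")

    observed = count_overlap(query, validated, count_mode)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        idx = rng.choice(len(pool_intervals), size=n_query, replace=False)
        draw = IntervalSet(pool_intervals[j] for j in idx)
        counts[i] = count_overlap(draw, validated, count_mode)

    null_mean = float(np.mean(counts))
    null_sd = float(np.std(counts, ddof=1)) if n_iter > 1 else 0.0
    p_empirical = (int(np.sum(counts >= observed)) + 1) / (n_iter + 1)
    if null_sd > 0:
        p_normal = float(sps.norm.sf((observed - null_mean) / null_sd))
    else:
        p_normal = None
    return MonteCarloResult(
        observed=observed,
        n_iter=n_iter,
        null_mean=null_mean,
        null_sd=null_sd,
        p_empirical=p_empirical,
        p_normal=p_normal,
        seed=seed,
        count_mode=count_mode,
    )


def poisson_enrichment(k_observed: int, lambda_expected: float) -> EnrichmentResult:
    """Upper-tail Poisson probability P(X >= k) of seeing ``k_observed``
    or more events when ``lambda_expected`` are expected."""
    if lambda_expected <= 0:
        raise ValueError("lambda_expected must be > 0")
    if k_observed < 0:
        raise ValueError("k_observed must be >= 0")
    p = 1.0 if k_observed == 0 else float(sps.poisson.sf(k_observed - 1, lambda_expected))
    return EnrichmentResult(k_observed, lambda_expected, p)


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_common: int
    pct_of_a: float
    pct_of_b: float


def overlap_summary(set_a: set, set_b: set) -> OverlapSummary:
    """Exact sizes and intersection of two gene sets, with the
    intersection as a rounded percentage of each side."""
    a, b = set(set_a), set(set_b)
    common = len(a & b)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_common=common,
        pct_of_a=round(100.0 * common / len(a)) if a else 0.0,
        pct_of_b=round(100.0 * common / len(b)) if b else 0.0,
    )
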