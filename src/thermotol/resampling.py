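"""Difference-in-medians randomization tests and percentile bootstrap CIs.

This module is the inference engine used throughout the package. Thermal
tolerance scores (knockdown / recovery times, CTmin / CTmax) are typically
non-normal with heterogeneous variance and skew, so group comparisons use a
two-sample randomization test whose statistic is the difference of group
medians, ``Md = median(a) - median(b)``, and uncertainty on each group median
is expressed as a percentile bootstrap confidence interval.

Conventions
-----------
* Two-tailed p-values count null draws with ``|T*| >= |T_obs|`` (absolute
  value method, not tail-doubling).
* Monte-Carlo p-values carry the add-one correction
  ``p = (1 + #extreme) / (n_perm + 1)`` so that p is never exactly zero.
* When the number of distinct group assignments is at most
  ``enumeration_threshold`` every assignment is enumerated and the p-value is
  exact (no add-one correction; the observed assignment is one of those
  enumerated so p > 0 regardless).
* Comparisons between ``|T*|`` and ``|T_obs|`` use exact floating-point
  equality; heavy ties therefore make the test (mildly) conservative.
* The null resampling stream depends only on the pooled multiset of values,
  the smaller group size and the seed, so swapping the two groups with the
  same seed yields the identical p-value and a negated ``md_diff``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import ConfigError

__all__ = [
    "PermutationResult",
    "BootstrapCI",
    "median",
    "median_diff",
    "randomization_test",
    "bootstrap_median_ci",
]

# rows per chunk when vectorising resampling draws; bounds peak memory
_CHUNK_ROWS = 20_000


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-sample difference-in-medians randomization test."""

    md_a: float
    md_b: float
    md_diff: float
    p_value: float
    n_perm: int
    exact: bool
    seed: int | None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval for a sample median."""

    median: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 10_000
    seed: int | None = None


def _as_values(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def median(values) -> float:
    """Sample median: middle order statistic, mean of the two middle ones
    for even n."""
    return float(np.median(_as_values(values, "values")))


def median_diff(a, b) -> float:
    """``median(a) - median(b)`` — the Md test statistic."""
    return median(a) - median(b)


def _int_or_none(seed) -> int | None:
    return int(seed) if isinstance(seed, (int, np.integer)) else None


def randomization_test(
    a,
    b,
    n_perm: int = 100_000,
    seed=None,
    enumeration_threshold: int = 100_000,
) -> PermutationResult:
    """Two-sample randomization test on the difference of group medians.

    The pooled values are repeatedly re-partitioned into groups of the
    observed sizes without replacement; the two-tailed p-value is the
    fraction of re-partitions whose ``|Md*|`` reaches ``|Md_obs|``. If the
    number of distinct partitions ``C(n, min(|a|, |b|))`` does not exceed
    ``enumeration_threshold``, all partitions are enumerated and the p-value
    is exact (``exact=True``); otherwise ``n_perm`` Monte-Carlo draws with
    the add-one correction are used.

    Parameters
    ----------
    a, b
        The two samples (each at least 2 finite observations).
    n_perm
        Monte-Carlo resampling budget (ignored in exact mode).
    seed
        Integer seed or ``numpy`` Generator for the Monte-Carlo draws.
    """
    arr_a = _as_values(a, "a")
    arr_b = _as_values(b, "b")
    if arr_a.size < 2 or arr_b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")

    md_a = float(np.median(arr_a))
    md_b = float(np.median(arr_b))
    t_obs = md_a - md_b
    abs_obs = abs(t_obs)

    # Canonical form: sorted pool + smaller group size. This makes the null
    # statistic stream independent of which sample was passed first.
    pooled = np.sort(np.concatenate([arr_a, arr_b]))
    n = pooled.size
    k = min(arr_a.size, arr_b.size)

    n_partitions = comb(n, k)
    if n_partitions <= enumeration_threshold:
        idx = np.fromiter(
            (i for c in combinations(range(n), k) for i in c),
            dtype=np.intp,
            count=n_partitions * k,
        ).reshape(n_partitions, k)
        mask = np.zeros((n_partitions, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        med_sub = np.median(pooled[idx], axis=1)
        med_rest = np.median(
            np.broadcast_to(pooled, mask.shape)[~mask].reshape(n_partitions, n - k),
            axis=1,
        )
        n_extreme = int(np.count_nonzero(np.abs(med_sub - med_rest) >= abs_obs))
        p = n_extreme / n_partitions
        return PermutationResult(
            md_a=md_a,
            md_b=md_b,
            md_diff=t_obs,
            p_value=p,
            n_perm=n_partitions,
            exact=True,
            seed=_int_or_none(seed),
        )

    rng = np.random.default_rng(seed)
    n_extreme = 0
    base = np.arange(n)
    done = 0
    while done < n_perm:
        m = min(_CHUNK_ROWS, n_perm - done)
        perm = rng.permuted(np.tile(base, (m, 1)), axis=1)
        vals = pooled[perm]
        t_null = np.median(vals[:, :k], axis=1) - np.median(vals[:, k:], axis=1)
        n_extreme += int(np.count_nonzero(np.abs(t_null) >= abs_obs))
        done += m
    p = (1 + n_extreme) / (n_perm + 1)
    return PermutationResult(
        md_a=md_a,
        md_b=md_b,
        md_diff=t_obs,
        p_value=p,
        n_perm=n_perm,
        exact=False,
        seed=_int_or_none(seed),
    )


def bootstrap_median_ci(
    values,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed=None,
) -> BootstrapCI:
    """Percentile bootstrap confidence interval for the median.

    Draws ``n_boot`` resamples with replacement of the original sample size
    and returns the ``((1-level)/2, 1-(1-level)/2)`` quantiles of the
    resampled medians (linear interpolation between order statistics).
    """
    arr = _as_values(values, "values")
    if arr.size < 2:
        raise ValueError("bootstrap needs at least 2 observations")
    if not 0.0 < level < 1.0:
        raise ConfigError("level must be in (0, 1)")
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")

    rng = np.random.default_rng(seed)
    n = arr.size
    meds = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(_CHUNK_ROWS, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        meds[done : done + m] = np.median(arr[idx], axis=1)
        done += m
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(meds, [alpha, 1.0 - alpha])
    obs = float(np.median(arr))
    if not lower <= obs <= upper:  # extreme small-sample pathology only
        warnings.warn(
            "sample median falls outside its percentile bootstrap interval",
            RuntimeWarning,
            stacklevel=2,
        )
    return BootstrapCI(
        median=obs,
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        seed=_int_or_none(seed),
    )
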