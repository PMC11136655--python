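"""Permutation tests, FDR control and bootstrap confidence intervals.

Non-parametric statistical routines used throughout the analyses: two-sample
and paired permutation tests (label shuffling / pair swapping), the
Benjamini-Hochberg step-up procedure for false-discovery-rate control, and
percentile bootstrap confidence intervals for the mean.

All randomized procedures take an explicit ``rng`` (or integer seed) and are
reproducible. P-values follow the +1 convention (the observed statistic is
counted as one permutation), so the smallest attainable p-value with
``runs`` permutations is ``1 / (runs + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "permutation_test",
    "paired_permutation_test",
    "bh_fdr",
    "bootstrap_ci",
]


@dataclass
class PermutationResult:
    """Outcome of a permutation test."""

    observed: float
    permuted: np.ndarray
    p_value: float
    sided: str
    n_runs: int
    seed_state: object = field(default=None, repr=False)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _pvalue(observed: float, permuted: np.ndarray, sided: str) -> float:
    n = len(permuted)
    if sided == "two":
        count = np.sum(np.abs(permuted) >= abs(observed))
    elif sided == "greater":
        count = np.sum(permuted >= observed)
    elif sided == "less":
        count = np.sum(permuted <= observed)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float((1 + count) / (1 + n))


def permutation_test(
    group_a,
    group_b,
    statistic=None,
    sided: str = "two",
    runs: int = 1000,
    rng=None,
) -> PermutationResult:
    """Two-sample permutation test by joint label shuffling.

    The default statistic is the difference of group means
    ``mean(a) - mean(b)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if statistic is None:
        statistic = lambda x, y: float(np.mean(x) - np.mean(y))  # noqa: E731
    gen = _as_rng(rng)
    pooled = np.concatenate([a, b])
    na = a.size
    observed = statistic(a, b)
    permuted = np.empty(runs)
    for i in range(runs):
        perm = gen.permutation(pooled)
        permuted[i] = statistic(perm[:na], perm[na:])
    p = _pvalue(observed, permuted, sided)
    return PermutationResult(observed, permuted, p, sided, runs)


def paired_permutation_test(
    pairs,
    sided: str = "two",
    runs: int = 1000,
    rng=None,
) -> PermutationResult:
    """Paired permutation test: members of each pair are randomly swapped.

    ``pairs`` is an (n, 2) array; the statistic is the mean of the paired
    differences ``pairs[:, 0] - pairs[:, 1]``.
    """
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    gen = _as_rng(rng)
    diffs = p[:, 0] - p[:, 1]
    observed = float(np.mean(diffs))
    signs = gen.integers(0, 2, size=(runs, diffs.size)) * 2 - 1
    permuted = (signs * diffs).mean(axis=1)
    pval = _pvalue(observed, permuted, sided)
    return PermutationResult(observed, permuted, pval, sided, runs)


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, adjusted)`` arrays aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, adjusted


def bootstrap_ci(values, level: float = 0.90, runs: int = 1000, rng=None):
    """Percentile bootstrap confidence interval for the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    gen = _as_rng(rng)
    idx = gen.integers(0, x.size, size=(runs, x.size))
    means = x[idx].mean(axis=1)
    lo = (1 - level) / 2
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1 - lo)),
    )
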