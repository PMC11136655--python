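"""Comparing model unit traces to repeat-structured neural recordings.

Recordings are repeat x timepoint matrices per (neuron type, stimulus)
combination. The module provides:

* repeat detrending (per-repeat z-scoring followed by a common affine
  rescaling so the repeat-averaged trace keeps its original mean and
  standard deviation over time);
* split-half reliability and a d-prime responsiveness criterion against a
  null built from the all-stimulus repeat pool with random time reversal and
  sign flips (responsive iff d' > 1);
* a noise-corrected R^2 that estimates agreement with the infinite-repeat
  mean response using an unbiased signal-power correction, invariant to
  affine transformation and sign of the model trace;
* a causal linear filter fit (10 taps plus offset) aligning a model unit
  trace to a calcium trace, and a cross-validated all-unit ridge mapping;
* a simple response-adaptation mechanism: whenever the raw response repeats
  exactly across consecutive frames, the output decays toward baseline with
  a per-frame rate (default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import r_squared

__all__ = [
    "RepeatSet",
    "ReliabilityReport",
    "detrend_repeats",
    "split_half_r2",
    "responsiveness",
    "noise_corrected_r2",
    "fit_causal_filter",
    "all_unit_mapping",
    "adaptation",
]


@dataclass
class RepeatSet:
    """Repeat x timepoint responses for one neuron type and one stimulus."""

    responses: np.ndarray
    frame_rate: float = 30.0
    stimulus_id: str = ""

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be (repeats, timepoints)")

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.responses.mean(axis=0)


@dataclass
class ReliabilityReport:
    d_prime: float
    responsive: bool
    actual_r2: np.ndarray
    null_r2: np.ndarray


def detrend_repeats(r: RepeatSet) -> RepeatSet:
    """Remove per-repeat drift while preserving the repeat-average statistics.

    Each repeat is z-scored across time; all z-scored repeats are then passed
    through one common affine map chosen so the output repeat-averaged trace
    has exactly the mean and standard deviation over time of the input
    repeat-averaged trace. Identical repeats come back unchanged, and the
    operation is idempotent. Zero-variance repeats are excluded with a
    warning.
    """
    X = r.responses
    stds = X.std(axis=1)
    keep = stds > 0
    if not keep.all():
        warnings.warn(f"excluding {np.sum(~keep)} zero-variance repeat(s)",
                      stacklevel=2)
        X = X[keep]
        stds = stds[keep]
    if X.shape[0] == 0:
        raise ValueError("no repeats with nonzero variance")
    orig_avg = X.mean(axis=0)
    mu, sigma = orig_avg.mean(), orig_avg.std()
    Z = (X - X.mean(axis=1, keepdims=True)) / stds[:, None]
    zavg = Z.mean(axis=0)
    zm, zs = zavg.mean(), zavg.std()
    if zs == 0:
        out = Z - zm + mu  # degenerate: flat average; keep the mean only
    else:
        out = (Z - zm) / zs * sigma + mu
    return RepeatSet(out, r.frame_rate, r.stimulus_id)


def split_half_r2(responses: np.ndarray, rng) -> float:
    """Squared Pearson correlation between the averages of two random
    equally sized halves of the repeats."""
    R = responses.shape[0]
    half = R // 2
    perm = rng.permutation(R)
    a = responses[perm[:half]].mean(axis=0)
    b = responses[perm[half:2 * half]].mean(axis=0)
    return r_squared(a, b)


def responsiveness(r: RepeatSet, all_stim_pool, runs: int = 50,
                   rng=None) -> ReliabilityReport:
    """Split-half reliability d' against a pooled, decorrelated null.

    The actual distribution contains ``runs`` random-half-split R^2 values.
    The null draws repeat groups of matched size uniformly from the pooled
    repeats across all stimuli, independently time-reversing (p = 0.5) and
    sign-flipping (p = 0.5) each drawn repeat, breaking temporal co-variation.
    d' = (mu_actual - mu_null) / sqrt((var_actual + var_null) / 2); a
    combination is responsive iff d' > 1.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if r.n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    pool = np.concatenate([np.asarray(p.responses if isinstance(p, RepeatSet) else p)
                           for p in all_stim_pool], axis=0)
    half = r.n_repeats // 2
    actual = np.array([split_half_r2(r.responses, gen) for _ in range(runs)])
    null = np.empty(runs)
    for i in range(runs):
        idx = gen.choice(pool.shape[0], size=2 * half, replace=False)
        draws = pool[idx].copy()
        rev = gen.random(2 * half) < 0.5
        draws[rev] = draws[rev, ::-1]
        flip = gen.random(2 * half) < 0.5
        draws[flip] *= -1.0
        a = draws[:half].mean(axis=0)
        b = draws[half:].mean(axis=0)
        null[i] = r_squared(a, b)
    actual_f = actual[np.isfinite(actual)]
    null_f = null[np.isfinite(null)]
    denom = np.sqrt((actual_f.var() + null_f.var()) / 2.0)
    d = float((actual_f.mean() - null_f.mean()) / denom) if denom > 0 else 0.0
    return ReliabilityReport(d, d > 1.0, actual, null)


def noise_corrected_r2(model_trace: np.ndarray, r: RepeatSet) -> float:
    """R^2 between a model trace and the infinite-repeat mean response.

    With repeats y_i = mu + eps_i (independent noise of per-timepoint
    variance sigma^2), the naive squared correlation between the model x and
    the repeat average is biased by the noise in the average. Both the
    squared covariance and the repeat-average variance are corrected by
    unbiased noise-power estimates:

        num = cov(x, ybar)^2 - var(x) * sigma^2 / (n (T-1))
        den = var(x) * (var(ybar) - sigma^2 / n)

    The estimate is invariant to affine transformation and sign of the model
    trace. Degenerate inputs return NaN.
    """
    x = np.asarray(model_trace, dtype=float)
    Y = r.responses
    n, T = Y.shape
    if n < 2 or x.shape[0] != T:
        raise ValueError("need >= 2 repeats and aligned traces")
    if np.std(x) == 0:
        return float("nan")
    ybar = Y.mean(axis=0)
    sigma2 = float(Y.var(axis=0, ddof=1).mean())
    cov = float(np.cov(x, ybar, ddof=1)[0, 1])
    var_x = float(np.var(x, ddof=1))
    var_ybar = float(np.var(ybar, ddof=1))
    num = cov ** 2 - var_x * sigma2 / (n * (T - 1))
    den = var_x * (var_ybar - sigma2 / n)
    if den <= 0:
        return float("nan")
    return num / den


def fit_causal_filter(unit_trace: np.ndarray, target_trace: np.ndarray,
                      taps: int = 10):
    """Least-squares causal filter (``taps`` past/current frames) plus an
    offset, aligning one model unit trace to a recorded trace.

    The prediction at frame t uses only frames <= t (zero-padded start).
    Returns (prediction, weights, offset). Ill-conditioned designs fall back
    to a ridge-regularized solution (logged via warning).
    """
    u = np.asarray(unit_trace, dtype=float)
    y = np.asarray(target_trace, dtype=float)
    T = u.shape[0]
    if y.shape[0] != T:
        raise ValueError("traces must be aligned")
    X = np.zeros((T, taps))
    for k in range(taps):
        X[k:, k] = u[:T - k]
    A = np.column_stack([X, np.ones(T)])
    if np.linalg.cond(A) > 1e10:
        warnings.warn("ill-conditioned causal-filter design; using ridge",
                      stacklevel=2)
        lam = 1e-6 * np.trace(A.T @ A) / A.shape[1]
        coef = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    weights, offset = coef[:taps], float(coef[taps])
    return A @ coef, weights, offset


def all_unit_mapping(unit_traces: np.ndarray, target_trace: np.ndarray,
                     folds: int = 5, alphas=(0.01, 0.1, 1.0, 10.0, 100.0),
                     seed: int = 0) -> float:
    """Cross-validated ridge mapping from all model units to one recorded
    trace; pooled out-of-fold predictions scored by squared Pearson R^2."""
    from .probe import all_unit_parameter_r2

    return all_unit_parameter_r2(unit_traces, target_trace, circular=False,
                                 folds=folds, alphas=alphas, seed=seed)


def adaptation(raw_trace: np.ndarray, decay: float = 0.1,
               baseline: float | None = None) -> np.ndarray:
    """Exponential adaptation of a static-response trace.

    Wherever consecutive raw responses are exactly equal, the output decays
    toward ``baseline`` (default: the first raw value) with per-frame rate
    ``decay``; any change in the raw trace re-seeds the output to the raw
    value. ``decay = 0`` is the identity.
    """
    x = np.asarray(raw_trace, dtype=float)
    if baseline is None:
        baseline = float(x[0])
    out = x.copy()
    for t in range(1, x.size):
        if x[t] == x[t - 1]:
            out[t] = baseline + (out[t - 1] - baseline) * (1.0 - decay)
        else:
            out[t] = x[t]
    return out
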