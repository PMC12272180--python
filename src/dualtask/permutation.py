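"""Non-parametric permutation tests for paired time-series contrasts.

Implements the sign-flip (within-participant label exchange) permutation
scheme for paired condition contrasts, pointwise paired t statistics, the
run-length significance criterion (p < alpha over a minimum number of
consecutive samples) and the window-restricted 95th-percentile criterion
used for alpha-power time courses.

P-values are two-sided on |T| with add-one smoothing:
``p = (#{|T_null| >= |T_obs|} + 1) / (n_iter + 1)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "PermutationResult", "pointwise_paired_t", "permutation_null",
    "significant_runs", "permutation_test", "windowed_percentile_test",
]


@dataclass
class PermutationResult:
    """Pointwise statistics and significant runs for one contrast."""

    t_observed: np.ndarray
    p_values: np.ndarray
    significant_runs: list          # [(start_s, end_s), ...]
    n_iterations: int
    alpha: float
    min_run_samples: int
    time: np.ndarray | None = None
    null_distribution: np.ndarray | None = None


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    """Paired t over the first axis; zero-variance points become +-inf (or 0)."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        fallback = np.where(mean == 0, 0.0, np.sign(mean) * np.inf)
    return np.where(sd == 0, fallback, t)


def pointwise_paired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired t statistic at each time point; rows are participants."""
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError("conditions must share participants and time base")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    return _t_from_diffs(a - b)


def _null_t(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for every sign-flip row of ``signs`` (iters x n)."""
    n = d.shape[0]
    ss = (d ** 2).sum(axis=0)                 # invariant under sign flips
    means = signs @ d / n                     # iters x T
    var = (ss - n * means ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
        fallback = np.where(means == 0, 0.0, np.sign(means) * np.inf)
    return np.where(var <= 0, fallback, t)


def permutation_null(a: np.ndarray, b: np.ndarray, n_iter: int = 2000,
                     rng: np.random.Generator | None = None,
                     exact: bool = False, return_null: bool = False):
    """Sign-flip permutation null and pointwise two-sided p-values.

    Each iteration independently flips each participant's condition labels
    (equivalently the sign of the paired difference).  With ``exact=True``
    all ``2**n`` sign patterns are enumerated and p-values are exact
    proportions (no add-one smoothing).

    Returns ``(p_values, t_observed)`` or additionally the null matrix
    when ``return_null``.
    """
    if n_iter < 1 and not exact:
        raise ValueError("n_iter must be >= 1")
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError("conditions must share participants and time base")
    d = a - b
    n = d.shape[0]
    t_obs = _t_from_diffs(d)
    # count ties robustly: the identity flip reproduces t_obs up to
    # floating-point reduction order, so compare with a relative slack
    with np.errstate(invalid="ignore"):
        thresh = np.abs(t_obs) * (1.0 - 1e-12)
    if exact:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        null = _null_t(d, signs)
        p = (np.abs(null) >= thresh).mean(axis=0)
    else:
        rng = rng or np.random.default_rng()
        signs = rng.choice((1.0, -1.0), size=(n_iter, n))
        null = _null_t(d, signs)
        p = ((np.abs(null) >= thresh).sum(axis=0) + 1.0) / (n_iter + 1.0)
    if return_null:
        return p, t_obs, null
    return p, t_obs


def significant_runs(p_values: np.ndarray, alpha: float = 0.05,
                     min_run: int = 15, rate: float | None = None,
                     times: np.ndarray | None = None):
    """Maximal runs of consecutive p < alpha with length >= ``min_run``.

    Runs are reported as ``(start, end)`` in seconds when a sample rate or
    time vector is given (end is the time of the last sub-threshold
    sample), otherwise as sample indices.
    """
    p = np.asarray(p_values)
    below = p < alpha
    runs = []
    start = None
    for i, flag in enumerate(np.concatenate([below, [False]])):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if times is not None:
        return [(float(times[s]), float(times[e])) for s, e in runs]
    if rate is not None:
        return [(s / rate, e / rate) for s, e in runs]
    return runs


def permutation_test(a, b, n_iter: int = 2000, alpha: float = 0.05,
                     min_run: int = 15, rng=None,
                     times: np.ndarray | None = None,
                     rate: float | None = None,
                     keep_null: bool = False) -> PermutationResult:
    """Full paired permutation test with the run-length criterion."""
    p, t_obs, null = permutation_null(a, b, n_iter=n_iter, rng=rng,
                                      return_null=True)
    runs = significant_runs(p, alpha=alpha, min_run=min_run,
                            rate=rate, times=times)
    return PermutationResult(t_observed=t_obs, p_values=p,
                             significant_runs=runs, n_iterations=n_iter,
                             alpha=alpha, min_run_samples=min_run,
                             time=times,
                             null_distribution=null if keep_null else None)


def windowed_percentile_test(a, b, times: np.ndarray, window: tuple,
                             n_iter: int = 2000, alpha: float = 0.05,
                             rng=None):
    """Permutation test restricted to a half-open time window [start, end).

    A time point is significant when |T_obs| exceeds the (1 - alpha)
    quantile of its null |T| distribution (equivalently, the smoothed
    two-sided p-value falls below alpha).

    Returns ``(significant_mask, result)`` where the mask and result cover
    only the window samples.
    """
    times = np.asarray(times)
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError("empty analysis window")
    a = np.atleast_2d(np.asarray(a, float))[:, sel]
    b = np.atleast_2d(np.asarray(b, float))[:, sel]
    p, t_obs = permutation_null(a, b, n_iter=n_iter, rng=rng)
    sig = p < alpha
    result = PermutationResult(t_observed=t_obs, p_values=p,
                               significant_runs=significant_runs(
                                   p, alpha=alpha, min_run=1,
                                   times=times[sel]),
                               n_iterations=n_iter, alpha=alpha,
                               min_run_samples=1, time=times[sel])
    return sig, result
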