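"""Diversity estimation: inverse Simpson, Chao1, rarefaction.

These estimators are applied to two kinds of count vector: per-species
individual counts, and per-interaction-type event counts.  Two rarefaction
flavours are provided: the classical (hypergeometric, without-replacement)
expected-richness curve in closed form, and a bootstrap accumulation curve
that resamples WITH replacement from the relative abundances (expectation
sum_i (1 - (1 - p_i)^m) at sample size m).  The slope-at-half-richness
accumulation statistic defaults to the classical curve, which is exact and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import TritrophError

__all__ = [
    "inverse_simpson",
    "Chao1Estimate",
    "chao1",
    "RarefactionCurve",
    "rarefy",
    "expected_richness",
    "expected_richness_hypergeom",
    "slope_at_half_richness",
    "hypergeom_slope_at_half_richness",
]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                     dtype=float)
    if arr.size == 0:
        raise TritrophError("empty count vector")
    if np.any(arr <= 0) or np.any(arr != np.rint(arr)):
        raise TritrophError("counts must be positive integers")
    return arr


def inverse_simpson(counts) -> float:
    """Inverse Simpson diversity 1/D = 1 / sum(p_i^2).

    Equals 1 for a single type and the observed richness for perfectly even
    counts; lies in [1, S_obs] otherwise.
    """
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(1.0 / np.sum(p * p))


@dataclass(frozen=True)
class Chao1Estimate:
    estimate: float
    s_obs: int
    f1: int
    f2: int


def chao1(counts, bias_corrected: bool = True) -> Chao1Estimate:
    """Chao1 nonparametric richness estimate from singletons and doubletons.

    The default is the bias-corrected form
    S_obs + F1*(F1-1) / (2*(F2+1)), which is defined for all inputs; the
    classic form S_obs + F1^2/(2*F2) is available when F2 > 0 (it falls back
    to the bias-corrected form at F2 = 0).
    """
    arr = _as_counts(counts)
    s_obs = int(arr.size)
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if bias_corrected or f2 == 0:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        est = s_obs + f1 * f1 / (2.0 * f2)
    return Chao1Estimate(estimate=float(est), s_obs=s_obs, f1=f1, f2=f2)


@dataclass
class RarefactionCurve:
    """Mean bootstrap richness at each sample size 1..N."""

    x: np.ndarray
    y_mean: np.ndarray
    n_resamples: int

    def final(self) -> float:
        return float(self.y_mean[-1])


def rarefy(
    counts, n_resamples: int = 500, rng: np.random.Generator | None = None
) -> RarefactionCurve:
    """Bootstrap rarefaction curve: mean richness vs individuals sampled.

    Each resample draws N = sum(counts) individuals i.i.d. from the relative
    abundances; richness at size m is the number of distinct types among the
    first m draws, averaged over resamples.
    """
    if n_resamples < 1:
        raise TritrophError("n_resamples must be >= 1")
    arr = _as_counts(counts)
    rng = np.random.default_rng() if rng is None else rng
    n_total = int(arr.sum())
    s = arr.size
    p = arr / arr.sum()

    draws = rng.choice(s, size=(n_resamples, n_total), p=p)
    # first occurrence of each (resample, type) pair, vectorized over rows:
    keys = (np.arange(n_resamples)[:, None] * s + draws).ravel()
    _, first_idx = np.unique(keys, return_index=True)
    flags = np.zeros(n_resamples * n_total, dtype=np.int64)
    flags[first_idx] = 1
    curves = np.cumsum(flags.reshape(n_resamples, n_total), axis=1)
    return RarefactionCurve(
        x=np.arange(1, n_total + 1),
        y_mean=curves.mean(axis=0),
        n_resamples=n_resamples,
    )


def expected_richness(counts, m) -> np.ndarray | float:
    """Closed-form expectation of with-replacement rarefied richness.

    E[S(m)] = sum_i (1 - (1 - p_i)^m).
    """
    arr = _as_counts(counts)
    p = arr / arr.sum()
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    vals = np.sum(1.0 - (1.0 - p[None, :]) ** m_arr[:, None], axis=1)
    return vals if np.ndim(m) else float(vals[0])


def expected_richness_hypergeom(counts, m) -> np.ndarray | float:
    """Classical rarefaction: expected richness in a without-replacement
    subsample of m individuals.

    E[S(m)] = sum_i (1 - C(N - n_i, m) / C(N, m)).
    """
    arr = _as_counts(counts)
    n_total = arr.sum()
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    if np.any(m_arr < 0) or np.any(m_arr > n_total):
        raise TritrophError("sample size m must lie in [0, N]")
    # log C(N-n_i, m)/C(N, m); zero probability once m > N - n_i
    log_frac = (
        gammaln(n_total - arr[None, :] + 1)
        + gammaln(n_total - m_arr[:, None] + 1)
        - gammaln(np.maximum(n_total - arr[None, :] - m_arr[:, None] + 1, 1.0))
        - gammaln(n_total + 1)
    )
    frac = np.where(n_total - arr[None, :] - m_arr[:, None] < 0, 0.0,
                    np.exp(log_frac))
    vals = np.sum(1.0 - frac, axis=1)
    return vals if np.ndim(m) else float(vals[0])


def hypergeom_slope_at_half_richness(counts) -> float:
    """Slope of the classical rarefaction curve at half the observed richness.

    Deterministic: the smallest subsample size m with E[S(m)] >= S_obs/2 is
    found by bisection on the closed-form curve, and the slope is the
    centered finite difference over +-1 individual (one-sided at the curve
    ends).
    """
    arr = _as_counts(counts)
    s_obs = arr.size
    n_total = int(arr.sum())
    target = s_obs / 2.0
    lo, hi = 1, n_total
    while lo < hi:
        mid = (lo + hi) // 2
        if expected_richness_hypergeom(arr, mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    m = lo
    a, b = max(m - 1, 1), min(m + 1, n_total)
    if a == b:
        return float(expected_richness_hypergeom(arr, 1))
    ya, yb = expected_richness_hypergeom(arr, [a, b])
    return float((yb - ya) / (b - a))


def slope_at_half_richness(curve: RarefactionCurve, total_richness: int) -> float:
    """Finite-difference slope of the mean curve where it first reaches
    half the total richness.

    A steep slope (near 1) means the half-way point sits on the initial,
    nearly linear part of the accumulation curve; a shallow slope means
    richness was already saturating.  Centered difference over +-1 sample;
    one-sided at the curve ends.
    """
    target = total_richness / 2.0
    y = curve.y_mean
    reached = np.flatnonzero(y >= target)
    if reached.size == 0:
        raise TritrophError(
            f"curve never reaches half richness ({target}); max {y[-1]:.3f}"
        )
    i = int(reached[0])
    n = len(y)
    if n == 1:
        return float(y[0])  # single-sample curve: slope from the origin
    lo = max(i - 1, 0)
    hi = min(i + 1, n - 1)
    return float((y[hi] - y[lo]) / (hi - lo))
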