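"""Power-law tail fitting with a bootstrap Kolmogorov-Smirnov test.

Implements the standard maximum-likelihood / KS machinery for continuous
power-law tails p(x) ~ x^(-alpha) above a cutoff x_min:

* the continuous (Hill) MLE  alpha = 1 + n / sum ln(x_i / x_min),
* the KS distance between the tail empirical CDF and the fitted CDF
  F(x) = 1 - (x / x_min)^(1 - alpha),
* cutoff selection by minimising the KS distance of the refitted tail, and
* a semiparametric bootstrap goodness-of-fit p-value: synthetic datasets
  draw tail points from the fitted power law and sub-cutoff points from the
  empirical data, each replicate is refitted before its KS statistic, and p
  is the fraction of replicates whose KS meets or exceeds the observed one.

MI values are continuous, so the continuous formulas are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InsufficientDataError

__all__ = ["TailFit", "fit_alpha", "ks_statistic", "gof_pvalue",
           "select_xmin", "fit_tail"]


@dataclass
class TailFit:
    """Result of a power-law tail fit."""

    alpha_hat: float
    x_min: float
    n_tail: int
    ks_stat: float
    p_value: float | None
    n_boot: int
    seed: int | None


def _tail(values, x_min) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if not (x_min > 0):
        raise ValueError("x_min must be positive")
    if np.any(v <= 0):
        raise ValueError("values must be positive for a power-law tail fit")
    t = v[v >= x_min]
    if t.size < 2:
        raise InsufficientDataError("need at least 2 tail values >= x_min")
    return t


def fit_alpha(values, x_min: float) -> float:
    """Continuous maximum-likelihood exponent over values >= x_min."""
    t = _tail(values, x_min)
    logsum = float(np.sum(np.log(t / x_min)))
    if logsum <= 0:
        raise DegenerateInputError("all tail values equal x_min; exponent undefined")
    return 1.0 + t.size / logsum


def ks_statistic(values, x_min: float, alpha: float) -> float:
    """Sup-distance between the tail empirical CDF and the fitted power-law CDF."""
    t = np.sort(_tail(values, x_min))
    n = t.size
    F = 1.0 - (t / x_min) ** (1.0 - alpha)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(hi - F)), np.max(np.abs(F - lo))))


def _powerlaw_draw(rng, size, x_min, alpha):
    # inverse-CDF sampling of the continuous power law above x_min
    return x_min * (1.0 - rng.random(size)) ** (-1.0 / (alpha - 1.0))


def gof_pvalue(values, x_min: float, n_boot: int = 500, seed: int = 0) -> float:
    """Semiparametric bootstrap KS goodness-of-fit p-value.

    Each of the ``n_boot`` synthetic datasets has the same size as the data;
    every point is, with probability n_tail / n, a draw from the fitted
    power law above x_min, and otherwise a uniform resample of the observed
    sub-cutoff values.  Each replicate is refitted (exponent re-estimated at
    the same cutoff) before computing its KS statistic.  Deterministic for a
    given seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    v = np.asarray(values, dtype=float).ravel()
    tail = _tail(v, x_min)
    below = v[v < x_min]
    alpha_obs = fit_alpha(v, x_min)
    ks_obs = ks_statistic(v, x_min, alpha_obs)
    p_tail = tail.size / v.size

    rng = np.random.default_rng(seed)
    n = v.size
    hits = 0
    for _ in range(n_boot):
        for _retry in range(100):
            take_tail = rng.random(n) < p_tail if below.size else np.ones(n, bool)
            n_t = int(take_tail.sum())
            if n_t >= 2:
                break
        synth = np.empty(n)
        synth[take_tail] = _powerlaw_draw(rng, n_t, x_min, alpha_obs)
        if n - n_t:
            synth[~take_tail] = rng.choice(below, size=n - n_t, replace=True)
        alpha_b = fit_alpha(synth, x_min)
        if ks_statistic(synth, x_min, alpha_b) >= ks_obs:
            hits += 1
    return hits / n_boot


def select_xmin(values, min_tail: int = 10) -> float:
    """Choose the cutoff minimising the KS distance of the refitted tail.

    Candidates are the distinct observed values whose tail (values >= the
    candidate) keeps at least ``min_tail`` points; for each, the exponent is
    refitted and the KS distance computed, and the candidate with minimal
    KS wins (ties: the smallest cutoff).
    """
    v = np.asarray(values, dtype=float).ravel()
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    distinct = np.unique(v)
    if distinct.size < 10:
        raise InsufficientDataError("need at least 10 distinct values to select x_min")
    best_xmin, best_ks = None, np.inf
    for cand in distinct:
        tail = v[v >= cand]
        if tail.size < max(min_tail, 2):
            break  # distinct is ascending: tails only shrink from here
        logsum = float(np.sum(np.log(tail / cand)))
        if logsum <= 0:
            continue
        alpha = 1.0 + tail.size / logsum
        ks = ks_statistic(tail, cand, alpha)
        if ks < best_ks:
            best_ks, best_xmin = ks, float(cand)
    if best_xmin is None:
        raise InsufficientDataError("no admissible x_min candidate")
    return best_xmin


def fit_tail(values, x_min: float | None = None, n_boot: int = 500,
             seed: int = 0, min_tail: int = 10) -> TailFit:
    """Full tail analysis: cutoff (optional), exponent, KS, bootstrap p-value.

    Set ``n_boot=0`` to skip the bootstrap (p_value = None).
    """
    v = np.asarray(values, dtype=float).ravel()
    if x_min is None:
        x_min = select_xmin(v, min_tail=min_tail)
    alpha = fit_alpha(v, x_min)
    ks = ks_statistic(v, x_min, alpha)
    p = gof_pvalue(v, x_min, n_boot=n_boot, seed=seed) if n_boot else None
    return TailFit(alpha_hat=alpha, x_min=float(x_min),
                   n_tail=int(np.sum(v >= x_min)), ks_stat=ks,
                   p_value=p, n_boot=n_boot, seed=seed)
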