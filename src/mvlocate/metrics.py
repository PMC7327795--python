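"""Localization and parameter-recovery metrics.

The simulation studies in this package report, per detection-count stratum:

* RMSE -- root mean squared Euclidean distance between each posterior-mean
  location and the truth;
* precision -- mean Euclidean distance of *posterior draws* to the truth
  (a property of the whole posterior cloud, not just its centre; smaller is
  better);
* coverage -- the fraction of signals whose true location falls inside the
  95% highest-density region of a 2-D kernel density estimate built from
  that signal's posterior draws;

plus relative frequentist bias of the scalar parameters across replicate
datasets, using posterior means as point estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "relative_bias",
    "localization_rmse",
    "posterior_precision",
    "hpd_covered",
    "hpd_coverage",
    "stratify_by_detection_count",
]


def relative_bias(estimates, truth: float) -> float:
    """(mean(estimates) - truth) / truth."""
    if truth == 0:
        raise ValueError("relative bias is undefined for truth == 0")
    est = np.asarray(estimates, dtype=float)
    return float((est.mean() - truth) / truth)


def localization_rmse(posterior_means, true_locations) -> float:
    """Root mean squared Euclidean distance of posterior means to truths."""
    pm = np.asarray(posterior_means, dtype=float)
    tr = np.asarray(true_locations, dtype=float)
    if pm.shape != tr.shape:
        raise ValueError(f"shape mismatch: {pm.shape} vs {tr.shape}")
    d2 = np.sum((pm - tr) ** 2, axis=-1)
    return float(np.sqrt(d2.mean()))


def posterior_precision(location_draws, true_location) -> float:
    """Mean Euclidean distance of posterior draws to the true location."""
    draws = np.asarray(location_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one posterior draw")
    d = np.sqrt(np.sum((draws - np.asarray(true_location, float)) ** 2, axis=-1))
    return float(d.mean())


def hpd_covered(location_draws, true_location, level: float = 0.95,
                max_draws: int = 1000, rng=None) -> bool:
    """Is the truth inside the ``level`` highest-density region of a 2-D
    Gaussian kernel density built on the draws?

    The region is defined implicitly: the truth is covered iff its estimated
    density is at least the empirical (1 - level) quantile of the density
    evaluated at the draws themselves.  Degenerate (zero-variance) draws fall
    back to an exact-match rule with a warning.
    """
    draws = np.asarray(location_draws, dtype=float).reshape(-1, 2)
    truth = np.asarray(true_location, dtype=float)
    if draws.shape[0] > max_draws:
        rng = np.random.default_rng(0) if rng is None else rng
        draws = draws[rng.choice(draws.shape[0], max_draws, replace=False)]
    if np.allclose(draws.var(axis=0), 0.0):
        warnings.warn("degenerate (zero-variance) draws; exact-match coverage rule")
        return bool(np.allclose(draws[0], truth))
    try:
        kde = gaussian_kde(draws.T)
    except np.linalg.LinAlgError:
        warnings.warn("singular draw covariance; exact-match coverage rule")
        return bool(np.allclose(draws.mean(axis=0), truth))
    f_truth = float(kde(truth[:, None])[0])
    f_draws = kde(draws.T)
    thr = float(np.quantile(f_draws, 1.0 - level))
    return f_truth >= thr


def hpd_coverage(location_draws_per_signal, truths, level: float = 0.95,
                 max_draws: int = 1000) -> float:
    """Fraction of signals whose truth lies in its ``level`` HPD region."""
    truths = np.asarray(truths, dtype=float)
    if len(location_draws_per_signal) != truths.shape[0]:
        raise ValueError("draw sets and truths length mismatch")
    if truths.shape[0] == 0:
        raise ValueError("no signals supplied")
    hits = [
        hpd_covered(d, t, level=level, max_draws=max_draws)
        for d, t in zip(location_draws_per_signal, truths)
    ]
    return float(np.mean(hits))


def stratify_by_detection_count(encounters, max_stratum: int = 6) -> np.ndarray:
    """Per-signal count of detecting receivers; counts above ``max_stratum``
    are returned as -1 (excluded from tabulation due to rarity)."""
    Y = np.asarray(encounters)
    counts = Y.sum(axis=-1).astype(int)
    counts[counts > max_stratum] = -1
    return counts
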