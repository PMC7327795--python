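"""Shared Metropolis-within-Gibbs machinery for the localization samplers.

All samplers in this package are plain random-walk Metropolis-within-Gibbs:
latent locations are updated site-wise (vectorised over conditionally
independent sites), scalar parameters by Gaussian random walks with uniform
priors handled by rejection at the support boundary.  Proposal scales are
adapted in batches during burn-in toward a target acceptance rate and frozen
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class MCMCSettings:
    """Chain settings. ``adapt_iters=None`` adapts throughout burn-in."""

    n_chains: int = 3
    n_iter: int = 4000
    n_burn: int = 1500
    thin: int = 2
    seed: int = 0
    adapt_iters: int | None = None

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("require n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_adapt(self) -> int:
        return self.n_burn if self.adapt_iters is None else self.adapt_iters

    @property
    def n_kept(self) -> int:
        return int(np.ceil((self.n_iter - self.n_burn) / self.thin))


@dataclass(frozen=True)
class TagData:
    """Observed data of one tag handed to a fitter: signal/detection times
    and the matching binary encounter matrix (signals x receivers)."""

    tag_id: int
    times: np.ndarray  # (T,)
    Y: np.ndarray  # (T, J) binary

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        Y = np.asarray(self.Y)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "Y", Y)
        if t.ndim != 1 or Y.ndim != 2 or Y.shape[0] != t.size:
            raise ValueError("times and encounter matrix shapes disagree")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all((Y == 0) | (Y == 1)):
            raise ValueError("encounter matrix must be binary")


def halfnormal_p(d2: np.ndarray, p0: float, sigma_det: float) -> np.ndarray:
    """Clipped half-normal detection probability from squared distances."""
    p = p0 * np.exp(-d2 / (2.0 * sigma_det * sigma_det))
    return np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)


class EncModel:
    """Fast per-signal encounter log-likelihood evaluator.

    Squared distances go through BLAS (``u @ X.T``); the all-zero baseline
    ``sum_j log(1-p_j)`` is computed densely and the few detected entries are
    corrected through a padded index table, avoiding a dense ``Y`` multiply.
    Detected entries use ``log p = log p0 - d^2/(2 sigma^2)`` directly, so no
    clipping is needed while ``p0 < 1``.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.X2 = (self.X**2).sum(axis=1)
        Y = np.asarray(Y)
        N = Y.shape[0]
        counts = Y.sum(axis=1).astype(int)
        maxdet = int(counts.max()) if N else 0
        self.cols = np.zeros((N, max(maxdet, 1)), dtype=int)
        self.mask = np.zeros((N, max(maxdet, 1)), dtype=bool)
        k = np.zeros(N, dtype=int)
        for r, c in zip(*np.nonzero(Y)):
            self.cols[r, k[r]] = c
            self.mask[r, k[r]] = True
            k[r] += 1

    @classmethod
    def from_sparse(cls, X, n_rows: int, det_rows, det_cols, det_mask) -> "EncModel":
        """Build without a dense Y: ``det_rows`` are the row positions whose
        padded detected-column table is (det_cols, det_mask); all other rows
        are all-zero."""
        self = cls.__new__(cls)
        self.X = np.asarray(X, dtype=float)
        self.X2 = (self.X**2).sum(axis=1)
        w = max(det_cols.shape[1], 1) if det_cols.size else 1
        self.cols = np.zeros((n_rows, w), dtype=int)
        self.mask = np.zeros((n_rows, w), dtype=bool)
        if det_cols.size:
            self.cols[det_rows] = det_cols
            self.mask[det_rows] = det_mask
        return self

    def _d2(self, u: np.ndarray) -> np.ndarray:
        d2 = (u**2).sum(axis=1)[:, None] + self.X2[None, :] - 2.0 * (u @ self.X.T)
        np.maximum(d2, 0.0, out=d2)
        return d2

    def rows(self, u: np.ndarray, p0: float, sigma_det: float, subset=None) -> np.ndarray:
        d2 = self._d2(u)
        c = 1.0 / (2.0 * sigma_det * sigma_det)
        p = p0 * np.exp(-d2 * c)
        base = np.log1p(-p).sum(axis=1)
        cols = self.cols if subset is None else self.cols[subset]
        mask = self.mask if subset is None else self.mask[subset]
        g = np.take_along_axis(d2, cols, axis=1)
        pg = np.take_along_axis(p, cols, axis=1)
        adj = ((np.log(p0) - g * c) - np.log1p(-pg)) * mask
        return base + adj.sum(axis=1)

    def allzero(self, u: np.ndarray, p0: float, sigma_det: float) -> np.ndarray:
        d2 = self._d2(u)
        p = p0 * np.exp(-d2 / (2.0 * sigma_det * sigma_det))
        return np.log1p(-p).sum(axis=1)


def enc_rows(u: np.ndarray, Y: np.ndarray, X: np.ndarray, p0: float, sigma_det: float) -> np.ndarray:
    """Per-signal encounter log-likelihood rows for locations ``u`` (n,2)
    against dense binary ``Y`` (n,J) and receiver coords ``X`` (J,2)."""
    d2 = ((u[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    p = halfnormal_p(d2, p0, sigma_det)
    return (Y * np.log(p) + (1.0 - Y) * np.log1p(-p)).sum(axis=1)


def allzero_rows(u: np.ndarray, X: np.ndarray, p0: float, sigma_det: float) -> np.ndarray:
    """Encounter log-likelihood of the all-zero history at locations ``u``."""
    d2 = ((u[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    p = halfnormal_p(d2, p0, sigma_det)
    return np.log1p(-p).sum(axis=1)


class ScaleAdapter:
    """Batch adaptation of random-walk scales toward a target acceptance
    rate; multiplicative steps, frozen once ``adapting`` is set False."""

    def __init__(self, scales, batch: int = 50, target_lo: float = 0.25,
                 target_hi: float = 0.45, step: float = 0.12):
        self.scales = np.atleast_1d(np.asarray(scales, dtype=float)).copy()
        self.accepts = np.zeros_like(self.scales)
        self.trials = np.zeros_like(self.scales)
        self.batch = batch
        self.lo, self.hi, self.step = target_lo, target_hi, step
        self.adapting = True

    def record(self, accepted, idx=None) -> None:
        if idx is None:
            self.accepts += accepted
            self.trials += 1
        else:
            np.add.at(self.accepts, idx, accepted)
            np.add.at(self.trials, idx, 1)

    def maybe_adapt(self, it: int) -> None:
        if not self.adapting or (it + 1) % self.batch:
            return
        with np.errstate(invalid="ignore"):
            rate = np.where(self.trials > 0, self.accepts / np.maximum(self.trials, 1), np.nan)
        up = rate > self.hi
        dn = rate < self.lo
        self.scales[up] *= np.exp(self.step)
        self.scales[dn] *= np.exp(-self.step)
        np.clip(self.scales, 1e-5, 1e3, out=self.scales)
        self.accepts[:] = 0
        self.trials[:] = 0

    @property
    def rate(self) -> np.ndarray:
        return self.accepts / np.maximum(self.trials, 1)


def rhat(draws_by_chain: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter,
    draws_by_chain shaped (chains, draws)."""
    import arviz as az

    return float(az.rhat(np.asarray(draws_by_chain)))
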