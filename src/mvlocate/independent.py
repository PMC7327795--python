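"""Independent per-signal localization: the baseline comparator.

Each detected occasion is localized on its own by Bayes' rule with a uniform
prior over the state space; detection parameters (p0, sigma_det) are
estimated jointly from the same detected occasions.  Occasions with zero
detections are discarded, which is exactly what makes this baseline biased:
dropping all-zero encounter histories over-represents locations with high
detection probability and inflates the estimate of p0.  No conditioning
correction is applied -- the estimator is reproduced as used in practice,
including that bias.

Observed zeros at non-detecting receivers ARE part of each encounter vector
(the SCR convention); only fully empty occasions are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._mh import EncModel, MCMCSettings, ScaleAdapter, rhat
from .kernels import DetectionParams, ReceiverArray, StateSpace, detection_prob

__all__ = ["IndependentFit", "independent_loglik", "fit_independent"]


def independent_loglik(
    params: DetectionParams,
    encounters: np.ndarray,
    array: ReceiverArray,
    space: StateSpace,
    grid_n: int = 200,
) -> float:
    """Marginal log-likelihood of detected occasions under the independent
    model: sum over occasions of log of the uniform-prior integral of the
    encounter likelihood over the state space (fixed quadrature grid).

    No >=1-detection conditioning is applied (see module docstring).
    """
    Y = np.asarray(encounters, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != array.n_receivers:
        raise ValueError("encounters must be (T, n_receivers)")
    if Y.shape[0] == 0:
        raise ValueError("need at least one detected occasion")
    if np.any(Y.sum(axis=1) == 0):
        raise ValueError("independent model uses detected occasions only")
    pts, cell = space.grid(grid_n)
    d = np.sqrt(((pts[:, None, :] - array.coords[None, :, :]) ** 2).sum(-1))
    p = np.clip(detection_prob(d, params), 1e-12, 1 - 1e-12)
    logp, log1mp = np.log(p), np.log1p(-p)
    base = log1mp.sum(axis=1)  # all-zero loglik per grid point
    total = 0.0
    for y in Y:
        det = y > 0
        ll = base + (logp[:, det] - log1mp[:, det]).sum(axis=1)
        m = ll.max()
        total += m + np.log(np.exp(ll - m).sum() * cell / space.area)
    return float(total)


@dataclass(frozen=True)
class IndependentFit:
    """Posterior draws of (p0, sigma_det) and per-occasion localizations."""

    params: dict  # name -> (chains, kept)
    u_draws: np.ndarray  # (chains*kept, T, 2)
    Y: np.ndarray
    diagnostics: dict

    def param_draws(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.param_draws(name).mean())

    def posterior_mean_locations(self) -> np.ndarray:
        return self.u_draws.mean(axis=0)


def _run_chain(Y, em, X, space, settings, sd_max, seed, spacing_guess,
               fix_params=None):
    rng = np.random.default_rng(seed)
    T = Y.shape[0]
    counts = Y.sum(axis=1)
    u = (Y @ X) / counts[:, None] + rng.normal(0, 0.05, size=(T, 2))
    u[:, 0] = np.clip(u[:, 0], space.xmin, space.xmax)
    u[:, 1] = np.clip(u[:, 1], space.ymin, space.ymax)
    if fix_params is None:
        p0 = float(np.clip(0.5 + rng.normal(0, 0.05), 0.05, 0.95))
        sd = spacing_guess * 0.5 * np.exp(rng.normal(0, 0.1))
    else:
        p0, sd = fix_params
    enc = em.rows(u, p0, sd)
    u_adapt = ScaleAdapter(np.full(T, 0.4))
    p_adapt = ScaleAdapter([0.04, 0.06])  # joint (p0, sigma_det)
    kept = settings.n_kept
    out_p = np.empty((kept, 2))
    out_u = np.empty((kept, T, 2))
    k = 0
    for it in range(settings.n_iter):
        # all occasions are conditionally independent: one vectorised update
        prop = u + rng.standard_normal((T, 2)) * u_adapt.scales[:, None]
        enc_prop = em.rows(prop, p0, sd)
        logr = enc_prop - enc
        logr[~space.contains(prop)] = -np.inf  # uniform prior support
        acc = np.log(rng.uniform(size=T)) < logr
        u[acc] = prop[acc]
        enc[acc] = enc_prop[acc]
        u_adapt.record(acc.astype(float), np.arange(T))

        if fix_params is None:
            p0_prop = p0 + rng.normal(0, p_adapt.scales[0])
            sd_prop = sd + rng.normal(0, p_adapt.scales[1])
            acc_p = False
            if 0.0 < p0_prop < 1.0 and 0.0 < sd_prop < sd_max:
                enc_prop = em.rows(u, p0_prop, sd_prop)
                if np.log(rng.uniform()) < enc_prop.sum() - enc.sum():
                    enc, p0, sd = enc_prop, p0_prop, sd_prop
                    acc_p = True
            p_adapt.record(np.array([float(acc_p), float(acc_p)]), np.array([0, 1]))

        if it < settings.n_adapt:
            u_adapt.maybe_adapt(it)
            p_adapt.maybe_adapt(it)
        elif u_adapt.adapting:
            u_adapt.adapting = p_adapt.adapting = False

        if it >= settings.n_burn and (it - settings.n_burn) % settings.thin == 0:
            out_p[k] = (p0, sd)
            out_u[k] = u
            k += 1
    return out_p[:k], out_u[:k]


def fit_independent(
    encounters,
    array: ReceiverArray,
    space: StateSpace,
    settings: MCMCSettings = MCMCSettings(),
    prior_sigma_det_max: float | None = None,
    fix_params: tuple | None = None,
) -> IndependentFit:
    """Metropolis-within-Gibbs over (p0, sigma_det) and one latent location
    per detected occasion, uniform location prior over ``space``.

    ``encounters`` is the pooled (T, J) binary matrix of detected occasions
    (rows from any number of tags; occasions are exchangeable here).  Pass
    ``fix_params=(p0, sigma_det)`` to localize with known detection
    parameters (used by oracle checks).
    """
    Y = np.asarray(encounters, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != array.n_receivers:
        raise ValueError("encounters must be (T, n_receivers)")
    if Y.shape[0] == 0 or np.any(Y.sum(axis=1) == 0):
        raise ValueError("independent model needs detected occasions only (>=1 detection each)")
    sd_max = prior_sigma_det_max if prior_sigma_det_max is not None else 0.5 * space.diagonal
    from scipy.spatial import cKDTree

    nn = cKDTree(array.coords).query(array.coords, k=min(2, array.n_receivers))[0]
    spacing_guess = float(np.median(nn[:, -1])) if array.n_receivers > 1 else 1.0

    em = EncModel(array.coords, Y)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    pdraws, udraws = [], []
    for ss in seeds:
        p, uu = _run_chain(Y, em, array.coords, space, settings, sd_max, ss,
                           spacing_guess, fix_params=fix_params)
        pdraws.append(p)
        udraws.append(uu)
    P = np.stack(pdraws)
    params = {"p0": P[:, :, 0], "sigma_det": P[:, :, 1]}
    diag = {}
    if fix_params is None and settings.n_chains > 1 and P.shape[1] > 3:
        diag["rhat"] = {k: rhat(v) for k, v in params.items()}
    return IndependentFit(
        params=params,
        u_draws=np.concatenate(udraws, axis=0),
        Y=Y.astype(np.uint8),
        diagnostics=diag,
    )
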