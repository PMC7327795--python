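"""Movement-assisted localization: detection-only and known-interval fits.

Both variants run a joint Metropolis-within-Gibbs sampler over the latent
trajectories of all tags and the shared parameters (p0, sigma_det, sigma_u):

* ``detection_only`` uses only occasions with at least one detection and
  links consecutive detected occasions with the observed elapsed time, so
  missed signals are silently absorbed into longer movement intervals;
* ``known_interval`` assumes the full signal schedule is known, including
  occasions with zero detections, whose all-zero encounter histories then
  contribute to the likelihood.  Leading/trailing stretches beyond the first
  and last detection are trimmed to a fixed buffer (default five signals) to
  avoid estimating an unbounded number of unconstrained locations.

Within a sweep every location is updated by random-walk Metropolis against
its full conditional (encounter likelihood times the movement kernels to its
neighbours), alternating over odd/even sites so each half-sweep is fully
vectorised; then sigma_u, sigma_det and p0 are updated by random-walk
Metropolis against the pooled joint likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._mh import EncModel, MCMCSettings, ScaleAdapter, TagData, rhat
from .kernels import (
    DetectionParams,
    MovementParams,
    ReceiverArray,
    StateSpace,
    encounter_loglik,
    movement_logdensity,
)

__all__ = [
    "MCMCSettings",
    "TagData",
    "MovementFit",
    "detected_only_data",
    "known_interval_data",
    "location_full_conditional_logdensity",
    "fit_movement",
]

_VARIANTS = ("detection_only", "known_interval")


def detected_only_data(tag) -> TagData | None:
    """Detected occasions of a simulated tag; None if fewer than two (no
    movement information)."""
    counts = tag.encounters.sum(axis=1)
    keep = counts > 0
    if keep.sum() < 2:
        return None
    return TagData(tag_id=tag.tag_id, times=tag.schedule.times[keep], Y=tag.encounters[keep])


def known_interval_data(tag, buffer: int = 5) -> TagData | None:
    """Full known schedule of a simulated tag, trimmed to ``buffer`` signals
    before the first and after the last detection; None if never detected."""
    counts = tag.encounters.sum(axis=1)
    det = np.flatnonzero(counts > 0)
    if det.size == 0:
        return None
    lo = max(0, det[0] - buffer)
    hi = min(len(counts) - 1, det[-1] + buffer)
    sl = slice(lo, hi + 1)
    return TagData(tag_id=tag.tag_id, times=tag.schedule.times[sl], Y=tag.encounters[sl])


def location_full_conditional_logdensity(
    u_t,
    y_t,
    u_prev,
    u_next,
    delta_prev,
    delta_next,
    array: ReceiverArray,
    det: DetectionParams,
    move: MovementParams,
) -> float:
    """Unnormalised log full-conditional of one location: encounter term plus
    movement kernels to whichever neighbours exist (pass None at trajectory
    ends)."""
    ll = encounter_loglik(y_t, u_t, array, det)
    if u_prev is not None:
        ll += movement_logdensity(u_t, u_prev, move, delta_prev)
    if u_next is not None:
        ll += movement_logdensity(u_next, u_t, move, delta_next)
    return float(ll)


@dataclass(frozen=True)
class MovementFit:
    """Pooled posterior draws from a movement-assisted fit.

    ``params`` maps name -> (chains, kept) arrays; ``u_draws`` stacks all
    chains, shape (chains*kept, N, 2) over the flattened signals of all tags.
    """

    variant: str
    params: dict
    u_draws: np.ndarray
    tag_ids: tuple
    tag_slices: tuple  # per tag (start, stop) into the flat signal axis
    times: np.ndarray
    Y: np.ndarray
    diagnostics: dict

    def param_draws(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.param_draws(name).mean())

    def posterior_mean_locations(self) -> np.ndarray:
        return self.u_draws.mean(axis=0)

    def tag_u_draws(self, tag_id) -> np.ndarray:
        i = self.tag_ids.index(tag_id)
        s = self.tag_slices[i]
        return self.u_draws[:, s[0]: s[1], :]


class _FlatTags:
    """Per-tag sequences concatenated into flat arrays with neighbour masks."""

    def __init__(self, tags: list[TagData], n_receivers: int):
        self.tag_ids = tuple(t.tag_id for t in tags)
        times = [np.asarray(t.times, float) for t in tags]
        self.times = np.concatenate(times)
        self.Y = np.concatenate([np.asarray(t.Y, dtype=float) for t in tags])
        self.N = self.times.size
        lens = [len(t) for t in times]
        stops = np.cumsum(lens)
        starts = stops - np.array(lens)
        self.tag_slices = tuple((int(a), int(b)) for a, b in zip(starts, stops))
        self.tag_first = np.zeros(self.N, dtype=bool)
        self.tag_first[starts] = True
        # delta[i] is the elapsed time of segment (i-1, i); invalid at firsts
        self.delta = np.empty(self.N)
        self.delta[0] = np.nan
        self.delta[1:] = np.diff(self.times)
        self.delta[self.tag_first] = np.nan
        self.has_prev = ~self.tag_first
        self.has_next = np.zeros(self.N, dtype=bool)
        self.has_next[:-1] = ~self.tag_first[1:]


class _ZeroRuns:
    """Maximal runs of consecutive zero-detection signals within each tag,
    with padded duration tables for whole-run Brownian-bridge regeneration.

    Single-site updates relax the large-scale modes of a long imputed
    stretch in O(length^2) sweeps; regenerating the whole run from the
    movement bridge between its detected anchors (an independence proposal
    whose bridge density cancels, leaving only the all-zero encounter terms
    in the Metropolis ratio) makes those modes mix in O(1).
    """

    def __init__(self, flat: "_FlatTags"):
        zero = flat.Y.sum(axis=1) == 0
        runs = []
        for (a, b) in flat.tag_slices:
            i = a
            while i < b:
                if not zero[i]:
                    i += 1
                    continue
                j = i
                while j < b and zero[j]:
                    j += 1
                left = i - 1 if i > a else -1
                right = j if j < b else -1
                runs.append((np.arange(i, j), left, right))
                i = j
        self.any = bool(runs)
        if not self.any:
            return
        kinds = {"interior": [], "leading": [], "trailing": []}
        for pos, left, right in runs:
            if left >= 0 and right >= 0:
                kinds["interior"].append((pos, left, right))
            elif right >= 0:
                kinds["leading"].append((pos, left, right))
            else:
                kinds["trailing"].append((pos, left, right))
        self.groups = {}
        for kind, rs in kinds.items():
            if not rs:
                continue
            L = np.array([len(p) for p, _, _ in rs])
            Lmax = int(L.max())
            pos = np.full((len(rs), Lmax), -1, dtype=int)
            # durations of the len+1 transitions (anchor->z_0, ..., z_last->anchor)
            dur = np.full((len(rs), Lmax + 1), np.nan)
            anchors = np.full((len(rs), 2), -1, dtype=int)
            for r, (p, left, right) in enumerate(rs):
                pos[r, : len(p)] = p
                dur[r, : len(p)] = flat.delta[p]
                if right >= 0:
                    dur[r, len(p)] = flat.delta[right]
                anchors[r] = (left, right)
            grp = {"len": L, "pos": pos, "dur": dur, "anchors": anchors}
            if kind == "interior":
                # suffix sums of the remaining bridge time at each step
                suf = np.where(np.isnan(dur), 0.0, dur)[:, ::-1].cumsum(axis=1)[:, ::-1]
                grp["suffix"] = suf
            self.groups[kind] = grp

    def propose(self, u: np.ndarray, su: float, rng: np.random.Generator) -> dict:
        """Draw a full bridge/extension proposal for every run; returns per
        group an array aligned with ``pos``."""
        out = {}
        for kind, g in self.groups.items():
            R, Lmax = g["pos"].shape
            prop = np.zeros((R, Lmax, 2))
            if kind in ("interior", "trailing"):
                left = g["anchors"][:, 0]
                z = u[left].copy()
                if kind == "interior":
                    uR = u[g["anchors"][:, 1]]
                for m in range(Lmax):
                    act = g["len"] > m
                    d = g["dur"][act, m]
                    if kind == "interior":
                        T = g["suffix"][act, m]
                        w = d / T
                        mean = z[act] + w[:, None] * (uR[act] - z[act])
                        var = su * su * d * (T - d) / T
                    else:
                        mean = z[act]
                        var = su * su * d
                    znew = mean + np.sqrt(var)[:, None] * rng.standard_normal((act.sum(), 2))
                    prop[act, m] = znew
                    z[act] = znew
            else:  # leading: backward extension from the right anchor
                uR = u[g["anchors"][:, 1]]
                z = uR.copy()
                for back in range(Lmax):
                    m = g["len"] - 1 - back  # per-run position index
                    act = m >= 0
                    d = g["dur"][act, m[act] + 1]
                    znew = z[act] + np.sqrt(su * su * d)[:, None] * rng.standard_normal((act.sum(), 2))
                    prop[act, m[act]] = znew
                    z[act] = znew
            out[kind] = prop
        return out


def _init_locations(flat: _FlatTags, X: np.ndarray) -> np.ndarray:
    """Detected signals start at the mean detecting receiver; zero-detection
    signals by linear interpolation between nearest detected neighbours."""
    counts = flat.Y.sum(axis=1)
    u = np.zeros((flat.N, 2))
    det = counts > 0
    u[det] = (flat.Y[det] @ X) / counts[det, None]
    for (a, b) in flat.tag_slices:
        idx = np.arange(a, b)
        dloc = idx[det[a:b]]
        if dloc.size == 0:
            center = X.mean(axis=0)
            u[a:b] = center
            continue
        for ax in (0, 1):
            u[a:b, ax] = np.interp(idx, dloc, u[dloc, ax])
    return u


def _run_movement_chain(flat, em, X, space, settings, su_max, sd_max, seed,
                        spacing_guess, fix_params=None, zero_runs=None):
    rng = np.random.default_rng(seed)
    N = flat.N
    n_iter = settings.n_iter
    u = _init_locations(flat, X) + rng.normal(0, 0.05, size=(N, 2))
    # clamp tag-first sites inside the state space (uniform prior support)
    u[:, 0] = np.clip(u[:, 0], space.xmin, space.xmax)
    u[:, 1] = np.clip(u[:, 1], space.ymin, space.ymax)

    seg = flat.has_prev
    if fix_params is not None:
        p0, sd, su = map(float, fix_params)
    else:
        p0 = float(np.clip(0.5 + rng.normal(0, 0.05), 0.05, 0.95))
        sd = spacing_guess * 0.5 * np.exp(rng.normal(0, 0.1))
        r2 = np.sum((u[1:] - u[:-1]) ** 2, axis=1)
        r2_over_d = np.zeros(N)
        r2_over_d[1:] = r2 / np.where(np.isnan(flat.delta[1:]), 1.0, flat.delta[1:])
        su = float(np.sqrt(max(np.mean(r2_over_d[seg]) / 2.0, 1e-4))) * np.exp(rng.normal(0, 0.1))
        su = min(su, 0.5 * su_max)

    enc = em.rows(u, p0, sd)
    parity_idx = (np.flatnonzero(np.arange(N) % 2 == 0), np.flatnonzero(np.arange(N) % 2 == 1))
    u_adapt = ScaleAdapter(np.full(N, 0.3))
    p_adapt = ScaleAdapter([0.04, 0.06, 0.04])  # (p0, sigma_det) joint, sigma_u

    kept = settings.n_kept
    out_p = np.empty((kept, 3))
    out_u = np.empty((kept, N, 2))
    k = 0

    prev_idx = np.arange(N) - 1
    next_idx = np.arange(N) + 1

    def move_r2_terms(uv, idx):
        """Sum of squared-residual/delta movement terms for sites idx with
        site values uv (m,2), neighbours taken from the current state."""
        out = np.zeros(len(idx))
        mp = flat.has_prev[idx]
        if mp.any():
            i = idx[mp]
            out[mp] += np.sum((uv[mp] - u[prev_idx[i]]) ** 2, axis=1) / flat.delta[i]
        mn = flat.has_next[idx]
        if mn.any():
            i = idx[mn]
            out[mn] += np.sum((u[next_idx[i]] - uv[mn]) ** 2, axis=1) / flat.delta[i + 1]
        return out

    for it in range(n_iter):
        for idx in parity_idx:
            prop = u[idx] + rng.standard_normal((len(idx), 2)) * u_adapt.scales[idx, None]
            enc_prop = em.rows(prop, p0, sd, subset=idx)
            logr = enc_prop - enc[idx]
            logr -= (move_r2_terms(prop, idx) - move_r2_terms(u[idx], idx)) / (2.0 * su * su)
            first = flat.tag_first[idx]
            if first.any():
                outside = first & ~space.contains(prop)
                logr[outside] = -np.inf
            acc = np.log(rng.uniform(size=len(idx))) < logr
            u[idx[acc]] = prop[acc]
            enc[idx[acc]] = enc_prop[acc]
            u_adapt.record(acc.astype(float), idx)

        # whole-run bridge regeneration of zero-detection stretches
        if zero_runs is not None and zero_runs.any:
            props = zero_runs.propose(u, su, rng)
            for kind, g in zero_runs.groups.items():
                prop = props[kind]
                R = g["pos"].shape[0]
                mask = g["pos"] >= 0
                flatpos = g["pos"][mask]
                ez = em.allzero(prop[mask], p0, sd)
                run_id = np.repeat(np.arange(R), g["len"])
                logr = (np.bincount(run_id, ez, minlength=R)
                        - np.bincount(run_id, enc[flatpos], minlength=R))
                if kind == "leading":
                    # the run starts at the tag's first signal: uniform prior
                    inside = space.contains(prop[:, 0, :])
                    logr = np.where(inside, logr, -np.inf)
                acc = np.log(rng.uniform(size=R)) < logr
                if acc.any():
                    accmask = mask & acc[:, None]
                    u[g["pos"][accmask]] = prop[accmask]
                    enc[g["pos"][accmask]] = ez[accmask[mask]]

        if fix_params is None:
            # sigma_u: closed-form likelihood in the sufficient statistics
            d = flat.delta[seg]
            diffs = u[flat.has_prev] - u[prev_idx[flat.has_prev]]
            S = float(np.sum(np.sum(diffs**2, axis=1) / d))
            n_seg = int(seg.sum())
            su_prop = su + rng.normal(0, p_adapt.scales[2])
            acc_su = False
            if 0 < su_prop < su_max:
                logr = (-2.0 * n_seg * np.log(su_prop / su)
                        - 0.5 * S * (1.0 / su_prop**2 - 1.0 / su**2))
                acc_su = np.log(rng.uniform()) < logr
                if acc_su:
                    su = su_prop
            p_adapt.record(np.array([float(acc_su)]), np.array([2]))

            # joint (p0, sigma_det) update against the pooled encounter likelihood
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
            out_p[k] = (p0, sd, su)
            out_u[k] = u
            k += 1

    return out_p[:k], out_u[:k], {"u_scale_mean": float(u_adapt.scales.mean())}


def fit_movement(
    tags,
    array: ReceiverArray,
    space: StateSpace,
    variant: str,
    settings: MCMCSettings = MCMCSettings(),
    prior_sigma_det_max: float | None = None,
    prior_sigma_u_max: float | None = None,
    fix_params: tuple | None = None,
) -> MovementFit:
    """Joint MCMC over pooled-tag trajectories and (p0, sigma_det, sigma_u).

    ``tags`` is a sequence of :class:`TagData`.  For ``detection_only`` every
    supplied occasion must have at least one detection (tags with fewer than
    two such occasions are dropped with a warning); for ``known_interval``
    the full (buffered) schedule including all-zero occasions is expected.
    Pass ``fix_params=(p0, sigma_det, sigma_u)`` to sample trajectories with
    the parameters held at known values (used by oracle cross-checks).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    usable = []
    for t in tags:
        if t is None:
            continue
        if variant == "detection_only":
            if np.any(t.Y.sum(axis=1) == 0):
                raise ValueError("detection_only expects only detected occasions")
            if len(t.times) < 2:
                warnings.warn(
                    f"tag {t.tag_id}: <2 detected occasions, excluded from detection_only fit"
                )
                continue
        usable.append(t)
    if not usable:
        raise ValueError("no usable tags supplied")

    flat = _FlatTags(usable, array.n_receivers)
    em = EncModel(array.coords, flat.Y)
    zero_runs = _ZeroRuns(flat) if variant == "known_interval" else None
    sd_max = prior_sigma_det_max if prior_sigma_det_max is not None else 0.5 * space.diagonal
    su_max = prior_sigma_u_max if prior_sigma_u_max is not None else 0.5 * space.diagonal
    # data-driven detection-range starting guess: median receiver NN spacing
    from scipy.spatial import cKDTree

    nn = cKDTree(array.coords).query(array.coords, k=min(2, array.n_receivers))[0]
    spacing_guess = float(np.median(nn[:, -1])) if array.n_receivers > 1 else 1.0

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    pdraws, udraws = [], []
    diag = {}
    for c, ss in enumerate(seeds):
        p, uu, info = _run_movement_chain(
            flat, em, array.coords, space, settings, su_max, sd_max, ss,
            spacing_guess, fix_params=fix_params, zero_runs=zero_runs,
        )
        pdraws.append(p)
        udraws.append(uu)
        diag[f"chain{c}"] = info
    P = np.stack(pdraws)  # (chains, kept, 3)
    params = {"p0": P[:, :, 0], "sigma_det": P[:, :, 1], "sigma_u": P[:, :, 2]}
    if fix_params is None and settings.n_chains > 1 and P.shape[1] > 3:
        diag["rhat"] = {k: rhat(v) for k, v in params.items()}
    return MovementFit(
        variant=variant,
        params=params,
        u_draws=np.concatenate(udraws, axis=0),
        tag_ids=flat.tag_ids,
        tag_slices=flat.tag_slices,
        times=flat.times,
        Y=flat.Y.astype(np.uint8),
        diagnostics=diag,
    )
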