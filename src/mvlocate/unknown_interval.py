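"""Unknown-interval movement-assisted localization.

When tags signal on a random schedule (intervals Uniform(a, b)) and only
detection times are recorded, the number of signals missed inside each
inter-detection gap is latent.  This module implements the trans-dimensional
Metropolis-within-Gibbs sampler that estimates, jointly with the detection
and movement parameters: the number of missed signals ``n`` per gap and the
latent locations at which they were emitted.

Signal-rate sub-model.  A gap of observed length ``delta_obs`` bounded by
two detections and containing ``n`` missed signals is tiled by ``k``
inter-signal intervals, each iid Uniform(a, b).  The default convention is
``k = n + 1`` (n interior emissions split the gap into n+1 intervals); the
alternative reading ``k = n`` is available via the ``convention`` flag
because transmitter documentation is sometimes written that way.  The sum
of the k uniforms is approximated as
``delta_obs ~ Normal(k (a+b)/2, k (b-a)^2 / 12)``, which carries all the
schedule information; geometrically a gap with n interior emissions always
has n+1 movement segments, each assigned the equal duration
``delta_obs / (n+1)`` rather than sampling constrained interval durations.

Trans-dimensional update.  Sub-trajectories for every admissible ``n`` are
maintained: dormant ones are refreshed each sweep as exact draws from the
Brownian bridge between the bounding detected locations (their
pseudo-prior), while the active one is updated location-wise against its
full conditional (all-zero encounter terms times the movement bridge).  A
proposed ``n'`` (uniform over the admissible set) is then accepted by
Metropolis-Hastings; because dormant trajectories are distributed exactly
as the movement bridge, the bridge densities cancel from the ratio, which
reduces to the signal-rate term plus the all-zero encounter terms of the
two sub-trajectories.  This is what makes large ``n`` rejectable in the
array interior: each missed signal there must explain an improbable
all-zero encounter history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._mh import EncModel, MCMCSettings, ScaleAdapter, rhat
from .kernels import (
    DetectionParams,
    MovementParams,
    ReceiverArray,
    StateSpace,
    encounter_loglik,
    movement_logdensity,
)

__all__ = [
    "Gap",
    "UnknownIntervalFit",
    "missed_signal_bounds",
    "gap_loglik",
    "sample_bridge",
    "update_gap",
    "fit_unknown_interval",
]

_CONVENTIONS = ("n+1", "n")
_EPS = 1e-9


def missed_signal_bounds(delta_obs: float, a: float, b: float,
                         convention: str = "n+1") -> np.ndarray:
    """Admissible missed-signal counts for a gap of length ``delta_obs``.

    A count ``n`` is admissible iff the gap can be tiled by ``k`` intervals
    each in [a, b] summing to ``delta_obs`` (``k`` per the n<->k
    convention).  Returns an empty array when no tiling exists (e.g.
    ``delta_obs < a``).
    """
    if delta_obs <= 0:
        raise ValueError("delta_obs must be > 0")
    if not (0 < a <= b):
        raise ValueError("require 0 < a <= b")
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    k_min = max(1, int(np.ceil(delta_obs / b - _EPS)))
    k_max = int(np.floor(delta_obs / a + _EPS))
    if k_max < k_min:
        return np.empty(0, dtype=int)
    ks = np.arange(k_min, k_max + 1)
    return ks - 1 if convention == "n+1" else ks


def gap_loglik(delta_obs: float, n: int, a: float, b: float,
               convention: str = "n+1") -> float:
    """Signal-rate log-likelihood of a gap: normal approximation to the sum
    of k iid Uniform(a, b) intervals evaluated at ``delta_obs``."""
    adm = missed_signal_bounds(delta_obs, a, b, convention)
    if n not in adm:
        raise ValueError(
            f"n={n} is not admissible for delta_obs={delta_obs}, a={a}, b={b}")
    if a == b:
        # degenerate schedule: point mass, constant over the single admissible n
        return 0.0
    k = n + 1 if convention == "n+1" else n
    mean = k * (a + b) / 2.0
    var = k * (b - a) ** 2 / 12.0
    return float(-0.5 * np.log(2.0 * np.pi * var)
                 - (delta_obs - mean) ** 2 / (2.0 * var))


@lru_cache(maxsize=None)
def _bridge_chol(k: int) -> np.ndarray:
    """Cholesky factor of the k-segment Brownian-bridge covariance (unit
    per-segment variance) at the k-1 interior points."""
    i = np.arange(1, k)
    M = np.minimum(i[:, None], i[None, :]) - i[:, None] * i[None, :] / k
    return np.linalg.cholesky(M)


def sample_bridge(u_left, u_right, k: int, sigma_u: float, delta_seg: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Exact draw of the k-1 interior points of a Brownian bridge with k
    equal-duration segments between fixed endpoints."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.empty((0, 2))
    u_left = np.asarray(u_left, float)
    u_right = np.asarray(u_right, float)
    frac = np.arange(1, k)[:, None] / k
    mean = u_left + frac * (u_right - u_left)
    z = rng.standard_normal((k - 1, 2))
    return mean + sigma_u * np.sqrt(delta_seg) * (_bridge_chol(k) @ z)


@dataclass
class Gap:
    """One inter-detection gap and its trans-dimensional sampler state."""

    delta_obs: float
    a: float
    b: float
    convention: str = "n+1"
    current_n: int = -1
    sub_trajectories: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        adm = missed_signal_bounds(self.delta_obs, self.a, self.b, self.convention)
        if adm.size == 0:
            raise ValueError(
                f"gap of length {self.delta_obs} admits no tiling by intervals in "
                f"[{self.a}, {self.b}]"
            )
        self.admissible = adm
        if self.current_n < 0:
            expect = int(round(2.0 * self.delta_obs / (self.a + self.b))) - (
                1 if self.convention == "n+1" else 0
            )
            self.current_n = int(adm[np.argmin(np.abs(adm - expect))])
        if self.current_n not in adm:
            raise ValueError(f"current_n={self.current_n} not admissible")

    @property
    def n_min(self) -> int:
        return int(self.admissible.min())

    @property
    def n_max(self) -> int:
        return int(self.admissible.max())

    def seg_duration(self, n: int | None = None) -> float:
        """Movement-segment duration: n interior emissions always cut the
        gap into n+1 segments, whatever the schedule convention."""
        n = self.current_n if n is None else n
        return self.delta_obs / (n + 1)


def update_gap(
    gap: Gap,
    u_left,
    u_right,
    array: ReceiverArray,
    det: DetectionParams,
    move: MovementParams,
    rng: np.random.Generator,
    loc_scale: float = 0.3,
) -> Gap:
    """One sweep of the trans-dimensional gap update (reference single-gap
    implementation; the pooled fitter applies the same kernel in batch).

    (i) refresh every dormant admissible sub-trajectory from its Brownian
    bridge; (ii) update the active sub-trajectory by per-location random-walk
    Metropolis against the bridge full conditional; (iii) propose a new
    missed-signal count uniformly over the admissible set and accept by
    Metropolis-Hastings (signal-rate term plus all-zero encounter terms).
    """
    zeros = np.zeros(array.n_receivers)
    adm = gap.admissible
    cur = gap.current_n

    def enc_sum(traj):
        if len(traj) == 0:
            return 0.0
        return float(np.sum(encounter_loglik(
            np.zeros((len(traj), array.n_receivers)), traj, array, det)))

    for n in adm:
        if n != cur:
            gap.sub_trajectories[n] = sample_bridge(
                u_left, u_right, n + 1, move.sigma_u, gap.seg_duration(n), rng)
    if cur not in gap.sub_trajectories:
        gap.sub_trajectories[cur] = sample_bridge(
            u_left, u_right, cur + 1, move.sigma_u, gap.seg_duration(cur), rng)

    # (ii) per-location MH on the active sub-trajectory
    traj = gap.sub_trajectories[cur]
    dseg = gap.seg_duration(cur)
    pts = ([np.asarray(u_left, float)] + [traj[m] for m in range(len(traj))]
           + [np.asarray(u_right, float)])
    for m in range(1, len(pts) - 1):
        prop = pts[m] + rng.normal(0, loc_scale, size=2)
        cur_ll = (encounter_loglik(zeros, pts[m], array, det)
                  + movement_logdensity(pts[m], pts[m - 1], move, dseg)
                  + movement_logdensity(pts[m + 1], pts[m], move, dseg))
        prop_ll = (encounter_loglik(zeros, prop, array, det)
                   + movement_logdensity(prop, pts[m - 1], move, dseg)
                   + movement_logdensity(pts[m + 1], prop, move, dseg))
        if np.log(rng.uniform()) < prop_ll - cur_ll:
            pts[m] = prop
    gap.sub_trajectories[cur] = np.array(pts[1:-1]).reshape(-1, 2)

    # (iii) trans-dimensional MH on n
    if adm.size > 1:
        choices = adm[adm != cur]
        n_prop = int(choices[rng.integers(choices.size)])
        logr = (gap_loglik(gap.delta_obs, n_prop, gap.a, gap.b, gap.convention)
                + enc_sum(gap.sub_trajectories[n_prop])
                - gap_loglik(gap.delta_obs, cur, gap.a, gap.b, gap.convention)
                - enc_sum(gap.sub_trajectories[cur]))
        if np.log(rng.uniform()) < logr:
            gap.current_n = n_prop
    return gap


@dataclass(frozen=True)
class UnknownIntervalFit:
    """Posterior draws from the unknown-interval model: parameters, detected
    -signal locations, and per-gap missed-signal counts."""

    params: dict  # name -> (chains, kept)
    u_draws: np.ndarray  # (chains*kept, Nd, 2) detected signals only
    n_draws: np.ndarray  # (chains*kept, n_gaps) int
    gap_tag: np.ndarray  # tag index per gap
    gap_delta_obs: np.ndarray
    tag_ids: tuple
    tag_slices: tuple  # per tag (start, stop) into the detected-signal axis
    times: np.ndarray
    Y: np.ndarray
    convention: str
    diagnostics: dict

    def param_draws(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.param_draws(name).mean())

    def posterior_mean_locations(self) -> np.ndarray:
        return self.u_draws.mean(axis=0)

    def gap_n_posterior_mean(self) -> np.ndarray:
        return self.n_draws.mean(axis=0)

    def missed_total_by_tag(self) -> dict:
        """Posterior-mean total number of missed signals per tag (summed
        over that tag's gaps)."""
        means = self.gap_n_posterior_mean()
        return {
            tid: float(means[self.gap_tag == i].sum())
            for i, tid in enumerate(self.tag_ids)
        }


class _UIStruct:
    """Static skeleton of the interleaved flat trajectory (detections plus
    the current missed locations of every gap), with a vectorised rebuild
    for each new missed-count configuration."""

    def __init__(self, tag_lens, gap_tag, gap_delta, boundary_buffer, pad_delta):
        if boundary_buffer:
            raise NotImplementedError(
                "boundary_buffer > 0 is not supported by the pooled sampler; "
                "extend the detected schedule explicitly instead")
        self.tag_lens = np.asarray(tag_lens, dtype=int)
        self.gap_delta = np.asarray(gap_delta, dtype=float)
        n_tags = len(tag_lens)
        G = len(gap_delta)
        # global slot order: per tag, det, gap, det, gap, ..., det
        slot_type, slot_ref = [], []
        det_i = gap_i = 0
        first_det_index = []
        for ti, Td in enumerate(tag_lens):
            first_det_index.append(det_i)
            for li in range(Td):
                slot_type.append(0)
                slot_ref.append(det_i)
                det_i += 1
                if li < Td - 1:
                    slot_type.append(1)
                    slot_ref.append(gap_i)
                    gap_i += 1
        assert gap_i == G
        self.slot_type = np.asarray(slot_type, dtype=int)
        self.slot_ref = np.asarray(slot_ref, dtype=int)
        self.first_det_index = np.asarray(first_det_index, dtype=int)
        self.Nd = det_i

    def build(self, u_det: np.ndarray, gap_trajs: list, cur_n: np.ndarray) -> dict:
        n_arr = np.asarray(cur_n, dtype=int)
        gap_ref = np.where(self.slot_type == 1, self.slot_ref, 0)
        sizes = np.where(self.slot_type == 0, 1, n_arr[gap_ref])
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        N = int(offsets[-1])
        det_slots = self.slot_type == 0
        det_pos = offsets[:-1][det_slots]
        gap_start = offsets[:-1][~det_slots]
        M = int(n_arr.sum())
        # positions of missed locations, in gap order
        missed_gap = np.repeat(np.arange(len(n_arr)), n_arr)
        within = np.arange(M) - np.repeat(np.cumsum(n_arr) - n_arr, n_arr)
        missed_pos = np.repeat(gap_start, n_arr) + within
        u = np.empty((N, 2))
        u[det_pos] = u_det
        if M:
            u[missed_pos] = np.concatenate([t for t in gap_trajs if len(t)], axis=0)
        # segment durations: each gap contributes n+1 positions at delta/(n+1)
        dseg = self.gap_delta / (n_arr + 1)
        tag_first_pos = det_pos[self.first_det_index]
        delta = np.empty(N)
        delta[tag_first_pos] = np.nan
        rest = np.ones(N, dtype=bool)
        rest[tag_first_pos] = False
        delta[rest] = np.repeat(dseg, n_arr + 1)
        tag_first = np.zeros(N, dtype=bool)
        tag_first[tag_first_pos] = True
        has_next = np.zeros(N, dtype=bool)
        has_next[:-1] = ~tag_first[1:]
        return {
            "u": u,
            "delta": delta,
            "tag_first": tag_first,
            "has_prev": ~tag_first,
            "has_next": has_next,
            "det_pos": det_pos,
            "missed_pos": missed_pos,
            "missed_gap": missed_gap,
            "gap_start": gap_start,
            "gap_left_pos": gap_start - 1,
            "gap_right_pos": gap_start + n_arr,
        }


def _run_ui_chain(struct, gaps_meta, X, space, settings, su_max, sd_max, seed,
                  spacing_guess, convention):
    (gap_tag, gap_delta, gap_adm, gap_gapll, n_gaps) = gaps_meta
    rng = np.random.default_rng(seed)
    Nd = struct.Nd
    Ydet_all = struct._Ydet_all

    counts = Ydet_all.sum(axis=1)
    u_det = (Ydet_all @ X) / counts[:, None] + rng.normal(0, 0.05, (Nd, 2))
    mean_iv = struct._mean_interval
    cur_n = np.empty(n_gaps, dtype=int)
    for g in range(n_gaps):
        expect = round(gap_delta[g] / mean_iv) - (1 if convention == "n+1" else 0)
        adm = gap_adm[g]
        cur_n[g] = int(adm[np.argmin(np.abs(adm - expect))])
    # straight-line initial sub-trajectories between the bounding detections
    left_det = struct._gap_left_det
    gap_trajs = []
    for g in range(n_gaps):
        n = cur_n[g]
        ul, ur = u_det[left_det[g]], u_det[left_det[g] + 1]
        frac = (np.arange(1, n + 1) / (n + 1))[:, None]
        gap_trajs.append(ul + frac * (ur - ul))
    flat = struct.build(u_det, gap_trajs, cur_n)
    det_em = EncModel(X, Ydet_all)

    def make_em(fl):
        return EncModel.from_sparse(X, fl["u"].shape[0], fl["det_pos"],
                                    det_em.cols, det_em.mask)

    p0 = float(np.clip(0.5 + rng.normal(0, 0.05), 0.05, 0.95))
    sd = spacing_guess * 0.5 * np.exp(rng.normal(0, 0.1))
    su = 0.25 * spacing_guess * np.exp(rng.normal(0, 0.2))
    u = flat["u"]
    em = make_em(flat)
    enc = em.rows(u, p0, sd)

    u_adapt = ScaleAdapter(np.array([0.2, 0.4]))  # detected, missed
    p_adapt = ScaleAdapter([0.04, 0.06, 0.04])  # (p0, sigma_det) joint, sigma_u

    kept = settings.n_kept
    out_p = np.empty((kept, 3))
    out_u = np.empty((kept, Nd, 2))
    out_n = np.empty((kept, n_gaps), dtype=np.int16)
    k_out = 0

    # padded admissible-set tables for the vectorised n-update; gaps whose
    # only admissible count is 0 never need an update, all others get a
    # proposal each sweep (proposing the current n acts as an independence
    # bridge refresh, which keeps long gaps mixing)
    nontrivial = np.flatnonzero(
        [gap_adm[g].size > 1 or gap_adm[g].max() > 0 for g in range(n_gaps)])
    if nontrivial.size:
        W = max(gap_adm[g].size for g in nontrivial)
        adm_pad = np.zeros((nontrivial.size, W), dtype=int)
        ll_pad = np.full((nontrivial.size, W), -np.inf)
        adm_size = np.empty(nontrivial.size, dtype=int)
        n_min_nt = np.empty(nontrivial.size, dtype=int)
        for i, g in enumerate(nontrivial):
            adm = gap_adm[g]
            adm_pad[i, : adm.size] = adm
            ll_pad[i, : adm.size] = gap_gapll[g]
            adm_size[i] = adm.size
            n_min_nt[i] = adm.min()

    for it in range(settings.n_iter):
        N = u.shape[0]
        tf, hp, hn, delta = (flat["tag_first"], flat["has_prev"],
                             flat["has_next"], flat["delta"])
        is_missed = np.zeros(N, dtype=bool)
        is_missed[flat["missed_pos"]] = True

        # location sweep (checkerboard)
        for start in (0, 1):
            idx = np.arange(start, N, 2)
            scale = np.where(is_missed[idx], u_adapt.scales[1], u_adapt.scales[0])
            prop = u[idx] + rng.standard_normal((len(idx), 2)) * scale[:, None]
            enc_prop = em.rows(prop, p0, sd, subset=idx)
            logr = enc_prop - enc[idx]
            dm = np.zeros(len(idx))
            mp = hp[idx]
            if mp.any():
                i = idx[mp]
                dm[mp] += (np.sum((prop[mp] - u[i - 1]) ** 2, 1)
                           - np.sum((u[i] - u[i - 1]) ** 2, 1)) / delta[i]
            mn = hn[idx]
            if mn.any():
                i = idx[mn]
                dm[mn] += (np.sum((u[i + 1] - prop[mn]) ** 2, 1)
                           - np.sum((u[i + 1] - u[i]) ** 2, 1)) / delta[i + 1]
            logr -= dm / (2.0 * su * su)
            first = tf[idx]
            if first.any():
                outside = first & ~space.contains(prop)
                logr[outside] = -np.inf
            acc = np.log(rng.uniform(size=len(idx))) < logr
            u[idx[acc]] = prop[acc]
            enc[idx[acc]] = enc_prop[acc]
            for gsel in (0, 1):
                m = is_missed[idx] == bool(gsel)
                if m.any():
                    u_adapt.record(np.array([acc[m].mean()]), np.array([gsel]))

        # sigma_u
        diffs = u[hp] - u[np.flatnonzero(hp) - 1]
        S = float(np.sum(np.sum(diffs**2, axis=1) / delta[hp]))
        n_seg = int(hp.sum())
        su_prop = su + rng.normal(0, p_adapt.scales[2])
        acc_su = False
        if 0 < su_prop < su_max:
            logr = (-2.0 * n_seg * np.log(su_prop / su)
                    - 0.5 * S * (1.0 / su_prop**2 - 1.0 / su**2))
            acc_su = np.log(rng.uniform()) < logr
            if acc_su:
                su = su_prop
        p_adapt.record(np.array([float(acc_su)]), np.array([2]))

        # joint (p0, sigma_det)
        p0_prop = p0 + rng.normal(0, p_adapt.scales[0])
        sd_prop = sd + rng.normal(0, p_adapt.scales[1])
        acc_p = False
        if 0.0 < p0_prop < 1.0 and 0.0 < sd_prop < sd_max:
            enc_prop = em.rows(u, p0_prop, sd_prop)
            if np.log(rng.uniform()) < enc_prop.sum() - enc.sum():
                enc, p0, sd = enc_prop, p0_prop, sd_prop
                acc_p = True
        p_adapt.record(np.array([float(acc_p), float(acc_p)]), np.array([0, 1]))

        # trans-dimensional n updates, fully batched
        if nontrivial.size:
            cur_enc_sum = np.zeros(n_gaps)
            if flat["missed_pos"].size:
                np.add.at(cur_enc_sum, flat["missed_gap"], enc[flat["missed_pos"]])
            ar = np.arange(nontrivial.size)
            j = (rng.random(nontrivial.size) * adm_size).astype(int)
            n_prop = adm_pad[ar, j]
            cur_nt = cur_n[nontrivial]
            active = np.flatnonzero((n_prop != cur_nt) | (n_prop > 0))
            accepted = {}
            if active.size:
                ks = n_prop[active] + 1  # movement segments of the proposal
                cur_j = cur_nt - n_min_nt  # admissible sets are contiguous
                ul = u[flat["gap_left_pos"][nontrivial[active]]]
                ur = u[flat["gap_right_pos"][nontrivial[active]]]
                base_logr = (ll_pad[active, j[active]]
                             - ll_pad[active, cur_j[active]]
                             - cur_enc_sum[nontrivial[active]])
                for kk in np.unique(ks):
                    sel = np.flatnonzero(ks == kk)
                    gsel = nontrivial[active[sel]]
                    if kk == 1:
                        enc_sum_prop = np.zeros(sel.size)
                        trajs = [np.empty((0, 2))] * sel.size
                    else:
                        frac = np.arange(1, kk)[None, :, None] / kk
                        mean = (ul[sel][:, None, :]
                                + frac * (ur[sel] - ul[sel])[:, None, :])
                        z = rng.standard_normal((sel.size, kk - 1, 2))
                        L = _bridge_chol(int(kk))
                        dsegs = gap_delta[gsel] / kk
                        w = np.einsum("ij,gjd->gid", L, z)
                        batch = mean + (su * np.sqrt(dsegs))[:, None, None] * w
                        trajs = list(batch)
                        ez = em.allzero(batch.reshape(-1, 2), p0, sd)
                        enc_sum_prop = ez.reshape(sel.size, kk - 1).sum(axis=1)
                    logr = base_logr[sel] + enc_sum_prop
                    acc = np.log(rng.uniform(size=sel.size)) < logr
                    for s, ok in zip(range(sel.size), acc):
                        if ok:
                            accepted[int(gsel[s])] = (int(n_prop[active[sel[s]]]),
                                                      trajs[s])
            if accepted:
                for g, (n_new, _) in accepted.items():
                    cur_n[g] = n_new
                u_det_now = u[flat["det_pos"]]
                gs_arr = flat["gap_start"]
                new_trajs = []
                for g in range(n_gaps):
                    if g in accepted:
                        new_trajs.append(accepted[g][1])
                    else:
                        s = gs_arr[g]
                        new_trajs.append(u[s: s + cur_n[g]])
                flat = struct.build(u_det_now, new_trajs, cur_n)
                u = flat["u"]
                em = make_em(flat)
                enc = em.rows(u, p0, sd)

        if it < settings.n_adapt:
            u_adapt.maybe_adapt(it)
            p_adapt.maybe_adapt(it)
        elif u_adapt.adapting:
            u_adapt.adapting = p_adapt.adapting = False

        if it >= settings.n_burn and (it - settings.n_burn) % settings.thin == 0:
            out_p[k_out] = (p0, sd, su)
            out_u[k_out] = u[flat["det_pos"]]
            out_n[k_out] = cur_n
            k_out += 1

    return out_p[:k_out], out_u[:k_out], out_n[:k_out]


def fit_unknown_interval(
    tags,
    a: float,
    b: float,
    array: ReceiverArray,
    space: StateSpace,
    settings: MCMCSettings = MCMCSettings(),
    convention: str = "n+1",
    n_cap: int = 50,
    prior_sigma_det_max: float | None = None,
    prior_sigma_u_max: float | None = None,
) -> UnknownIntervalFit:
    """Fit the unknown-interval movement-assisted localization model.

    ``tags`` holds detected occasions per tag (times and encounter rows);
    the transmitter interval bounds ``a`` and ``b`` are data.  Gaps whose
    admissible missed-count range is wider than ``n_cap`` are refused: the
    schedule is too fine relative to the gaps, and the data should be
    coarsened first.  Leading/trailing gaps (before the first / after the
    last detection) carry no bounding location on one side and are excluded.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    usable = []
    for t in tags:
        if t is None:
            continue
        if np.any(t.Y.sum(axis=1) == 0):
            raise ValueError("unknown_interval expects only detected occasions")
        if len(t.times) < 2:
            warnings.warn(f"tag {t.tag_id}: <2 detected occasions, excluded")
            continue
        usable.append(t)
    if not usable:
        raise ValueError("no usable tags supplied")

    tag_lens = [len(t.times) for t in usable]
    gap_tag, gap_delta, gap_adm, gap_gapll = [], [], [], []
    for ti, t in enumerate(usable):
        for li in range(len(t.times) - 1):
            d = float(t.times[li + 1] - t.times[li])
            adm = missed_signal_bounds(d, a, b, convention)
            if adm.size == 0:
                raise ValueError(
                    f"tag {t.tag_id}: gap of length {d} admits no tiling by "
                    f"intervals in [{a}, {b}]; check a/b or detection grouping"
                )
            if adm.max() - adm.min() > n_cap:
                raise ValueError(
                    f"tag {t.tag_id}: gap of length {d} admits {adm.size} "
                    f"missed-signal counts (> n_cap={n_cap}); coarsen the data "
                    "(fixed-interval averaging) or raise n_cap"
                )
            gap_adm.append(adm)
            gap_gapll.append(
                np.array([gap_loglik(d, int(n), a, b, convention) for n in adm]))
            gap_tag.append(ti)
            gap_delta.append(d)
    n_gaps = len(gap_delta)
    gap_tag = np.asarray(gap_tag, dtype=int)
    gap_delta = np.asarray(gap_delta, dtype=float)

    struct = _UIStruct(tag_lens, gap_tag, gap_delta, 0, (a + b) / 2.0)
    struct._Ydet_all = np.concatenate([np.asarray(t.Y, float) for t in usable])
    struct._mean_interval = (a + b) / 2.0
    # detected-signal index to the left of each gap
    stops = np.cumsum(tag_lens)
    starts = stops - np.asarray(tag_lens)
    left = []
    for ti, t in enumerate(usable):
        left.extend(range(starts[ti], stops[ti] - 1))
    struct._gap_left_det = np.asarray(left, dtype=int)
    gaps_meta = (gap_tag, gap_delta, gap_adm, gap_gapll, n_gaps)

    sd_max = prior_sigma_det_max if prior_sigma_det_max is not None else 0.5 * space.diagonal
    su_max = prior_sigma_u_max if prior_sigma_u_max is not None else 0.5 * space.diagonal
    from scipy.spatial import cKDTree

    nn = cKDTree(array.coords).query(array.coords, k=min(2, array.n_receivers))[0]
    spacing_guess = float(np.median(nn[:, -1])) if array.n_receivers > 1 else 1.0

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    pdraws, udraws, ndraws = [], [], []
    for ss in seeds:
        p, uu, nn_d = _run_ui_chain(struct, gaps_meta, array.coords, space,
                                    settings, su_max, sd_max, ss, spacing_guess,
                                    convention)
        pdraws.append(p)
        udraws.append(uu)
        ndraws.append(nn_d)
    P = np.stack(pdraws)
    params = {"p0": P[:, :, 0], "sigma_det": P[:, :, 1], "sigma_u": P[:, :, 2]}
    diag = {}
    if settings.n_chains > 1 and P.shape[1] > 3:
        diag["rhat"] = {k: rhat(v) for k, v in params.items()}
    return UnknownIntervalFit(
        params=params,
        u_draws=np.concatenate(udraws, axis=0),
        n_draws=np.concatenate(ndraws, axis=0),
        gap_tag=gap_tag,
        gap_delta_obs=gap_delta,
        tag_ids=tuple(t.tag_id for t in usable),
        tag_slices=tuple((int(x), int(y)) for x, y in zip(starts, stops)),
        times=np.concatenate([t.times for t in usable]),
        Y=np.concatenate([t.Y for t in usable]).astype(np.uint8),
        convention=convention,
        diagnostics=diag,
    )
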