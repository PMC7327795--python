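"""Replicated simulation study: parameter recovery and localization metrics.

Runs the benchmark design end to end: simulate replicate datasets, fit the
four localization models (independent, movement-assisted detection-only,
known-interval, unknown-interval), and tabulate relative parameter bias,
stratum-wise localization RMSE / precision / HPD coverage, and
missed-signal recovery.

The default study keeps the benchmark per-dataset design intact (25 tags,
150 time units, 10x10 unit grid) and is desk-scaled by the replicate count
and chain length: 3 replicate datasets, chains 3 x 3000 with 1000 burn-in
thinned by 2 for every model.  The full-size version (100 datasets, longer
chains) is a matter of turning these knobs up; the estimators are
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._mh import MCMCSettings
from .independent import fit_independent
from .kernels import detection_prob
from .metrics import hpd_covered, stratify_by_detection_count
from .movement import detected_only_data, fit_movement, known_interval_data
from .simulate import SimConfig, make_grid_array, simulate_dataset
from .unknown_interval import fit_unknown_interval

__all__ = ["StudyResult", "run_study", "min_interior_detection_prob"]

_MODELS = ("independent", "detection_only", "known_interval", "unknown_interval")
_STRATA = tuple(range(7))


def min_interior_detection_prob(config: SimConfig | None = None,
                                margin: float = 1.0, step: float = 0.05) -> float:
    """Minimum, over a fine lattice on the array interior, of the probability
    that a signal is detected by at least one receiver.

    ``margin`` shrinks the array hull on every side (default one receiver
    spacing: detection probability drops quickly in the outermost ring).
    """
    config = config if config is not None else SimConfig()
    array = make_grid_array(config.grid_nx, config.grid_ny, config.spacing)
    x0, x1, y0, y1 = array.bounding_box()
    xs = np.arange(x0 + margin, x1 - margin + step / 2, step)
    ys = np.arange(y0 + margin, y1 - margin + step / 2, step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((pts[:, None, :] - array.coords[None, :, :]) ** 2).sum(-1))
    p = detection_prob(d, config.det)
    pdet = 1.0 - np.prod(1.0 - p, axis=1)
    return float(pdet.min())


@dataclass
class StudyResult:
    """Aggregated results of a replicated simulation study."""

    n_datasets: int
    true_params: dict
    param_means: dict  # model -> param -> array of per-dataset posterior means
    bias: dict  # model -> param -> relative bias (fraction)
    strata: dict  # model -> {"stratum","rmse","precision","coverage","n"}
    ui_missed_true_total: float = np.nan
    ui_missed_est_total: float = np.nan
    n_signals_total: int = 0

    @property
    def ui_missed_rel_bias(self) -> float:
        return (self.ui_missed_est_total - self.ui_missed_true_total) / self.ui_missed_true_total

    def stratum_value(self, model: str, stratum: int, what: str) -> float:
        tab = self.strata[model]
        i = list(tab["stratum"]).index(stratum)
        return float(tab[what][i])

    def rmse_reduction_pct(self, stratum: int = 1,
                           model: str = "known_interval") -> float:
        r_ind = self.stratum_value("independent", stratum, "rmse")
        r_mv = self.stratum_value(model, stratum, "rmse")
        return 100.0 * (r_ind - r_mv) / r_ind


class _StratAcc:
    def __init__(self):
        self.se = {s: [] for s in _STRATA}
        self.prec = {s: [] for s in _STRATA}
        self.cov = {s: [] for s in _STRATA}

    def add(self, u_draws, truths, strata, coverage, cov_rng):
        pm = u_draws.mean(axis=0)
        se = ((pm - truths) ** 2).sum(axis=-1)
        dist = np.sqrt(((u_draws - truths[None]) ** 2).sum(axis=-1))
        prec = dist.mean(axis=0)
        for s in _STRATA:
            m = strata == s
            if not m.any():
                continue
            self.se[s].extend(se[m])
            self.prec[s].extend(prec[m])
            if coverage:
                for i in np.flatnonzero(m):
                    self.cov[s].append(
                        hpd_covered(u_draws[:, i, :], truths[i], max_draws=500,
                                    rng=cov_rng)
                    )

    def table(self) -> dict:
        out = {"stratum": [], "rmse": [], "precision": [], "coverage": [], "n": []}
        for s in _STRATA:
            if not self.se[s]:
                continue
            out["stratum"].append(s)
            out["rmse"].append(float(np.sqrt(np.mean(self.se[s]))))
            out["precision"].append(float(np.mean(self.prec[s])))
            out["coverage"].append(float(np.mean(self.cov[s])) if self.cov[s] else np.nan)
            out["n"].append(len(self.se[s]))
        return {k: np.asarray(v) for k, v in out.items()}


def run_study(
    seed: int = 0,
    n_datasets: int = 3,
    n_individuals: int = 25,
    duration: float = 150.0,
    settings: MCMCSettings | None = None,
    models=_MODELS,
    coverage: bool = True,
    ki_buffer: int = 5,
    verbose: bool = False,
) -> StudyResult:
    """Run the replicated simulation study and aggregate the metrics."""
    if settings is None:
        settings = MCMCSettings(n_chains=3, n_iter=3000, n_burn=1000, thin=2)
    base = SimConfig(n_individuals=n_individuals, duration=duration)
    true = {"p0": base.det.p0, "sigma_det": base.det.sigma_det, "sigma_u": base.move.sigma_u}

    master = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(master.spawn(1)[0])
    param_means = {m: {p: [] for p in true} for m in models}
    accs = {m: _StratAcc() for m in models}
    missed_true_total = 0.0
    missed_est_total = 0.0
    n_signals_total = 0

    for d, ss in enumerate(master.spawn(n_datasets)):
        sub = ss.generate_state(len(models) + 1) % (2**31)
        config = replace(base, seed=int(sub[0]))
        sim = simulate_dataset(config)
        n_signals_total += sum(len(t.schedule) for t in sim.tags)
        counts = {t.tag_id: t.encounters.sum(axis=1) for t in sim.tags}
        det_idx = {t.tag_id: np.flatnonzero(counts[t.tag_id] > 0) for t in sim.tags}

        for mi, model in enumerate(models):
            mseed = int(sub[mi + 1])
            st = replace(settings, seed=mseed)
            if verbose:
                print(f"[study] dataset {d} model {model}", flush=True)
            if model == "independent":
                Y = np.concatenate([t.encounters[counts[t.tag_id] > 0] for t in sim.tags])
                truths = np.concatenate(
                    [t.trajectory[counts[t.tag_id] > 0] for t in sim.tags])
                fit = fit_independent(Y, sim.array, sim.space, st)
                param_means[model]["p0"].append(fit.posterior_mean("p0"))
                param_means[model]["sigma_det"].append(fit.posterior_mean("sigma_det"))
                strata = stratify_by_detection_count(Y)
                accs[model].add(fit.u_draws, truths, strata, coverage, cov_rng)
            elif model in ("detection_only", "known_interval"):
                if model == "detection_only":
                    tags = [detected_only_data(t) for t in sim.tags]
                    truth_map = {
                        t.tag_id: t.trajectory[det_idx[t.tag_id]]
                        for t in sim.tags if det_idx[t.tag_id].size >= 2
                    }
                else:
                    tags = [known_interval_data(t, buffer=ki_buffer) for t in sim.tags]
                    truth_map = {}
                    for t in sim.tags:
                        di = det_idx[t.tag_id]
                        if di.size == 0:
                            continue
                        lo = max(0, di[0] - ki_buffer)
                        hi = min(len(t.schedule) - 1, di[-1] + ki_buffer)
                        truth_map[t.tag_id] = t.trajectory[lo: hi + 1]
                fit = fit_movement([t for t in tags if t is not None],
                                   sim.array, sim.space, model, st)
                for p in true:
                    param_means[model][p].append(fit.posterior_mean(p))
                truths = np.concatenate([truth_map[tid] for tid in fit.tag_ids])
                strata = stratify_by_detection_count(fit.Y)
                accs[model].add(fit.u_draws, truths, strata, coverage, cov_rng)
            else:  # unknown_interval
                tags = [detected_only_data(t) for t in sim.tags]
                # tags that wander off the array for long stretches produce
                # gaps ~100 intervals wide; raise the admissible-range cap
                fit = fit_unknown_interval([t for t in tags if t is not None],
                                           base.a, base.b, sim.array, sim.space,
                                           st, n_cap=500)
                for p in true:
                    param_means[model][p].append(fit.posterior_mean(p))
                truth_map = {
                    t.tag_id: t.trajectory[det_idx[t.tag_id]]
                    for t in sim.tags if det_idx[t.tag_id].size >= 2
                }
                truths = np.concatenate([truth_map[tid] for tid in fit.tag_ids])
                strata = stratify_by_detection_count(fit.Y)
                accs[model].add(fit.u_draws, truths, strata, coverage, cov_rng)
                est = fit.missed_total_by_tag()
                for t in sim.tags:
                    if t.tag_id not in est:
                        continue
                    di = det_idx[t.tag_id]
                    c = counts[t.tag_id][di[0]: di[-1] + 1]
                    missed_true_total += float((c == 0).sum())
                    missed_est_total += est[t.tag_id]

    bias = {
        m: {p: (np.mean(v) - true[p]) / true[p] for p, v in pm.items() if len(v)}
        for m, pm in param_means.items()
    }
    return StudyResult(
        n_datasets=n_datasets,
        true_params=true,
        param_means={m: {p: np.asarray(v) for p, v in pm.items() if len(v)}
                     for m, pm in param_means.items()},
        bias=bias,
        strata={m: accs[m].table() for m in models},
        ui_missed_true_total=missed_true_total,
        ui_missed_est_total=missed_est_total,
        n_signals_total=n_signals_total,
    )
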