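"""Estimating missed signals when the transmission schedule is unobserved.

Tags signal every Uniform(a, b) time units, but only detected signals have
timestamps.  The unknown-interval model treats the number of missed signals
in each inter-detection gap as a latent variable with trans-dimensional
MCMC updates, and recovers both the detection/movement parameters and the
per-tag totals of missed signals.
"""

import numpy as np

from mvlocate import (
    MCMCSettings,
    SimConfig,
    fit_unknown_interval,
    missed_signal_bounds,
    simulate_dataset,
)
from mvlocate.movement import detected_only_data

cfg = SimConfig(n_individuals=6, duration=60.0, seed=9)
ds = simulate_dataset(cfg)

# what the bounds look like for a single 4-time-unit gap under a=1, b=2
print("admissible missed counts for a gap of length 4.0:",
      [int(n) for n in missed_signal_bounds(4.0, 1.0, 2.0)])

tags = [detected_only_data(t) for t in ds.tags]
st = MCMCSettings(n_chains=2, n_iter=3000, n_burn=1000, thin=2, seed=2)
fit = fit_unknown_interval([t for t in tags if t], cfg.a, cfg.b,
                           ds.array, ds.space, st)

print(f"\nestimated p0 {fit.posterior_mean('p0'):.3f} (truth 0.562), "
      f"sigma_det {fit.posterior_mean('sigma_det'):.3f} (truth 0.750), "
      f"sigma_u {fit.posterior_mean('sigma_u'):.3f} (truth 0.250)\n")

est = fit.missed_total_by_tag()
print("tag   true missed   estimated missed")
for t in ds.tags:
    if t.tag_id not in est:
        continue
    c = t.encounters.sum(1)
    di = np.flatnonzero(c > 0)
    true_missed = int((c[di[0]: di[-1] + 1] == 0).sum())
    print(f"{t.tag_id:3d}   {true_missed:11d}   {est[t.tag_id]:16.1f}")

print(
    "\n'True missed' counts undetected emissions between a tag's first and\n"
    "last detection; the posterior-mean totals track them closely even\n"
    "though no schedule information beyond (a, b) was used."
)
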