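# mvlocate — movement-assisted localization for acoustic telemetry

Acoustic telemetry studies track fish, turtles, marine mammals and other
aquatic animals by listening for coded tag transmissions at fixed receiver
arrays.  Estimating *where* each transmission came from ("localization")
classically requires simultaneous detections at three or more receivers, and
discards both the occasions with fewer detections and the information in the
receivers that stayed silent.

`mvlocate` treats localization as a hierarchical Bayesian state-space
problem, in the spirit of spatial capture-recapture: the latent source
locations $\mathbf u_t$ follow a Brownian-motion movement process
($\mathbf u_t \mid \mathbf u_{t-1} \sim \mathcal N(\mathbf u_{t-1},
\sigma_u^2 \Delta_t I)$), each receiver $j$ detects signal $t$ independently
with distance-dependent probability (half-normal by default,
$p_{j,t} = p_0 e^{-\lVert \mathbf u_t - \mathbf x_j \rVert^2 / 2\sigma_{det}^2}$),
and — when the transmitter schedule $\Delta_t \sim \mathrm{Uniform}(a,b)$ is
only partially observed — the number of signals missed inside each
inter-detection gap is itself a latent variable with likelihood
$\Delta_{obs} \sim \mathcal N(k(a{+}b)/2,\, k(b{-}a)^2/12)$ for $k$ tiling
intervals.  Everything is estimated jointly by custom
Metropolis-within-Gibbs MCMC, including trans-dimensional updates of the
missed-signal counts.  The payoff: usable localizations from one, two, or
even **zero** detections, unbiased detection/movement parameters estimated
*in situ*, and per-tag estimates of how many transmissions were missed.

Four fitters are provided, mirroring a canonical simulation comparison:

| model | schedule | uses all-zero occasions | typical use |
|---|---|---|---|
| `fit_independent` | none | no | classical per-signal baseline |
| `fit_movement(..., "detection_only")` | elapsed time between detections | no | movement prior only |
| `fit_movement(..., "known_interval")` | fully known | yes | archival/known schedules |
| `fit_unknown_interval` | only (a, b) known | via latent missed signals | realistic field protocol |

See `docs/methods.md` for the model, sampler and design choices, and
`examples/` for narrative scripts (detection functions, simulation,
movement-assisted vs independent localization, missed-signal estimation).

## Worked example

```python
from mvlocate import (SimConfig, MCMCSettings, simulate_dataset,
                      fit_unknown_interval)
from mvlocate.movement import detected_only_data

ds = simulate_dataset(SimConfig(n_individuals=6, duration=60.0, seed=9))
tags = [detected_only_data(t) for t in ds.tags]
fit = fit_unknown_interval([t for t in tags if t], a=1.0, b=2.0,
                           array=ds.array, space=ds.space,
                           settings=MCMCSettings(n_chains=2, n_iter=3000,
                                                 n_burn=1000, seed=2))
print({k: round(fit.posterior_mean(k), 3) for k in fit.params})
print(fit.missed_total_by_tag())
```

Running `python examples/04_unknown_intervals.py` (the same computation with
a per-tag comparison against the simulated truth) prints:

```
admissible missed counts for a gap of length 4.0: [1, 2, 3]

estimated p0 0.527 (truth 0.562), sigma_det 0.787 (truth 0.750), sigma_u 0.261 (truth 0.250)

tag   true missed   estimated missed
  0             3                3.0
  1             4                4.0
  2             0                0.0
  3             4                4.0
  5             3                3.0
```

i.e. the detection intercept, detection range and movement scale are
recovered from detections alone, and the posterior-mean missed-signal totals
track the true number of undetected transmissions per tag.

A thin CLI wraps the library for shell use:

```bash
mvlocate simulate --seed 1 --out simdir
mvlocate fit --model unknown_interval --a 1 --b 2 \
    --receivers simdir/receivers.csv --detections simdir/detections.csv --out fitdir
mvlocate evaluate --truth simdir/truth.csv --localizations fitdir/localizations_mean.csv
```

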