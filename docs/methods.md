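# Methods

## The model

`mvlocate` estimates where tagged aquatic animals were when their acoustic
tags transmitted, using only the *spatial encounter history* — the binary
pattern of which receivers of a fixed array detected each transmission —
optionally joined with a movement model and a signal-rate model.

Notation: a tag emits signals at occasions $t = 1, \dots, T$ from latent
planar locations $\mathbf u_t$; receiver $j$ sits at $\mathbf x_j$;
$y_{j,t} \in \{0,1\}$ records whether receiver $j$ detected signal $t$;
$\Delta_t$ is the interval between transmissions $t-1$ and $t$.

Three sub-models:

1. **Detection.** Conditional on $\mathbf u_t$, detections are independent
   Bernoulli across receivers with a distance-dependent probability.  The
   default (and the only family currently wired into the samplers) is the
   half-normal
   $p_{j,t} = p_0 \exp\!\big(-\lVert\mathbf u_t-\mathbf x_j\rVert^2 / 2\sigma_{det}^2\big)$;
   logistic ($\mathrm{logit}\,p = \alpha_0 + \alpha_1 d$) and hazard-rate
   ($p = 1 - \exp(-(d^2/\sigma)^{-\theta})$, with $p(0)=1$ by continuity)
   forms are provided as kernels.  Receiver-level conditional independence
   given $\mathbf u_t$ is a modelling assumption, implicit in the product
   form of the likelihood.
2. **Movement.** A Brownian-motion Markov chain:
   $\mathbf u_t \mid \mathbf u_{t-1} \sim \mathcal N(\mathbf u_{t-1},\,
   \sigma_u^2 \Delta_t I_2)$.  The second parameter is a *variance* scaled
   linearly by elapsed time; $\sigma_u$ has units distance·time$^{-1/2}$.
   The first location of each tag has a uniform prior over the rectangular
   state space; subsequent locations are not truncated.
3. **Signal rate** (unknown-interval model only). Transmitters emit on a
   random schedule $\Delta_t \sim \mathrm{Uniform}(a, b)$ with $(a, b)$
   known transmitter settings.  A gap of observed length
   $\Delta_{obs}$ between consecutive detections containing $n$ missed
   signals is tiled by $k$ intervals; the sum of $k$ uniforms is
   approximated by
   $\Delta_{obs} \sim \mathcal N\!\big(k(a{+}b)/2,\; k(b{-}a)^2/12\big)$.

### The n ↔ k convention

Whether a gap with $n$ missed signals contains $k = n+1$ intervals (the
geometrically coherent count: $n$ interior emissions split the gap into
$n+1$ pieces) or $k = n$ is a genuine documentation ambiguity in how
transmitter schedules are described.  The package defaults to $k = n+1$
and exposes `convention="n"` as an alternative on
`missed_signal_bounds`, `gap_loglik` and `fit_unknown_interval`.  All
reported results use the default.

### Within-gap interval durations

Sampling $k$ individual interval durations constrained to the simplex
$\sum_i \Delta_i = \Delta_{obs}$, $\Delta_i \in [a,b]$ mixes poorly and
complicates the bridge updates.  Instead each of the $k$ movement segments
inside a gap is assigned the equal duration $\Delta_{obs}/k$, and the
normal approximation above carries all the schedule information.  This is a
documented approximation: it leaves $k\,\Delta_{seg} = \Delta_{obs}$ exact
and is the main suspected source of the small residual downward bias in
$\sigma_u$ under the unknown-interval model (movement variance inside gaps
is slightly regularised toward equal spacing).

## Estimation

All four fitters are custom Metropolis-within-Gibbs samplers (no external
PPL):

* **independent** — detected occasions only, uniform location prior over
  the state space; joint posterior over $(p_0, \sigma_{det})$ and one
  location per occasion.  Deliberately reproduces the biased baseline:
  all-zero occasions are dropped and no $\Pr(\text{detected})$ correction
  is applied, so $p_0$ is overestimated.  Observed zeros at non-detecting
  receivers *are* used.
* **detection_only** — adds the movement chain between detected occasions,
  with $\Delta$ set to the observed elapsed time (missed signals silently
  lengthen intervals).  Tags with fewer than two detected occasions carry
  no movement information and are dropped with a warning.
* **known_interval** — the full schedule is data; all-zero occasions enter
  the likelihood.  Leading/trailing stretches are trimmed to 5 signals
  beyond the first/last detection (configurable), to bound the number of
  unconstrained boundary locations.
* **unknown_interval** — per-gap missed counts $n$ are latent.  Admissible
  counts are enumerated from the tiling constraint
  $k a \le \Delta_{obs} \le k b$; gaps admitting a range wider than
  `n_cap` (default 50) are refused with guidance to coarsen the data.
  Leading/trailing gaps are excluded: with no bounding detection on one
  side, neither the movement bridge nor the tiling constraint is defined
  for them.

### Sampler design

Latent locations are updated site-wise by Gaussian random-walk Metropolis
against the full conditional (encounter term plus the movement kernels to
both neighbours, Markov-blanket only).  Sites are swept in an odd/even
checkerboard so each half-sweep updates conditionally independent sites and
is fully vectorised across all tags.  Scalar parameters use Gaussian random
walks: $(p_0, \sigma_{det})$ jointly against the pooled encounter
likelihood, $\sigma_u$ against the closed-form Gaussian-increments
likelihood.  Priors are uniform: $p_0 \sim U(0,1)$,
$\sigma_{det}, \sigma_u \sim U(0, L)$ with $L$ = half the state-space
diagonal by default (configurable); support violations are handled by
rejection.  Proposal scales adapt multiplicatively in batches of 50 during
burn-in toward a 0.25–0.45 acceptance rate and are frozen afterwards;
location scales are per-site in the fixed-dimension samplers and pooled
(detected vs missed) in the trans-dimensional one.

Single-site random walks relax the large-scale modes of a long imputed
stretch only in O(length²) sweeps, which is far too slow for the
known-interval model's zero-detection runs (tags absent from the array for
tens of signals).  The known-interval sampler therefore adds a whole-run
regeneration move each sweep: every maximal run of consecutive
zero-detection signals is reproposed in one block from the Brownian bridge
between its detected anchors (or a free Brownian extension at a tag's
boundary), an independence proposal whose bridge density cancels against
the movement prior so the Metropolis ratio is just the all-zero encounter
sum difference.  The unknown-interval sampler gets the same effect for
free: proposing the *current* missed count with a fresh bridge is accepted
on the identical ratio, so every gap is re-proposed wholesale each sweep.

Initialization: detected signals start at the mean of their detecting
receivers; zero-detection signals at linear interpolations between the
nearest detected neighbours; missed counts at the schedule expectation
$\Delta_{obs}/\tfrac{a+b}{2}$ rounded to the nearest admissible value.
This guarantees a finite initial log-posterior.

### The trans-dimensional gap update

Sub-trajectories are maintained for every admissible $n$ of a gap.  Each
sweep: (i) the active sub-trajectory (the current $n$) is updated
location-wise against its bridge full conditional — all-zero encounter
terms times the movement kernels; (ii) dormant sub-trajectories are
refreshed as *exact draws* from the Brownian bridge between the bounding
detected locations (equal segment durations, covariance
$\sigma_u^2\Delta_{seg}(\min(i,j) - ij/k)$, sampled via a cached Cholesky
factor); (iii) a new count $n'$ is proposed uniformly over the admissible
set and accepted by Metropolis–Hastings.

Because dormant trajectories are distributed exactly according to the
bridge (their pseudo-prior), the bridge densities cancel between the model
prior and the pseudo-prior in the acceptance ratio, which reduces to

$\log r = \big[\ell_{gap}(n') + \ell_{enc}(\text{traj}_{n'})\big] -
          \big[\ell_{gap}(n) + \ell_{enc}(\text{traj}_{n})\big]$,

with $\ell_{gap}$ the normal-approximation schedule term and $\ell_{enc}$
the sum of all-zero encounter terms over the sub-trajectory.  The common
factor $\mathcal N(\mathbf u_R \mid \mathbf u_L, \sigma_u^2\Delta_{obs})$
cancels across $n$ because every admissible tiling spans the same total
time.  This makes the update an exactly valid product-space
(pseudo-prior) sampler; it is verified against an exhaustive lattice
enumeration of the joint $(n, \text{bridge})$ posterior in the test suite.
It is also what makes large $n$ rejectable inside the array: each missed
signal must explain an improbable all-zero encounter history.  The pooled
fitter applies the identical kernel to all gaps at once, grouping bridge
draws by $k$; dormant trajectories that are never evaluated in a sweep are
simply not materialised, which leaves the sampled law unchanged.

### Chain settings and diagnostics

Defaults follow `MCMCSettings`: 3 chains, 4000 iterations, 1500 burn-in,
thinning 2.  Split-chain $\widehat R$ for the scalar parameters is computed
via ArviZ and reported in `diagnostics["rhat"]`; it is reported, not
auto-failed.

## Numerical choices

* Bernoulli probabilities are clipped to $[10^{-12}, 1-10^{-12}]$ inside
  `encounter_loglik`; this only matters beyond ~7 $\sigma_{det}$ and
  prevents $-\infty$ from floating-point underflow.  The fast sampler path
  evaluates $\log p = \log p_0 - d^2/2\sigma_{det}^2$ directly for detected
  entries, which needs no clipping while $p_0 < 1$.
* Squared distances go through BLAS
  ($\lVert u\rVert^2 + \lVert x\rVert^2 - 2u\cdot x$), floored at 0.
* Admissibility bounds use a $10^{-9}$ tolerance so that degenerate
  schedules ($a = b$, where emission times are exact multiples up to
  float error) enumerate correctly; with $a = b$ the schedule term is a
  constant point mass and the model provably collapses to the
  known-interval model (tested).
* HPD coverage uses a 2-D Gaussian KDE (scipy's plug-in bandwidth) on at
  most 1000 subsampled draws; the truth is covered iff its estimated
  density reaches the empirical $(1-q)$ quantile of the density at the
  draws.  Zero-variance draw sets fall back to an exact-match rule with a
  warning.
* "Precision" aggregates draw-to-truth Euclidean distances by the *mean*
  (not RMS); the two readings are both defensible and the mean is
  documented here as the package's choice.

## The simulator and what passing tests show

`simulate_dataset` reproduces the benchmark study system: a 10×10
unit-spaced receiver grid; initial positions uniform on the array bounding
box buffered by $5\sigma_{det}$; Brownian motion with $\sigma_u = 0.25$;
intervals Uniform(1, 2) over 150 time units; half-normal detection with
$p_0 = \mathrm{logit}^{-1}(0.25) = 0.562$, $\sigma_{det} = 0.75$.  Under
these settings the probability that a signal emitted in the array interior
(one receiver spacing inside the hull) is heard somewhere exceeds 0.90,
dropping quickly outside the hull.  The first emission time of each tag is
drawn Uniform(0, b) — tags are phase-offset, the natural reading of random
schedules deployed to avoid tag interference; the sampling window truncates
the last interval.

The generator emulates the *model*, exactly: real acoustic data violate it
in ways the simulation cannot reveal — sound attenuation varying with
environment (non-Euclidean effective distance), tag collisions, clock
drift, depth, correlated movement.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
these field effects.

## Study scale

The package's replicated study (`run_study`, also driven by
`scripts/acceptance.py`) keeps the benchmark per-dataset design intact —
25 tags over 150 time units, about 2500 signals per dataset — and is
desk-scaled through the replicate count (3 datasets instead of 100) and the
chain length (3 × 3000 iterations, 1000 burn-in, thinned by 2).  The
per-dataset design is deliberately not shrunk: the selection biases of the
detection-only and independent models and the small-sample behaviour of
the scale parameters are properties of the per-dataset data size, whereas
the replicate count only controls the Monte-Carlo error of the tabulated
averages — which is what the acceptance-test tolerances absorb.

## Known limitations

* Samplers estimate the half-normal detection family only; the logistic
  and hazard kernels are available for simulation and likelihood
  evaluation but not wired into the MCMC.
* No auxiliary time-difference-of-arrival or signal-strength likelihoods.
* Single-site location updates: adequate at benchmark scale, but blocked
  updates would mix faster for very dense schedules with tiny
  $\sigma_{det}$.
* The unknown-interval model reports marginal location posteriors for
  detected signals and per-gap missed-count posteriors; missed-signal
  locations have no fixed identity across $n$ draws and are not tabulated
  into RMSE strata (the zero-detection stratum is reported only by the
  known-interval model).
* The unknown-interval model makes no inference before a tag's first or
  after its last detection; there is no analogue of the known-interval
  model's 5-signal boundary buffer.
* The Poisson cue-rate variant of the signal-rate sub-model (natural for
  passive acoustic monitoring of calls) is not shipped; the gap likelihood
  is pluggable in principle but only the uniform/normal-approximation form
  is implemented.
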