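"""Unknown-interval model: missed-signal bounds, the normal-approximation
signal-rate likelihood, Brownian-bridge proposals, and the trans-dimensional
sampler against an exhaustive enumeration oracle."""

import numpy as np
import pytest

from mvlocate import (
    DetectionParams,
    Gap,
    MCMCSettings,
    MovementParams,
    ReceiverArray,
    fit_movement,
    fit_unknown_interval,
    gap_loglik,
    missed_signal_bounds,
    sample_bridge,
    simulate_dataset,
    update_gap,
)
from mvlocate.movement import detected_only_data, known_interval_data
from mvlocate.simulate import SimConfig


class TestMissedSignalBounds:
    @pytest.mark.parametrize(
        "delta,a,b,expected",
        [
            (1.5, 1.0, 2.0, [0]),  # the gap is itself one valid interval
            (1.0, 1.0, 2.0, [0]),
            (2.0, 1.0, 2.0, [0, 1]),  # boundary: one interval of 2 or two of 1
            (3.0, 1.0, 2.0, [1, 2]),
            (600.0, 90.0, 150.0, [3, 4, 5]),  # k in {4,5,6} intervals
        ],
    )
    def test_default_convention(self, delta, a, b, expected):
        assert list(missed_signal_bounds(delta, a, b)) == expected

    def test_alternative_convention_counts_intervals(self):
        assert list(missed_signal_bounds(600.0, 90.0, 150.0, convention="n")) == [4, 5, 6]

    def test_tiling_identity_by_enumeration(self):
        # n is admissible iff k=n+1 satisfies k*a <= delta <= k*b
        for delta in np.linspace(0.5, 12, 47):
            got = set(missed_signal_bounds(delta, 1.0, 2.0).tolist())
            brute = {
                k - 1 for k in range(1, 20) if k * 1.0 <= delta + 1e-12 and delta <= k * 2.0 + 1e-12
            }
            assert got == brute

    def test_short_gap_has_no_tiling(self):
        assert missed_signal_bounds(0.5, 1.0, 2.0).size == 0

    def test_degenerate_schedule(self):
        assert list(missed_signal_bounds(4.5, 1.5, 1.5)) == [2]
        assert missed_signal_bounds(4.0, 1.5, 1.5).size == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            missed_signal_bounds(-1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            missed_signal_bounds(1.0, 2.0, 1.0)


class TestGapLoglik:
    def test_closed_form_at_the_mean(self):
        # k=2 intervals on [1,2]: sum ~ Normal(3, 1/6); logpdf at 3
        expected = -0.5 * np.log(2 * np.pi / 6)
        assert gap_loglik(3.0, 1, 1.0, 2.0) == pytest.approx(expected)
        assert gap_loglik(3.0, 1, 1.0, 2.0) == pytest.approx(-0.0231, abs=2e-4)

    def test_maximised_at_k_times_mean_interval(self):
        lls = [gap_loglik(d, 1, 1.0, 2.0) for d in (2.7, 3.0, 3.3)]
        assert lls[1] == max(lls)

    def test_mean_and_variance_scale_with_k(self):
        # evaluate at the mode: only the -0.5*log(2*pi*k*var1) term remains
        v1 = (2.0 - 1.0) ** 2 / 12
        for n, k in ((1, 2), (3, 4)):
            got = gap_loglik(k * 1.5, n, 1.0, 2.0)
            assert got == pytest.approx(-0.5 * np.log(2 * np.pi * k * v1))

    def test_inadmissible_count_rejected(self):
        with pytest.raises(ValueError):
            gap_loglik(1.5, 3, 1.0, 2.0)


class TestSampleBridge:
    def test_moments(self, rng):
        ul, ur = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        k, su, dseg = 4, 0.5, 0.8
        draws = np.array([sample_bridge(ul, ur, k, su, dseg, rng) for _ in range(8000)])
        m = np.arange(1, k)
        expected_mean = ul + (m / k)[:, None] * (ur - ul)
        expected_var = su**2 * dseg * (m * (k - m) / k)
        assert np.allclose(draws.mean(0), expected_mean, atol=0.02)
        assert np.allclose(draws.var(0), expected_var[:, None], rtol=0.08)

    def test_single_interval_is_empty(self, rng):
        assert sample_bridge([0, 0], [1, 1], 1, 0.5, 1.0, rng).shape == (0, 2)


def _enum_n_posterior(adm, ul, ur, delta, a, b, su, det, array, half=2.2, step=0.15):
    """Exhaustive (n, bridge) enumeration on a lattice: posterior over n."""
    from mvlocate import encounter_loglik

    xs = np.arange(-half, half + step / 2, step)
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    enc0 = np.exp(encounter_loglik(np.zeros((len(pts), array.n_receivers)),
                                   pts, array, det))
    h2 = step * step

    def n2(x, mu, v):
        r2 = ((x - mu) ** 2).sum(-1)
        return np.exp(-r2 / (2 * v)) / (2 * np.pi * v)

    C = n2(ur, ul, su * su * delta)
    zs = {}
    for n in adm:
        k = n + 1
        v = su * su * delta / k
        if n == 0:
            zs[n] = np.exp(gap_loglik(delta, 0, a, b))
            continue
        T = n2(pts[:, None, :], pts[None, :, :], v)
        vec = n2(pts, ul, v) * enc0
        for _ in range(n - 1):
            vec = (T.T @ vec) * enc0 * h2
        z = (vec * n2(ur, pts, v)).sum() * h2 / C
        zs[n] = np.exp(gap_loglik(delta, int(n), a, b)) * z
    tot = sum(zs.values())
    return {n: z / tot for n, z in zs.items()}


class TestUpdateGap:
    ARRAY = ReceiverArray(ids=(0,), coords=np.array([[0.0, 1.5]]))
    DET = DetectionParams(p0=0.9, sigma_det=0.75)
    MOVE = MovementParams(sigma_u=0.5)

    def test_singleton_admissible_set_never_moves(self, rng):
        gap = Gap(delta_obs=2.5, a=1.0, b=2.0)  # only k=2 tiles 2.5
        assert list(gap.admissible) == [1]
        for _ in range(50):
            update_gap(gap, [0, 0], [1, 0], self.ARRAY, self.DET, self.MOVE, rng)
            assert gap.current_n == 1
            assert gap.sub_trajectories[1].shape == (1, 2)

    def test_matches_enumeration_oracle(self, rng):
        """Single-gap trans-dimensional sampler recovers the exhaustively
        enumerated missed-count posterior."""
        ul, ur = np.array([-0.5, 0.0]), np.array([0.5, 0.0])
        delta, a, b = 4.0, 1.0, 2.0
        gap = Gap(delta_obs=delta, a=a, b=b)
        assert list(gap.admissible) == [1, 2, 3]
        oracle = _enum_n_posterior(gap.admissible, ul, ur, delta, a, b,
                                   self.MOVE.sigma_u, self.DET, self.ARRAY)
        counts = {n: 0 for n in gap.admissible}
        n_sweeps, burn = 6000, 500
        for s in range(n_sweeps):
            update_gap(gap, ul, ur, self.ARRAY, self.DET, self.MOVE, rng)
            if s >= burn:
                counts[gap.current_n] += 1
        total = n_sweeps - burn
        for n in gap.admissible:
            assert counts[n] / total == pytest.approx(oracle[int(n)], abs=0.06)

    def test_interior_gaps_favour_few_missed_signals(self, rng):
        """High detection probability at the gap midpoint pushes the
        missed-count posterior down relative to the schedule-only prior."""
        arr = ReceiverArray(ids=(0,), coords=np.array([[0.0, 0.0]]))
        det = DetectionParams(p0=0.95, sigma_det=1.0)
        ul, ur = np.array([-0.5, 0.0]), np.array([0.5, 0.0])
        hot = _enum_n_posterior([1, 2, 3], ul, ur, 4.0, 1.0, 2.0, 0.3, det, arr)
        far = ReceiverArray(ids=(0,), coords=np.array([[0.0, 50.0]]))
        cold = _enum_n_posterior([1, 2, 3], ul, ur, 4.0, 1.0, 2.0, 0.3, det, far)
        assert hot[1] > cold[1]
        assert hot[2] + hot[3] < cold[2] + cold[3]


class TestFitUnknownInterval:
    def test_draws_respect_bounds(self, rng):
        cfg = SimConfig(n_individuals=4, duration=30.0, seed=21)
        ds = simulate_dataset(cfg)
        tags = [detected_only_data(t) for t in ds.tags]
        st = MCMCSettings(n_chains=1, n_iter=400, n_burn=100, thin=2, seed=3)
        fit = fit_unknown_interval([t for t in tags if t], cfg.a, cfg.b,
                                   ds.array, ds.space, st)
        for g in range(fit.n_draws.shape[1]):
            adm = missed_signal_bounds(fit.gap_delta_obs[g], cfg.a, cfg.b)
            assert np.isin(fit.n_draws[:, g], adm).all()

    def test_degenerate_schedule_collapses_to_known_interval(self):
        """a == b: the schedule is deterministic, every gap's missed count is
        known, and the unknown-interval fit reproduces the known-interval fit
        on the same data."""
        cfg = SimConfig(n_individuals=5, duration=40.0, a=1.5, b=1.5, seed=8)
        ds = simulate_dataset(cfg)
        st = MCMCSettings(n_chains=2, n_iter=2000, n_burn=700, thin=2, seed=17)
        tags = [detected_only_data(t) for t in ds.tags]
        fit_ui = fit_unknown_interval([t for t in tags if t], 1.5, 1.5,
                                      ds.array, ds.space, st)
        tags_ki = [known_interval_data(t, buffer=0) for t in ds.tags
                   if detected_only_data(t) is not None]
        fit_ki = fit_movement(tags_ki, ds.array, ds.space, "known_interval", st)

        # per-gap missed counts are pinned to the truth
        truth_missed = []
        for t in ds.tags:
            if detected_only_data(t) is None:
                continue
            di = np.flatnonzero(t.encounters.sum(1) > 0)
            truth_missed.extend(np.diff(di) - 1)
        assert np.array_equal(fit_ui.n_draws.min(0), fit_ui.n_draws.max(0))
        assert np.array_equal(fit_ui.n_draws[0], np.array(truth_missed))

        for p in ("p0", "sigma_det", "sigma_u"):
            assert fit_ui.posterior_mean(p) == pytest.approx(
                fit_ki.posterior_mean(p), abs=0.05
            )

    def test_oversized_admissible_range_refused(self, two_receivers, small_space):
        from mvlocate import TagData

        tag = TagData(tag_id=0, times=np.array([0.0, 60.0]),
                      Y=np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError, match="coarsen"):
            fit_unknown_interval([tag], 0.1, 0.2, two_receivers, small_space)
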