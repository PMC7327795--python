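"""Movement-assisted fits: full-conditional construction, dense-grid HMM
smoother oracle, information ordering, and the flat-prior limit."""

import numpy as np
import pytest

from mvlocate import (
    MCMCSettings,
    MovementParams,
    TagData,
    detection_prob,
    encounter_loglik,
    fit_independent,
    fit_movement,
    location_full_conditional_logdensity,
    movement_logdensity,
)
from mvlocate.movement import detected_only_data, known_interval_data

DET = (0.562, 0.75)


def _two_node_smoother(array, space, det, move, y1, y2, delta, n=50):
    """Dense-grid forward-backward smoother for a two-signal trajectory with
    uniform prior on the first location."""
    pts, cell = space.grid(n)
    d = np.linalg.norm(pts[:, None, :] - array.coords[None], axis=-1)
    p = detection_prob(d, det)
    w1 = np.prod(np.where(y1 > 0, p, 1 - p), axis=1)
    w2 = np.prod(np.where(y2 > 0, p, 1 - p), axis=1)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    var = move.sigma_u**2 * delta
    K = np.exp(-d2 / (2 * var))  # transition kernel up to a constant
    m1 = w1 * (K @ w2)
    m2 = w2 * (K.T @ w1)
    out = []
    for m in (m1, m2):
        m = m / m.sum()
        mean = (m[:, None] * pts).sum(0)
        sd = np.sqrt((m[:, None] * (pts - mean) ** 2).sum(0))
        out.append((mean, sd))
    return out


class TestFullConditional:
    def test_matches_sum_of_kernels(self, two_receivers, halfnormal, move, rng):
        for _ in range(10):
            u_t, u_p, u_n = rng.normal(0, 1, (3, 2))
            y = rng.integers(0, 2, 2)
            expected = (
                encounter_loglik(y, u_t, two_receivers, halfnormal)
                + movement_logdensity(u_t, u_p, move, 1.3)
                + movement_logdensity(u_n, u_t, move, 0.7)
            )
            got = location_full_conditional_logdensity(
                u_t, y, u_p, u_n, 1.3, 0.7, two_receivers, halfnormal, move
            )
            assert got == pytest.approx(expected)

    def test_boundary_terms_dropped(self, two_receivers, halfnormal, move):
        u_t = np.array([0.2, 0.1])
        y = np.array([1, 0])
        got = location_full_conditional_logdensity(
            u_t, y, None, None, None, None, two_receivers, halfnormal, move
        )
        assert got == pytest.approx(encounter_loglik(y, u_t, two_receivers, halfnormal))


class TestDataPreparation:
    def _fake_tag(self):
        from mvlocate.simulate import SignalSchedule, SimulatedTag

        times = np.arange(8, dtype=float)
        Y = np.zeros((8, 2), dtype=np.uint8)
        Y[2, 0] = 1
        Y[5, 1] = 1
        return SimulatedTag(tag_id=7, schedule=SignalSchedule(times),
                            trajectory=np.zeros((8, 2)), encounters=Y)

    def test_detected_only_keeps_detected_rows(self):
        td = detected_only_data(self._fake_tag())
        assert list(td.times) == [2.0, 5.0]
        assert td.Y.sum() == 2

    def test_known_interval_buffers_by_five(self):
        td = known_interval_data(self._fake_tag(), buffer=5)
        assert list(td.times) == list(range(8))  # clipped at schedule ends
        td2 = known_interval_data(self._fake_tag(), buffer=1)
        assert list(td2.times) == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]


class TestFitMovement:
    def test_trajectory_posterior_matches_grid_smoother(
        self, two_receivers, halfnormal, small_space
    ):
        """Two-signal toy with known parameters: MCMC marginals agree with
        the exhaustive grid smoother."""
        move = MovementParams(sigma_u=0.6)
        tag = TagData(tag_id=0, times=np.array([0.0, 1.0]),
                      Y=np.array([[1, 0], [0, 1]]))
        st = MCMCSettings(n_chains=2, n_iter=5000, n_burn=1000, thin=2, seed=9)
        fit = fit_movement([tag], two_receivers, small_space, "detection_only",
                           st, fix_params=(*DET, move.sigma_u))
        oracle = _two_node_smoother(two_receivers, small_space, halfnormal, move,
                                    np.array([1, 0]), np.array([0, 1]), 1.0)
        for t in (0, 1):
            mean, sd = oracle[t]
            draws = fit.u_draws[:, t, :]
            assert np.allclose(draws.mean(0), mean, atol=0.05)
            assert np.allclose(draws.std(0), sd, rtol=0.15)

    def test_zero_detection_signal_is_less_certain(self, two_receivers, small_space):
        """Known-interval: posterior spread at an undetected signal exceeds
        that at the adjacent detected signals (information ordering)."""
        tag = TagData(tag_id=0, times=np.array([0.0, 1.0, 2.0]),
                      Y=np.array([[1, 0], [0, 0], [1, 0]]))
        st = MCMCSettings(n_chains=2, n_iter=4000, n_burn=1000, thin=2, seed=5)
        fit = fit_movement([tag], two_receivers, small_space, "known_interval",
                           st, fix_params=(*DET, 0.4))
        sds = fit.u_draws.std(axis=0).sum(axis=1)  # total spread per signal
        assert sds[1] > sds[0]
        assert sds[1] > sds[2]

    def test_flat_movement_prior_recovers_independent_posterior(
        self, two_receivers, small_space
    ):
        """sigma_u -> infinity: the movement chain contributes nothing and
        each detected occasion reverts to independent localization."""
        tag = TagData(tag_id=0, times=np.array([0.0, 1.0]),
                      Y=np.array([[1, 0], [0, 1]]))
        st = MCMCSettings(n_chains=2, n_iter=5000, n_burn=1000, thin=2, seed=10)
        fit = fit_movement([tag], two_receivers, small_space, "detection_only",
                           st, fix_params=(*DET, 60.0))
        ind = fit_independent(np.array([[1, 0]]), two_receivers, small_space,
                              st, fix_params=DET)
        mv_draws = fit.u_draws[:, 0, :]
        ind_draws = ind.u_draws[:, 0, :]
        assert np.allclose(mv_draws.mean(0), ind_draws.mean(0), atol=0.08)
        assert np.allclose(mv_draws.std(0), ind_draws.std(0), rtol=0.15)

    def test_detection_only_rejects_zero_rows_and_short_tags(
        self, two_receivers, small_space
    ):
        bad = TagData(tag_id=0, times=np.array([0.0, 1.0]),
                      Y=np.array([[1, 0], [0, 0]]))
        with pytest.raises(ValueError):
            fit_movement([bad], two_receivers, small_space, "detection_only")
        short = TagData(tag_id=1, times=np.array([0.0]), Y=np.array([[1, 0]]))
        ok = TagData(tag_id=2, times=np.array([0.0, 1.0]),
                     Y=np.array([[1, 0], [1, 1]]))
        with pytest.warns(UserWarning):
            fit = fit_movement([short, ok], two_receivers, small_space,
                               "detection_only",
                               MCMCSettings(n_chains=1, n_iter=200, n_burn=50, seed=0))
        assert fit.tag_ids == (2,)

    def test_unknown_variant_rejected(self, two_receivers, small_space):
        with pytest.raises(ValueError):
            fit_movement([], two_receivers, small_space, "bogus")
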