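"""Closed-form and oracle checks of the detection, movement and encounter
kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import bernoulli, norm

from mvlocate import (
    DetectionParams,
    MovementParams,
    ReceiverArray,
    StateSpace,
    detection_prob,
    encounter_loglik,
    movement_logdensity,
)


class TestDetectionProb:
    @pytest.mark.parametrize(
        "dist,expected",
        [
            (0.0, 0.562),
            (0.75, 0.562 * np.exp(-0.5)),  # one sigma_det out
            (100.0, 0.0),
        ],
    )
    def test_halfnormal_values(self, halfnormal, dist, expected):
        assert detection_prob(dist, halfnormal) == pytest.approx(expected, abs=1e-12)

    def test_logistic_matches_expit(self):
        from scipy.special import expit

        par = DetectionParams(family="logistic", alpha0=0.25, alpha1=-2.0)
        d = np.linspace(0, 5, 11)
        assert np.allclose(detection_prob(d, par), expit(0.25 - 2.0 * d))

    def test_hazard_is_one_at_zero_and_vanishes(self):
        par = DetectionParams(family="hazard", sigma_det=0.75, theta=2.0)
        assert detection_prob(0.0, par) == 1.0
        assert detection_prob(50.0, par) < 1e-6

    @pytest.mark.parametrize(
        "par",
        [
            DetectionParams(family="halfnormal", p0=0.9, sigma_det=0.5),
            DetectionParams(family="logistic", alpha0=1.0, alpha1=-3.0),
            DetectionParams(family="hazard", sigma_det=0.5, theta=1.5),
        ],
    )
    def test_monotone_nonincreasing_and_in_unit_interval(self, par):
        d = np.linspace(0, 10, 500)
        p = detection_prob(d, par)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.diff(p) <= 1e-12)

    def test_negative_distance_rejected(self, halfnormal):
        with pytest.raises(ValueError):
            detection_prob(-0.1, halfnormal)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(family="exponential", p0=0.5, sigma_det=1.0)

    def test_missing_family_fields_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(family="logistic", p0=0.5, sigma_det=1.0)


class TestMovementLogdensity:
    def test_value_at_mean(self, move):
        # two axes, each N(0, 0.0625): logpdf sums to -ln(2*pi*0.0625)
        expected = -np.log(2 * np.pi * 0.25**2)
        got = movement_logdensity([1.0, 2.0], [1.0, 2.0], move, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.9347, abs=2e-4)

    def test_matches_scipy_norm(self, move, rng):
        u = rng.normal(size=2)
        v = rng.normal(size=2)
        delta = 2.7
        expected = norm.logpdf(u, loc=v, scale=move.sigma_u * np.sqrt(delta)).sum()
        assert movement_logdensity(u, v, move, delta) == pytest.approx(expected)

    @given(
        dx=st.floats(-3, 3),
        dy=st.floats(-3, 3),
        delta=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_in_arguments(self, dx, dy, delta):
        move = MovementParams(sigma_u=0.4)
        a, b = np.array([0.0, 0.0]), np.array([dx, dy])
        assert movement_logdensity(a, b, move, delta) == pytest.approx(
            movement_logdensity(b, a, move, delta)
        )

    def test_variance_linear_in_delta(self, move):
        # quadrupling the interval doubles the per-axis SD
        u, v = np.array([0.3, -0.2]), np.array([0.0, 0.0])
        wide = MovementParams(sigma_u=2 * move.sigma_u)
        assert movement_logdensity(u, v, move, 4.0) == pytest.approx(
            movement_logdensity(u, v, wide, 1.0)
        )

    def test_integrates_to_one(self, move):
        xs = np.linspace(-2, 2, 401)
        cell = (xs[1] - xs[0]) ** 2
        gx, gy = np.meshgrid(xs, xs)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        ld = movement_logdensity(pts, np.zeros(2), move, 1.5)
        assert np.exp(ld).sum() * cell == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_delta_rejected(self, move):
        with pytest.raises(ValueError):
            movement_logdensity([0, 0], [0, 0], move, 0.0)


class TestEncounterLoglik:
    def test_far_away_all_zero_is_free(self, two_receivers, halfnormal):
        ll = encounter_loglik(np.zeros(2), np.array([500.0, 500.0]),
                              two_receivers, halfnormal)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_single_receiver_detection_at_zero_distance(self, halfnormal):
        arr = ReceiverArray(ids=("r",), coords=np.array([[2.0, 1.0]]))
        ll = encounter_loglik(np.ones(1), np.array([2.0, 1.0]), arr, halfnormal)
        assert ll == pytest.approx(np.log(0.562))

    def test_matches_bernoulli_product_oracle(self, rng, halfnormal):
        arr = ReceiverArray(ids=tuple(range(5)), coords=rng.uniform(0, 3, (5, 2)))
        for _ in range(20):
            u = rng.uniform(-1, 4, 2)
            y = rng.integers(0, 2, 5)
            p = np.array([
                detection_prob(np.linalg.norm(u - x), halfnormal) for x in arr.coords
            ])
            expected = bernoulli.logpmf(y, p).sum()
            assert encounter_loglik(y, u, arr, halfnormal) == pytest.approx(expected)

    def test_length_mismatch_rejected(self, two_receivers, halfnormal):
        with pytest.raises(ValueError):
            encounter_loglik(np.zeros(3), np.zeros(2), two_receivers, halfnormal)

    def test_finite_even_for_conflicting_detection(self, two_receivers, halfnormal):
        # detection at an absurd distance: clipped, never -inf
        ll = encounter_loglik(np.array([1, 0]), np.array([100.0, 0.0]),
                              two_receivers, halfnormal)
        assert np.isfinite(ll)


class TestStateSpace:
    def test_contains_and_area(self):
        sp = StateSpace(0, 2, 0, 1)
        assert sp.area == 2
        assert sp.contains([1, 0.5])
        assert not sp.contains([3, 0.5])
        assert list(sp.contains(np.array([[1, 0.5], [3, 0.5]]))) == [True, False]

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            StateSpace(1, 1, 0, 2)
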