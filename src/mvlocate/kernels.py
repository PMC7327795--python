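"""Probability kernels shared by the simulator and every estimator.

The model has three building blocks:

* a distance-dependent *detection function* ``p(d)`` giving the probability
  that a receiver at distance ``d`` from the transmitting tag records the
  signal (half-normal, logistic, or hazard-rate forms);
* a Brownian-motion *movement kernel*: the location at the next signal is
  bivariate normal around the current location with per-axis variance
  ``sigma_u**2 * delta`` where ``delta`` is the elapsed time; and
* the per-signal *encounter likelihood*: conditional on the source location
  ``u``, detections at the J receivers are independent Bernoulli trials with
  probabilities ``p(||u - x_j||)``.  The binary vector over receivers is the
  spatial encounter history of that signal.

Distances are Euclidean in a planar, pre-projected coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionParams",
    "MovementParams",
    "ReceiverArray",
    "StateSpace",
    "detection_prob",
    "movement_logdensity",
    "encounter_loglik",
]

# Bernoulli probabilities are clipped to this floor/ceiling inside the
# log-likelihood so that floating-point underflow far from the array
# (beyond ~7 sigma_det for the half-normal) cannot produce -inf.
_P_FLOOR = 1e-12

_FAMILIES = ("halfnormal", "logistic", "hazard")


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of a distance-dependent detection function.

    ``p0`` and ``sigma_det`` parameterise the half-normal family
    (``p0`` also caps the hazard family is not used there); ``alpha0``,
    ``alpha1`` are the logistic intercept/slope on the logit scale; ``theta``
    is the hazard-rate shape.  Family-specific fields must be present iff
    that family is selected.
    """

    family: str = "halfnormal"
    p0: float | None = None
    sigma_det: float | None = None
    alpha0: float | None = None
    alpha1: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown detection family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "halfnormal":
            if self.p0 is None or self.sigma_det is None:
                raise ValueError("halfnormal family requires p0 and sigma_det")
            if not (0.0 < self.p0 <= 1.0):
                raise ValueError(f"p0 must be in (0, 1], got {self.p0}")
            if self.sigma_det <= 0:
                raise ValueError(f"sigma_det must be > 0, got {self.sigma_det}")
        elif self.family == "logistic":
            if self.alpha0 is None or self.alpha1 is None:
                raise ValueError("logistic family requires alpha0 and alpha1")
        elif self.family == "hazard":
            if self.sigma_det is None or self.theta is None:
                raise ValueError("hazard family requires sigma_det and theta")
            if self.sigma_det <= 0:
                raise ValueError(f"sigma_det must be > 0, got {self.sigma_det}")
            if self.theta <= 0:
                raise ValueError(f"theta must be > 0, got {self.theta}")


@dataclass(frozen=True)
class MovementParams:
    """Brownian-motion movement: per-axis displacement SD over one unit of
    time is ``sigma_u`` (units: distance / sqrt(time))."""

    sigma_u: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_u) or self.sigma_u < 0:
            raise ValueError(f"sigma_u must be finite and >= 0, got {self.sigma_u}")


@dataclass(frozen=True)
class ReceiverArray:
    """Fixed receiver coordinates defining the sampling geometry."""

    ids: tuple
    coords: np.ndarray  # (J, 2)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "ids", tuple(self.ids))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must have shape (J, 2)")
        if coords.shape[0] < 1:
            raise ValueError("a receiver array needs at least one receiver")
        if len(self.ids) != coords.shape[0]:
            raise ValueError("ids and coords length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("receiver ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValueError("receiver coordinates must be finite")

    @property
    def n_receivers(self) -> int:
        return self.coords.shape[0]

    def bounding_box(self) -> tuple[float, float, float, float]:
        x, y = self.coords[:, 0], self.coords[:, 1]
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())


@dataclass(frozen=True)
class StateSpace:
    """Rectangular planar region over which latent locations live."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("state space requires xmin < xmax and ymin < ymax")

    @classmethod
    def from_array(cls, array: ReceiverArray, buffer: float = 0.0) -> "StateSpace":
        x0, x1, y0, y1 = array.bounding_box()
        return cls(x0 - buffer, x1 + buffer, y0 - buffer, y1 + buffer)

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.xmax - self.xmin, self.ymax - self.ymin))

    def contains(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        pts = np.atleast_2d(u)
        inside = (
            (pts[..., 0] >= self.xmin)
            & (pts[..., 0] <= self.xmax)
            & (pts[..., 1] >= self.ymin)
            & (pts[..., 1] <= self.ymax)
        )
        return inside if u.ndim > 1 else bool(inside[0])

    def grid(self, n: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Cell-centred n x n quadrature grid; returns (points, (n*n,2)),
        cell area)."""
        xs = np.linspace(self.xmin, self.xmax, n + 1)
        ys = np.linspace(self.ymin, self.ymax, n + 1)
        cx = 0.5 * (xs[:-1] + xs[1:])
        cy = 0.5 * (ys[:-1] + ys[1:])
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        return pts, cell


def detection_prob(dist, params: DetectionParams):
    """Detection probability at source-receiver distance ``dist`` (>= 0).

    Vectorised over ``dist``.  The hazard family is defined by continuity at
    zero distance: p(0) = 1.
    """
    d = np.asarray(dist, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if params.family == "halfnormal":
        p = params.p0 * np.exp(-(d**2) / (2.0 * params.sigma_det**2))
    elif params.family == "logistic":
        from scipy.special import expit

        p = expit(params.alpha0 + params.alpha1 * d)
    else:  # hazard
        p = np.empty_like(d, dtype=float)
        zero = d == 0
        p[zero] = 1.0
        with np.errstate(divide="ignore"):
            p[~zero] = 1.0 - np.exp(-((d[~zero] ** 2 / params.sigma_det) ** (-params.theta)))
    if np.ndim(dist) == 0:
        return float(p)
    return p


def movement_logdensity(u, u_prev, move: MovementParams, delta) -> float:
    """Log-density of the Brownian displacement ``u | u_prev`` over elapsed
    time ``delta``: independent Normal(u_prev_axis, sigma_u**2 * delta) per
    axis.  Symmetric in (u, u_prev)."""
    delta = float(delta)
    if delta <= 0:
        raise ValueError(f"elapsed time must be > 0, got {delta}")
    if move.sigma_u <= 0:
        raise ValueError("movement_logdensity requires sigma_u > 0")
    u = np.asarray(u, dtype=float)
    u_prev = np.asarray(u_prev, dtype=float)
    var = move.sigma_u**2 * delta
    r2 = np.sum((u - u_prev) ** 2, axis=-1)
    out = -np.log(2.0 * np.pi * var) - r2 / (2.0 * var)
    return float(out) if np.ndim(r2) == 0 else out


def encounter_loglik(y, u, array: ReceiverArray, params: DetectionParams):
    """Bernoulli log-likelihood of one spatial encounter history ``y`` (binary
    vector over receivers) given source location ``u``.

    Probabilities are clipped away from {0, 1} (see module docstring), so a
    finite value is returned even for detections far outside the nominal
    detection range.
    """
    y = np.asarray(y)
    u = np.asarray(u, dtype=float)
    if y.shape[-1] != array.n_receivers:
        raise ValueError(
            f"encounter vector has length {y.shape[-1]}, expected {array.n_receivers}"
        )
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("encounter history must be binary")
    d = np.sqrt(np.sum((u[..., None, :] - array.coords) ** 2, axis=-1))
    p = np.clip(detection_prob(d, params), _P_FLOOR, 1.0 - _P_FLOOR)
    ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p), axis=-1)
    return float(ll) if np.ndim(ll) == 0 else ll
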