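"""Loss functions connecting data to parameters, and joint beliefs.

The update rule exponentiates a negative weighted loss in place of a
likelihood, so any map ``l(theta, datum) -> real`` defines an inference once
an integrability condition holds.  Self-information losses ``-log f(x; theta)``
recover classical Bayes; M-estimation losses (squared, absolute, Huber) give
robust general-Bayes analogues; a loss may also ignore the datum entirely,
encoding non-stochastic information such as "theta is close to zero".
"""

from __future__ import annotations

import dataclasses
from typing import Any, Callable

import numpy as np

from .belief import BeliefState

__all__ = ["LossSpec", "JointBelief", "make_loss", "LOSS_REGISTRY"]


@dataclasses.dataclass(frozen=True)
class LossSpec:
    """A loss ``l(theta, datum)`` with weight ``w``.

    ``fn`` must be vectorized over its first argument: given a 1-D array of
    parameter points (or ``(n, d)`` for multivariate parameters) and one datum
    it returns the per-point loss.  ``+inf`` encodes a hard constraint (zero
    posterior density); ``-inf`` is an error.
    """

    fn: Callable[[np.ndarray, Any], np.ndarray]
    weight: float = 1.0
    name: str = "custom"
    cumulative: bool = True

    def __post_init__(self):
        if not self.weight > 0:
            raise ValueError("loss weight w must be positive")

    def __call__(self, theta: np.ndarray, datum: Any) -> np.ndarray:
        vals = np.asarray(self.fn(theta, datum), dtype=float)
        if np.any(np.isneginf(vals)) or np.any(np.isnan(vals)):
            raise ValueError(f"loss {self.name!r} produced -inf or NaN values")
        return vals

    def cumulative_loss(self, theta: np.ndarray, data) -> np.ndarray:
        """Sum of per-datum losses over the data list (order-free)."""
        theta = np.asarray(theta, dtype=float)
        total = np.zeros(theta.shape[0] if theta.ndim > 1 else theta.shape, dtype=float)
        for x in data:
            total = total + self(theta, x)
        return total

    def with_weight(self, w: float) -> "LossSpec":
        return dataclasses.replace(self, weight=w)


# ---------------------------------------------------------------------------
# Registry of standard losses

def _squared(theta, x):
    return (theta - x) ** 2


def _absolute(theta, x):
    return np.abs(theta - x)


def _huber_factory(delta: float):
    def _huber(theta, x):
        r = np.abs(theta - x)
        return np.where(r <= delta, 0.5 * r**2, delta * (r - 0.5 * delta))
    return _huber


def _normal_selfinfo_factory(sigma: float):
    c = np.log(sigma * np.sqrt(2 * np.pi))
    def _nll(theta, x):
        return 0.5 * ((x - theta) / sigma) ** 2 + c
    return _nll


def _bernoulli_selfinfo(theta, x):
    # xlogy handles the 0*log(0) corners; impossible outcomes get +inf loss
    from scipy.special import xlogy
    return -(xlogy(x, theta) + xlogy(1 - x, 1 - theta))


def _nonstochastic_quadratic(theta, _info):
    # l(theta, I) = theta^2: non-stochastic statement that theta is near zero.
    return theta**2


LOSS_REGISTRY: dict[str, Callable[..., Callable]] = {
    "squared": lambda: _squared,
    "absolute": lambda: _absolute,
    "huber": _huber_factory,
    "normal_self_information": _normal_selfinfo_factory,
    "bernoulli_self_information": lambda: _bernoulli_selfinfo,
    "nonstochastic_quadratic": lambda: _nonstochastic_quadratic,
}


def make_loss(name: str, weight: float = 1.0, **params) -> LossSpec:
    """Construct a registered loss by name (used by config files and the CLI)."""
    if name not in LOSS_REGISTRY:
        raise KeyError(f"unknown loss {name!r}; available: {sorted(LOSS_REGISTRY)}")
    fn = LOSS_REGISTRY[name](**params)
    return LossSpec(fn=fn, weight=weight, name=name)


# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class JointBelief:
    """A joint belief m(theta, x): marginal prior over theta plus a
    conditional belief for a datum given theta.

    Used by unit-information calibration, where the expected loss is taken
    with respect to this joint.  The conditional is supplied as a sampler
    (``sample_x(theta, rng) -> datum``, vectorized over theta) and optionally
    as a log-density with an x-grid for quadrature.
    """

    prior: BeliefState
    sample_x: Callable[[np.ndarray, np.random.Generator], np.ndarray]
    conditional_logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    x_grid: np.ndarray | None = None

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n pairs (theta_i, x_i) from the joint belief."""
        prior = self.prior if self.prior.normalized else self.prior.normalize()
        masses = prior._masses().ravel()
        idx = rng.choice(masses.size, size=n, p=masses)
        thetas = prior.points[idx]
        if thetas.shape[1] == 1:
            thetas = thetas.ravel()
        xs = np.asarray(self.sample_x(thetas, rng))
        if not np.all(np.isfinite(xs)):
            raise ValueError("conditional sampler produced non-finite data")
        return thetas, xs
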