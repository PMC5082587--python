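"""The general Bayesian update.

Given a prior belief pi(theta), a loss l(theta, x) with weight w > 0 and data
x_1..x_n, the updated belief is

    nu(theta)  ∝  exp{ -w * sum_i l(theta, x_i) }  pi(theta),

the unique coherent minimizer of expected-loss-plus-KL over probability
measures.  With the self-information loss -log f(x; theta) and w = 1 this is
exactly Bayes' rule; with any other loss it is a Gibbs posterior.  All
computation is in the log domain so that the normalizer never overflows.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .belief import BeliefState
from .losses import LossSpec, make_loss

try:  # estimator base: optional, degrades to a plain class
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

__all__ = ["gibbs_update", "log_partition", "sequential_update", "GibbsPosterior"]


def _cumulative_weighted_loss(prior: BeliefState, loss: LossSpec, data) -> np.ndarray:
    """w * sum_i l(theta, x_i) on the prior support, shaped like log_density."""
    pts = prior.points
    theta = pts.ravel() if pts.shape[1] == 1 else pts
    total = loss.cumulative_loss(theta, data)
    return loss.weight * total.reshape(prior.log_density.shape)


def gibbs_update(prior: BeliefState, loss: LossSpec, data) -> BeliefState:
    """Update a prior belief with data through a weighted loss.

    Returns the normalized posterior belief on the prior's support; the prior
    object is left unmodified.  An empty data list returns the (normalized)
    prior, since zero cumulative loss carries no information.

    Raises
    ------
    ValueError
        If the loss produces ``-inf``/NaN anywhere on the support, or if
        ``exp{-w·Σl}·pi`` has zero or non-finite mass (non-integrable
        posterior), naming the offending loss.
    """
    prior_n = prior if prior.normalized else prior.normalize()
    data = list(data)
    if len(data) == 0:
        return prior_n
    wl = _cumulative_weighted_loss(prior_n, loss, data)
    log_post = prior_n.log_density - wl
    post = BeliefState(axes=prior_n.axes, log_density=log_post, kind=prior_n.kind)
    logz = post.log_mass()
    if not np.isfinite(logz):
        raise ValueError(
            f"posterior under loss {loss.name!r} is not integrable on the support "
            f"(log mass = {logz}); check the loss and the grid bounds"
        )
    return post.normalize()


def log_partition(prior: BeliefState, loss: LossSpec, data) -> float:
    """log ∫ exp{-w·Σ_i l(theta, x_i)} pi(dtheta), the update's normalizer.

    Evaluated entirely in the log domain (log-sum-exp over quadrature
    weights), so overflow/underflow cannot occur for finite losses.  Adding a
    constant c to the loss shifts the result by exactly ``-w·c·n``.
    """
    prior_n = prior if prior.normalized else prior.normalize()
    data = list(data)
    wl = _cumulative_weighted_loss(prior_n, loss, data) if data else 0.0
    return float(logsumexp(prior_n.log_density - wl + prior_n._log_quad_weights()))


def sequential_update(prior: BeliefState, loss: LossSpec, batches) -> BeliefState:
    """Update with data partitioned into batches, one batch at a time.

    Coherence of the update rule makes this identical (pointwise) to a single
    update on the concatenated data, in any batch order; empty batches are
    no-ops.
    """
    batches = [list(b) for b in batches]
    if any(len(b) == 0 for b in batches) and all(len(b) == 0 for b in batches):
        return prior if prior.normalized else prior.normalize()
    belief = prior
    for batch in batches:
        belief = gibbs_update(belief, loss, batch)
    return belief


class GibbsPosterior(BaseEstimator):
    """General-Bayes posterior over a scalar parameter, sklearn style.

    Parameters
    ----------
    loss : str or LossSpec, default="squared"
        Registered loss name (see ``genbayes.losses.LOSS_REGISTRY``) or a
        ready ``LossSpec``.
    loss_params : dict, optional
        Extra parameters for a registered loss (e.g. ``{"sigma": 2.0}``).
    weight : float, default=1.0
        The loss weight w (data-versus-prior temperature).
    prior : BeliefState, optional
        Prior belief; defaults to N(prior_mean, prior_sd²) on a dense grid.
    prior_mean, prior_sd, grid_size, grid_span
        Default-prior construction knobs.

    Attributes
    ----------
    posterior_ : BeliefState
        The normalized updated belief.
    log_partition_ : float
        Log normalizer of the update.
    posterior_mean_, posterior_var_ : float
        Moments of the posterior on its grid.
    """

    def __init__(self, loss="squared", loss_params=None, weight=1.0, prior=None,
                 prior_mean=0.0, prior_sd=1.0, grid_size=2048, grid_span=8.0):
        self.loss = loss
        self.loss_params = loss_params
        self.weight = weight
        self.prior = prior
        self.prior_mean = prior_mean
        self.prior_sd = prior_sd
        self.grid_size = grid_size
        self.grid_span = grid_span

    def _resolve(self):
        if isinstance(self.loss, LossSpec):
            loss = self.loss.with_weight(self.weight)
        else:
            loss = make_loss(self.loss, weight=self.weight, **(self.loss_params or {}))
        prior = self.prior
        if prior is None:
            prior = BeliefState.gaussian(self.prior_mean, self.prior_sd,
                                         num=self.grid_size, span=self.grid_span)
        return loss, prior

    def fit(self, X, y=None):
        loss, prior = self._resolve()
        data = list(np.asarray(X).ravel()) if np.ndim(X) <= 1 else list(np.asarray(X))
        self.loss_ = loss
        self.prior_ = prior if prior.normalized else prior.normalize()
        self.log_partition_ = log_partition(self.prior_, loss, data)
        self.posterior_ = gibbs_update(self.prior_, loss, data)
        self.posterior_mean_ = float(self.posterior_.mean()[0])
        self.posterior_var_ = float(self.posterior_.var()[0])
        return self

    def credible_interval(self, level: float = 0.95):
        return self.posterior_.interval(level)
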