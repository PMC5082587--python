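"""Choosing the loss weight w relative to the prior.

The weight w in exp{-w·l}·pi is the temperature trading information in the
data against information in the prior; nothing in the update rule fixes it
when the loss is not a log likelihood.  This module collects the calibration
procedures the package supports:

* **unit information** — match the prior's expected log-density drop from its
  mode against the expected loss under a joint belief m(theta, x), either
  analytically/by quadrature or from data via leave-one-out minimizers;
* **hierarchical** — treat w as unknown with loss xi·log(w), giving a joint
  belief over (theta, w);
* **Bayes-factor / operational** — elicit a subjective Bayes factor at design
  points whose loss-difference statistic has a known F sampling distribution;
* **coverage matching** — pick the w whose posterior credible intervals attain
  nominal frequentist coverage in simulation;
* **conjugate** — read w off a prior expressed as w/Lambda = 1/m prior
  observations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .belief import BeliefState
from .losses import JointBelief, LossSpec
from .update import gibbs_update

__all__ = [
    "prior_complexity",
    "unit_information_w",
    "empirical_unit_information_w",
    "hierarchical_posterior",
    "bayes_factor_calibration_w",
    "coverage_matching_w",
    "conjugate_w",
    "CoverageMatchResult",
]


def prior_complexity(prior: BeliefState) -> float:
    """Expected log density ratio to the prior mode, E_pi[log pi(mode)/pi(theta)].

    This is the prior's "complexity": 1/2 for any normal prior, 0 for a
    uniform prior on a bounded set, 1 for an exponential prior.  Computed by
    quadrature on the prior's grid.
    """
    if not prior.normalized:
        raise ValueError("prior must be normalized (call .normalize() first); "
                         "improper priors have no defined complexity")
    p = prior
    masses = p._masses().ravel()
    logd = p.log_density.ravel()
    mode_logd = np.max(logd)
    if not np.isfinite(mode_logd):
        raise ValueError("prior has no finite mode on its support")
    pos = masses > 0
    val = float(np.sum(masses[pos] * (mode_logd - logd[pos])))
    return val


def _min_loss_per_datum(loss: LossSpec, datum, support: np.ndarray) -> float:
    """min_theta l(theta, x): grid scan plus bounded refinement (tol 1e-10)."""
    vals = loss(support, datum)
    j = int(np.argmin(vals))
    lo = support[max(j - 1, 0)]
    hi = support[min(j + 1, support.size - 1)]
    if hi <= lo:
        return float(vals[j])
    res = optimize.minimize_scalar(
        lambda t: float(loss(np.array([t]), datum)[0]),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
    )
    return float(min(res.fun, vals[j]))


def _min_loss_many(loss: LossSpec, xs: np.ndarray, support: np.ndarray,
                   chunk: int = 512) -> np.ndarray:
    """min_theta l(theta, x_i) for many data, vectorized.

    Grid scan over the support with a three-point parabolic refinement of the
    minimum (exact for quadratic losses).  Requires the loss to broadcast over
    its datum argument; falls back to the scalar path otherwise.
    """
    xs = np.asarray(xs)
    out = np.empty(xs.shape[0])
    h = support[1] - support[0] if support.size > 1 else 0.0
    try:
        for s in range(0, xs.shape[0], chunk):
            xc = xs[s:s + chunk]
            L = loss.fn(support[:, None], xc[None, :])
            L = np.asarray(L, float)
            j = np.argmin(L, axis=0)
            m = L[j, np.arange(xc.size)]
            inner = (j > 0) & (j < support.size - 1)
            if np.any(inner) and h > 0:
                ji = j[inner]
                cols = np.arange(xc.size)[inner]
                y0, y1, y2 = L[ji - 1, cols], L[ji, cols], L[ji + 1, cols]
                denom = y0 - 2 * y1 + y2
                refine = np.where(denom > 0,
                                  y1 - (y0 - y2) ** 2 / (8 * np.maximum(denom, 1e-300)),
                                  y1)
                m[inner] = np.minimum(m[inner], refine)
            out[s:s + chunk] = m
    except Exception:
        out = np.array([_min_loss_per_datum(loss, x, support) for x in xs])
    return out


def unit_information_w(
    prior: BeliefState,
    loss: LossSpec,
    joint: JointBelief,
    n_mc: int = 100_000,
    seed: int | None = None,
    full_output: bool = False,
):
    """Unit-information weight w = prior_complexity / E_m[l(theta, x)].

    The loss is standardized internally so that min_theta l(theta, x) = 0 for
    every datum.  The denominator expectation is taken under the joint belief
    ``joint``: by nested quadrature when the joint carries a conditional
    log-density and x-grid, otherwise by Monte Carlo (``n_mc`` draws) with a
    reported standard error.

    Raises for flat priors (zero complexity): with log{pi(mode)/pi} identically
    zero this calibration would force w = 0 and is disallowed.
    """
    num = prior_complexity(prior)
    if num < 1e-12:
        raise ValueError(
            "unit-information calibration is disallowed for a flat prior: "
            "the prior's expected log-density drop is 0, so no finite w matches it"
        )
    support = prior.points.ravel()
    se = None
    if joint.conditional_logpdf is not None and joint.x_grid is not None:
        # Double quadrature: E[l] = sum_theta pi-mass * E[l - min l | theta].
        p = prior if prior.normalized else prior.normalize()
        theta_mass = p._masses().ravel()
        xg = np.asarray(joint.x_grid, float)
        from .belief import _trapezoid_weights
        xw = _trapezoid_weights(xg)
        mins = _min_loss_many(loss, xg, support)
        L = np.asarray(loss.fn(support[:, None], xg[None, :]), float)  # (Gt, Gx)
        cond = np.exp(np.asarray(joint.conditional_logpdf(xg[None, :], support[:, None]), float))
        cw = cond * xw[None, :]
        cw = cw / cw.sum(axis=1, keepdims=True)
        per_theta = np.sum(cw * (L - mins[None, :]), axis=1)
        denom = float(np.sum(theta_mass * per_theta))
    else:
        rng = np.random.default_rng(seed)
        thetas, xs = joint.sample(n_mc, rng)
        thetas = np.atleast_1d(np.asarray(thetas, float))
        xs = np.asarray(xs, float)
        mins = _min_loss_many(loss, xs, support)
        try:
            raw = np.asarray(loss.fn(thetas, xs), float)
        except Exception:
            raw = np.array([loss(np.atleast_1d(th), x)[0] for th, x in zip(thetas, xs)])
        std = raw - mins
        denom = float(np.mean(std))
        se = float(np.std(std, ddof=1) / np.sqrt(n_mc))
    if denom <= 0:
        raise ValueError("expected loss under the joint belief is zero; cannot calibrate w")
    w = num / denom
    if full_output:
        w_se = w * se / denom if se is not None else None
        return w, {"prior_complexity": num, "expected_loss": denom,
                   "expected_loss_se": se, "w_se": w_se}
    return w


def _loo_minimizers(loss: LossSpec, data: np.ndarray, grid: np.ndarray,
                    polish: bool) -> np.ndarray:
    """argmin_theta sum_{j != i} l(theta, x_j) for every i.

    Grid scan with parabolic refinement; for modest n each minimizer is
    additionally polished by bounded scalar minimization (tol 1e-10).  Ties
    break toward the smallest theta (argmin takes the first grid minimum).
    """
    n = data.size
    G = grid.size
    # loss matrix: L[g, j] = l(grid[g], x_j); float32 at large n bounds memory
    dtype = np.float64 if n <= 2000 else np.float32
    Lcols = np.empty((G, n), dtype=dtype)
    try:
        Lcols[:] = loss.fn(grid[:, None], data[None, :])
    except Exception:
        for j, x in enumerate(data):
            Lcols[:, j] = loss(grid, x)
    total = Lcols.sum(axis=1, dtype=np.float64)
    out = np.empty(n)
    for i in range(n):
        obj = total - Lcols[:, i]
        g = int(np.argmin(obj))
        theta = grid[g]
        if 0 < g < G - 1:
            y0, y1, y2 = obj[g - 1], obj[g], obj[g + 1]
            denom = y0 - 2 * y1 + y2
            if denom > 0:
                theta = grid[g] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0])
        if polish:
            lo = grid[max(g - 1, 0)]
            hi = grid[min(g + 1, G - 1)]
            others = np.delete(data, i)
            res = optimize.minimize_scalar(
                lambda t: float(np.sum(loss(np.full(others.shape, t), others))),
                bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
            )
            theta = float(res.x)
        out[i] = theta
    return out


def empirical_unit_information_w(
    data,
    prior: BeliefState,
    loss: LossSpec,
    grid_size: int = 2001,
    full_output: bool = False,
):
    """Empirical unit-information weight from leave-one-out minimizers.

    The expected loss is estimated by n^{-1} sum_i l(theta_hat_{-i}, x_i),
    where theta_hat_{-i} minimizes the cumulative loss of the held-out sample
    — the pairs (theta_hat_{-i}, x_i) standing in for draws from the joint
    belief.  Each per-datum loss is standardized to have minimum zero.  Then
    w = prior_complexity(prior) / E_hat[l].
    """
    data = np.asarray(data, float).ravel()
    n = data.size
    if n < 3:
        raise ValueError("empirical unit-information calibration needs n >= 3")
    num = prior_complexity(prior)
    if num < 1e-12:
        raise ValueError("unit-information calibration is disallowed for a flat prior")
    lo, hi = data.min(), data.max()
    pad = max(hi - lo, 1.0)
    grid = np.linspace(lo - 0.5 * pad, hi + 0.5 * pad, grid_size)
    polish = n <= 2000
    theta_loo = _loo_minimizers(loss, data, grid, polish=polish)
    support = prior.points.ravel()
    try:
        raw = np.asarray(loss.fn(theta_loo, data), float)
    except Exception:
        raw = np.array([loss(np.array([t]), x)[0] for t, x in zip(theta_loo, data)])
    mins = _min_loss_many(loss, data, support)
    ehat = float(np.mean(raw - mins))
    if ehat <= 0:
        raise ValueError(
            "empirical expected loss is zero (degenerate data); cannot calibrate w"
        )
    w = num / ehat
    if full_output:
        return w, {"prior_complexity": num, "expected_loss": ehat,
                   "loo_minimizers": theta_loo}
    return w


def hierarchical_posterior(
    prior_joint: BeliefState,
    loss: LossSpec,
    xi: float,
    data,
) -> BeliefState:
    """Joint belief over (theta, w) with w treated as unknown.

    With the scale loss l(w) = log(w) weighted by xi >= 0, the joint update is

        nu(theta, w) ∝ w^xi · exp{-w · sum_i l(theta, x_i)} · pi(theta, w),

    on a 2-D grid whose first axis is theta and second axis is w > 0.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    if prior_joint.kind != "grid" or len(prior_joint.axes) != 2:
        raise ValueError("hierarchical posterior needs a 2-D (theta, w) grid prior")
    theta_ax, w_ax = prior_joint.axes
    if np.any(w_ax <= 0):
        raise ValueError("the w axis must be strictly positive")
    cum = loss.cumulative_loss(theta_ax, list(data))
    log_post = (
        prior_joint.log_density
        + xi * np.log(w_ax)[None, :]
        - np.outer(cum, w_ax)
    )
    post = BeliefState(axes=prior_joint.axes, log_density=log_post, kind="grid")
    return post.normalize()


def bayes_factor_calibration_w(bf: float, n: int, alpha: float) -> float:
    """Weight from an elicited Bayes factor at F-distributed design points.

    At design points where the loss-difference statistic S equals the
    (1-alpha) quantile of F_{1, n-1} (the confidence interval just touching
    the null), an analyst stating posterior-to-prior odds BF fixes
    w = -log(BF) / S.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be at least 2")
    if bf > 1:
        raise ValueError(
            "Bayes factor must be in (0, 1]: at these design points the data "
            "evidence cannot favour the alternative over the interval bound"
        )
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    S = float(stats.f.ppf(1 - alpha, 1, n - 1))
    return -np.log(bf) / S


@dataclasses.dataclass
class CoverageMatchResult:
    """Outcome of coverage-matching calibration."""

    w: float
    coverage: float
    se: float
    table: "np.ndarray"  # columns: w, coverage, binomial SE
    warning: bool = False

    def __float__(self):
        return float(self.w)


def coverage_matching_w(
    truth_sampler,
    loss: LossSpec,
    alpha: float,
    w_grid=None,
    reps: int = 500,
    seed: int | None = None,
    prior: BeliefState | None = None,
    w0: float = 1.0,
) -> CoverageMatchResult:
    """Pick w so equal-tailed posterior intervals attain 1-alpha coverage.

    ``truth_sampler(rng) -> (theta0, data)`` generates datasets with known
    truth.  For every w on the grid the Monte Carlo coverage of theta0 by the
    central (1-alpha) posterior interval is estimated over ``reps`` datasets
    (shared across the grid, common random numbers); the w with coverage
    closest to 1-alpha is returned, with a warning flag when no grid point is
    within 3 binomial standard errors of the target.
    """
    if reps < 200:
        raise ValueError("coverage matching needs reps >= 200")
    if w_grid is None:
        w_grid = np.geomspace(w0 / 100.0, w0 * 100.0, 25)
    w_grid = np.asarray(w_grid, float)
    rng = np.random.default_rng(seed)
    if prior is None:
        prior = BeliefState.gaussian(0.0, 1.0)
    prior = prior if prior.normalized else prior.normalize()
    support = prior.points.ravel()

    datasets = [truth_sampler(rng) for _ in range(reps)]
    # Cumulative loss per dataset is independent of w: precompute once.
    cum = np.stack([loss.cumulative_loss(support, list(np.atleast_1d(d))) for _, d in datasets])
    theta0s = np.array([t for t, _ in datasets], float)

    level = 1 - alpha
    cov = np.empty(w_grid.size)
    widths = np.empty(w_grid.size)
    from .belief import _trapezoid_weights
    from scipy.special import logsumexp
    logqw = np.log(_trapezoid_weights(support))
    for k, w in enumerate(w_grid):
        logd = prior.log_density[None, :] - w * cum
        logm = logd + logqw[None, :]
        logm = logm - logsumexp(logm, axis=1, keepdims=True)
        cdf = np.cumsum(np.exp(logm), axis=1)
        hits = 0
        wsum = 0.0
        for r in range(reps):
            lo = np.interp(alpha / 2, cdf[r], support)
            hi = np.interp(1 - alpha / 2, cdf[r], support)
            hits += int(lo <= theta0s[r] <= hi)
            wsum += hi - lo
        cov[k] = hits / reps
        widths[k] = wsum / reps
    se = np.sqrt(np.maximum(cov * (1 - cov), 1e-12) / reps)
    best = int(np.argmin(np.abs(cov - level)))
    warning = bool(np.all(np.abs(cov - level) > 3 * se))
    table = np.column_stack([w_grid, cov, se, widths])
    return CoverageMatchResult(
        w=float(w_grid[best]), coverage=float(cov[best]), se=float(se[best]),
        table=table, warning=warning,
    )


def conjugate_w(lambda_total, m: float) -> float:
    """Weight from a conjugate-form prior pi ∝ exp{-sum_j lambda_j l(theta, mu_j)}.

    A prior worth m observations with total precision Lambda = sum_j lambda_j
    fixes w through w/Lambda = 1/m, i.e. w = Lambda / m.
    """
    lam = np.atleast_1d(np.asarray(lambda_total, float))
    if np.any(lam <= 0):
        raise ValueError("prior precisions lambda must be positive")
    if m <= 0:
        raise ValueError("prior observation count m must be positive")
    return float(lam.sum() / m)
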