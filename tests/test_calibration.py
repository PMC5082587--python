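"""Loss-weight calibration procedures."""

import numpy as np
import pytest
from scipy import stats

from genbayes import (BeliefState, JointBelief, LossSpec,
                      bayes_factor_calibration_w, conjugate_w,
                      coverage_matching_w, empirical_unit_information_w,
                      gibbs_update, hierarchical_posterior, make_loss,
                      prior_complexity, unit_information_w)


# ---------------------------------------------------------------------------
# prior complexity

@pytest.mark.parametrize("tau", [0.3, 1.0, 4.0])
def test_gaussian_prior_complexity_is_half(tau):
    prior = BeliefState.gaussian(0.0, tau, num=2 ** 15)
    assert abs(prior_complexity(prior) - 0.5) < 1e-6


def test_uniform_prior_complexity_zero():
    axis = np.linspace(-1, 1, 1001)
    prior = BeliefState(axes=(axis,), log_density=np.zeros(axis.size)).normalize()
    assert abs(prior_complexity(prior)) < 1e-12


def test_exponential_prior_complexity_one():
    lam = 1.7
    axis = np.linspace(0, 30 / lam, 2 ** 15)
    prior = BeliefState(axes=(axis,), log_density=-lam * axis).normalize()
    assert abs(prior_complexity(prior) - 1.0) < 1e-3


def test_unnormalized_prior_rejected():
    axis = np.linspace(-1, 1, 101)
    raw = BeliefState(axes=(axis,), log_density=np.ones(axis.size))
    with pytest.raises(ValueError, match="normalize"):
        prior_complexity(raw)


# ---------------------------------------------------------------------------
# unit information (analytic joint)

def _normal_joint(prior, sigma):
    return JointBelief(
        prior=prior,
        sample_x=lambda th, rng: rng.normal(th, sigma),
        conditional_logpdf=lambda x, th: (-0.5 * ((x - th) / sigma) ** 2
                                          - np.log(sigma * np.sqrt(2 * np.pi))),
        x_grid=np.linspace(-12 * sigma, 12 * sigma, 1201),
    )


@pytest.mark.parametrize("sigma", [1.0, 2.0])
def test_unit_information_quadratic_normal(sigma, std_normal_prior):
    joint = _normal_joint(std_normal_prior, sigma)
    w = unit_information_w(std_normal_prior, make_loss("squared"), joint)
    assert abs(w - 1 / (2 * sigma**2)) < 2e-3 / sigma**2


def test_unit_information_quadrature_vs_monte_carlo(std_normal_prior):
    joint_q = _normal_joint(std_normal_prior, 1.5)
    w_quad = unit_information_w(std_normal_prior, make_loss("squared"), joint_q)
    joint_mc = JointBelief(prior=std_normal_prior,
                           sample_x=lambda th, rng: rng.normal(th, 1.5))
    w_mc, info = unit_information_w(std_normal_prior, make_loss("squared"),
                                    joint_mc, n_mc=100_000, seed=7,
                                    full_output=True)
    assert abs(w_mc - w_quad) < 3 * info["w_se"]


def test_unit_information_flat_prior_disallowed():
    axis = np.linspace(-1, 1, 501)
    flat = BeliefState(axes=(axis,), log_density=np.zeros(axis.size)).normalize()
    joint = _normal_joint(flat, 1.0)
    with pytest.raises(ValueError, match="disallowed"):
        unit_information_w(flat, make_loss("squared"), joint)


def test_unit_information_invariant_to_loss_shift(std_normal_prior):
    joint = _normal_joint(std_normal_prior, 1.0)
    w0 = unit_information_w(std_normal_prior, make_loss("squared"), joint)
    shifted = LossSpec(fn=lambda t, x: (t - x) ** 2 + 11.0, name="shifted")
    w1 = unit_information_w(std_normal_prior, shifted, joint)
    assert abs(w0 - w1) < 1e-9


# ---------------------------------------------------------------------------
# empirical unit information

def test_empirical_hand_calculation(std_normal_prior):
    # data {-1,0,1}: loo means {0.5, 0, -0.5}, E_hat = 1.5, w = 0.5/1.5
    w = empirical_unit_information_w([-1.0, 0.0, 1.0], std_normal_prior,
                                     make_loss("squared"))
    assert abs(w - 1.0 / 3.0) < 1e-4


def test_empirical_converges_to_analytic(std_normal_prior):
    sigma = 2.0
    rng = np.random.default_rng(5)
    x = rng.normal(0.0, sigma, 10_000)
    w = empirical_unit_information_w(x, std_normal_prior, make_loss("squared"))
    assert abs(w - 1 / (2 * sigma**2)) / (1 / (2 * sigma**2)) < 0.05


def test_empirical_degenerate_data_error(std_normal_prior):
    with pytest.raises(ValueError, match="zero"):
        empirical_unit_information_w([5.0, 5.0, 5.0], std_normal_prior,
                                     make_loss("squared"))


def test_empirical_needs_three_points(std_normal_prior):
    with pytest.raises(ValueError):
        empirical_unit_information_w([1.0, 2.0], std_normal_prior,
                                     make_loss("squared"))


# ---------------------------------------------------------------------------
# hierarchical posterior over (theta, w)

def _theta_w_prior(nt=301, nw=240, w_a=2.0, w_b=3.0):
    theta = np.linspace(-6, 6, nt)
    w_axis = np.linspace(1e-3, 6, nw)
    ld = (-0.5 * theta[:, None] ** 2
          + (w_a - 1) * np.log(w_axis)[None, :] - w_b * w_axis[None, :])
    return BeliefState(axes=(theta, w_axis), log_density=ld).normalize(), w_a, w_b


def test_hierarchical_zero_loss_preserves_marginals():
    prior, w_a, w_b = _theta_w_prior()
    loss = LossSpec(fn=lambda t, x: np.zeros_like(t), name="zero")
    post = hierarchical_posterior(prior, loss, xi=0.7, data=[1.0])
    theta_marg = post.marginal(0)
    assert abs(theta_marg.mean()[0]) < 1e-8
    assert abs(theta_marg.var()[0] - 1.0) < 1e-3
    # w-marginal tilts by w^xi: Gamma(a,b) -> Gamma(a+xi, b)
    w_marg = post.marginal(1)
    assert abs(w_marg.mean()[0] - (w_a + 0.7) / w_b) < 2e-3


def test_hierarchical_gamma_conjugacy_at_fixed_theta():
    prior, w_a, w_b = _theta_w_prior()
    xi = 1.2
    data = [0.8, -0.3]
    loss = make_loss("squared")
    post = hierarchical_posterior(prior, loss, xi=xi, data=data)
    theta_axis, w_axis = post.axes
    i = np.argmin(np.abs(theta_axis - 1.0))
    L = float(np.sum((theta_axis[i] - np.asarray(data)) ** 2))
    cond = post.log_density[i, :]
    cond = BeliefState(axes=(w_axis,), log_density=cond).normalize()
    analytic = BeliefState(
        axes=(w_axis,),
        log_density=(w_a + xi - 1) * np.log(w_axis) - (w_b + L) * w_axis,
    ).normalize()
    assert np.max(np.abs(cond.pdf() - analytic.pdf())) < 1e-6


def test_hierarchical_mass_and_xi_validation():
    prior, *_ = _theta_w_prior(nt=101, nw=80)
    post = hierarchical_posterior(prior, make_loss("squared"), xi=0.0, data=[0.5])
    assert abs(np.exp(post.log_mass()) - 1.0) < 1e-8
    with pytest.raises(ValueError):
        hierarchical_posterior(prior, make_loss("squared"), xi=-1.0, data=[0.5])


def test_hierarchical_point_mass_w_reduces_to_gibbs_update(std_normal_prior):
    w0 = 0.8
    theta = std_normal_prior.axes[0]
    prior2 = BeliefState(axes=(theta, np.array([w0])),
                         log_density=std_normal_prior.log_density[:, None],
                         kind="grid").normalize()
    post2 = hierarchical_posterior(prior2, make_loss("squared"), xi=0.0,
                                   data=[1.4])
    post1 = gibbs_update(std_normal_prior, make_loss("squared", weight=w0), [1.4])
    marg = post2.marginal(0)
    assert np.max(np.abs(marg.pdf() - post1.pdf())) < 1e-8


# ---------------------------------------------------------------------------
# Bayes-factor (operational) calibration

def test_bayes_factor_unit_bf_gives_zero():
    assert bayes_factor_calibration_w(1.0, 100, 0.05) == 0.0


def test_bayes_factor_large_n_chi2_limit():
    w = bayes_factor_calibration_w(np.exp(-1.0), 1_000_000, 0.05)
    assert abs(w - 0.260318) < 1e-4


def test_bayes_factor_monotone_in_n():
    # F_{1,n-1} upper quantiles fall toward the chi-square limit as n grows,
    # so at fixed BF and alpha the implied w rises toward -log(BF)/3.84.
    ws = [bayes_factor_calibration_w(0.5, n, 0.05) for n in (5, 20, 100, 10_000)]
    assert all(a < b for a, b in zip(ws, ws[1:]))
    assert ws[-1] < -np.log(0.5) / stats.chi2.ppf(0.95, 1)


def test_bayes_factor_rejects_bf_above_one():
    with pytest.raises(ValueError):
        bayes_factor_calibration_w(1.5, 100, 0.05)


# ---------------------------------------------------------------------------
# coverage matching

def test_coverage_matching_recovers_unit_information_value(std_normal_prior):
    sigma, n = 1.0, 25
    def sampler(rng):
        theta0 = rng.normal(0, 1)
        return theta0, rng.normal(theta0, sigma, n)
    w_grid = np.geomspace(0.05, 5.0, 13)
    res = coverage_matching_w(sampler, make_loss("squared"), alpha=0.05,
                              w_grid=w_grid, reps=500, seed=42,
                              prior=std_normal_prior)
    target = 1 / (2 * sigma**2)
    assert target / 1.5 <= res.w <= target * 1.5
    # interval width strictly decreases as w grows
    widths = res.table[:, 3]
    assert np.all(np.diff(widths) < 0)
    # fixed seed reproduces the selection
    res2 = coverage_matching_w(sampler, make_loss("squared"), alpha=0.05,
                               w_grid=w_grid, reps=500, seed=42,
                               prior=std_normal_prior)
    assert res2.w == res.w and np.array_equal(res2.table, res.table)


def test_coverage_matching_requires_reps():
    with pytest.raises(ValueError):
        coverage_matching_w(lambda rng: (0.0, [0.0]), make_loss("squared"),
                            alpha=0.05, reps=50)


# ---------------------------------------------------------------------------
# conjugate loss prior

@pytest.mark.parametrize("lam, m, expect", [
    (1.0, 1.0, 1.0),
    (2.0, 4.0, 0.5),
    ([0.5, 1.5], 4.0, 0.5),
])
def test_conjugate_w(lam, m, expect):
    assert conjugate_w(lam, m) == pytest.approx(expect)


def test_conjugate_w_validation():
    with pytest.raises(ValueError):
        conjugate_w(-1.0, 2.0)
    with pytest.raises(ValueError):
        conjugate_w(1.0, 0.0)
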