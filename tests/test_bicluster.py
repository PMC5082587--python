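"""Change-point biclustering: loss, F calibration, partition MCMC, summaries."""

import numpy as np
import pytest
from scipy import stats

import genbayes as gb
from genbayes.bicluster import _initial_partition

from _oracles import enumerate_2x2_partition_posterior


# ---------------------------------------------------------------------------
# partitions and the SOS loss

def test_partition_validation():
    with pytest.raises(ValueError):
        gb.BiclusterPartition(np.array([0, 2]))          # labels not contiguous
    with pytest.raises(ValueError):
        gb.BiclusterPartition(np.array([0, 1]), (2, 2))  # duplicate change point


def test_segment_convention():
    # change point at c splits between columns c and c+1 (1-based)
    part = gb.BiclusterPartition(np.array([0]), (2,))
    assert part.segment_ids(4).tolist() == [0, 0, 1, 1]


def test_sos_finest_partition_is_zero():
    X = np.arange(12.0).reshape(3, 4)
    part = gb.BiclusterPartition(np.arange(3), (1, 2, 3))
    assert gb.sos_loss(part, X) == 0.0


def test_sos_hand_example():
    X = np.array([[0.0, 2.0], [4.0, 6.0]])
    part = gb.BiclusterPartition(np.array([0, 0]), ())
    assert gb.sos_loss(part, X) == 20.0


def test_sos_single_cell_variance_identity():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 7))
    part = gb.BiclusterPartition(np.zeros(5, int), ())
    assert abs(gb.sos_loss(part, X) - X.size * X.var()) < 1e-10


def test_sos_never_increases_under_splitting():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(6, 8))
    coarse = gb.BiclusterPartition(np.array([0, 0, 0, 1, 1, 1]), (4,))
    fine = gb.BiclusterPartition(np.array([0, 0, 1, 2, 2, 3]), (2, 4))
    assert gb.sos_loss(fine, X) <= gb.sos_loss(coarse, X)


def test_sos_decomposition_total_equals_within_plus_between():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 9))
    part = gb.BiclusterPartition(np.array([0, 1, 0, 2, 1, 2]), (3, 6))
    total = float(((X - X.mean()) ** 2).sum())
    within = gb.sos_loss(part, X)
    seg = part.segment_ids(9)
    between = 0.0
    for g in range(part.k_s):
        for s in range(part.k_t + 1):
            cell = X[np.ix_(part.row_labels == g, seg == s)]
            between += cell.size * (cell.mean() - X.mean()) ** 2
    assert abs(total - (within + between)) < 1e-8


# ---------------------------------------------------------------------------
# F-reference and w calibration

def test_reference_loss_limits_and_value():
    # alpha -> 0 limit: f* -> 0, reference equals the null loss
    assert gb.reference_loss(100.0, 3, 288, 1e-12) == pytest.approx(100.0, rel=1e-6)
    f_star = stats.f.ppf(0.999, 2, 285)
    assert gb.reference_loss(100.0, 3, 288, 0.999) == pytest.approx(
        100.0 / (1 + f_star * 2 / 285))
    with pytest.raises(ValueError):
        gb.reference_loss(1.0, 5, 4, 0.9)


def test_calibrate_w_literal_formula():
    l_null, k, n, alpha, R = 1e4, 3, 288, 0.99, 0.01
    f_star = stats.f.ppf(alpha, k - 1, n - k)
    expect = -np.log(R) / (l_null * f_star * (k - 1) / (n - k))
    assert gb.calibrate_w(l_null, k, n, alpha, R) == pytest.approx(expect)


def test_calibrate_w_variants_agree_when_f_term_small():
    # f*(k-1)/(n-k) < 0.05 -> literal and exact within 5%
    l_null, k, n = 500.0, 2, 2000
    alpha = 0.9
    assert stats.f.ppf(alpha, k - 1, n - k) * (k - 1) / (n - k) < 0.05
    lit = gb.calibrate_w(l_null, k, n, alpha, 0.05, variant="literal")
    exa = gb.calibrate_w(l_null, k, n, alpha, 0.05, variant="exact")
    assert abs(lit - exa) / exa < 0.05


def test_calibrate_w_vanishes_as_R_approaches_one():
    w = gb.calibrate_w(1e3, 3, 100, 0.95, 1 - 1e-9)
    assert w == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        gb.calibrate_w(1e3, 3, 100, 0.95, 1.2)


def test_calibrate_w_scale_consistency():
    # scaling X by c scales l_null by c^2 and w by 1/c^2: w*l invariant
    w1 = gb.calibrate_w(1e3, 3, 288, 0.99, 0.01)
    w2 = gb.calibrate_w(1e3 * 4.0, 3, 288, 0.99, 0.01)
    assert w1 * 1e3 == pytest.approx(w2 * 4e3)


def test_randomized_allocation_statistic_is_f_distributed():
    rng = np.random.default_rng(33)
    X = rng.normal(size=(16, 18))
    n, k = X.size, 3
    l_null = float(((X - X.mean()) ** 2).sum())
    vals = X.ravel()
    samples = []
    while len(samples) < 2000:
        lab = rng.integers(0, k, n)
        if np.bincount(lab, minlength=k).min() == 0:
            continue
        l_s = sum(float(((vals[lab == g] - vals[lab == g].mean()) ** 2).sum())
                  for g in range(k))
        samples.append(((l_null - l_s) / (k - 1)) / (l_s / (n - k)))
    p = stats.kstest(samples, "f", args=(k - 1, n - k)).pvalue
    assert p > 0.01


# ---------------------------------------------------------------------------
# partition posterior

def test_log_posterior_label_permutation_invariance():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(5, 6))
    prior = gb.PartitionPrior()
    p1 = gb.BiclusterPartition(np.array([0, 1, 0, 2, 1]), (3,))
    p2 = gb.BiclusterPartition(np.array([1, 0, 1, 2, 0]), (3,))
    assert gb.partition_log_posterior(p1, X, 0.5, prior) == pytest.approx(
        gb.partition_log_posterior(p2, X, 0.5, prior))


def test_log_posterior_ratio_identity():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(4, 6))
    prior = gb.PartitionPrior()
    w = 0.8
    p1 = gb.BiclusterPartition(np.array([0, 0, 1, 1]), (3,))
    p2 = gb.BiclusterPartition(np.array([0, 1, 1, 0]), (2, 4))
    lhs = (gb.partition_log_posterior(p1, X, w, prior)
           - gb.partition_log_posterior(p2, X, w, prior))
    rhs = (-w * (gb.sos_loss(p1, X) - gb.sos_loss(p2, X))
           + prior.log_prior(p1, 4, 6) - prior.log_prior(p2, 4, 6))
    assert lhs == pytest.approx(rhs)


def test_zero_weight_orders_by_prior_alone():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(4, 5))
    prior = gb.PartitionPrior()
    p1 = gb.BiclusterPartition(np.zeros(4, int), ())
    p2 = gb.BiclusterPartition(np.array([0, 1, 2, 3]), (1, 2, 3))
    d = (gb.partition_log_posterior(p1, X, 0.0, prior)
         - gb.partition_log_posterior(p2, X, 0.0, prior))
    assert d == pytest.approx(prior.log_prior(p1, 4, 5) - prior.log_prior(p2, 4, 5))


# ---------------------------------------------------------------------------
# partition MCMC

def test_partition_mcmc_matches_enumeration_2x2():
    X = np.array([[0.0, 2.0], [4.0, 6.0]])
    prior = gb.PartitionPrior()
    w = 0.3
    exact = enumerate_2x2_partition_posterior(X, w, prior)
    tr = gb.partition_mcmc(X, w, prior, iterations=100_000, burn_in=20_000,
                           seed=5)
    mc = tr.partition_probabilities()
    tv = 0.5 * sum(abs(mc.get(s, 0.0) - p) for s, p in exact.items())
    assert tv < 0.03


def test_partition_mcmc_seed_reproducibility():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(5, 6))
    t1 = gb.partition_mcmc(X, 0.4, iterations=3000, seed=11)
    t2 = gb.partition_mcmc(X, 0.4, iterations=3000, seed=11)
    assert np.array_equal(t1.row_labels, t2.row_labels)
    assert t1.change_points == t2.change_points


def test_conditional_sampler_recovers_planted_structure():
    means = 5.0 * np.arange(9).reshape(3, 3)
    hits = 0
    for seed in range(5):
        X, truth = gb.gen_bicluster(12, 12, 3, (4, 8), means, sigma=1.0,
                                    seed=400 + seed)
        rng = np.random.default_rng(500 + seed)
        labels = np.r_[0, 1, 2, rng.integers(0, 3, 9)]
        from genbayes.bicluster import _canonical_labels
        init = gb.BiclusterPartition(_canonical_labels(labels), (2, 6))
        w = gb.calibrate_w(
            gb.sos_loss(gb.BiclusterPartition(np.zeros(12, int), ()), X),
            3, X.size, 0.99, 0.01)
        tr = gb.partition_mcmc(X, w, iterations=10_000, burn_in=4000,
                               seed=seed, init=init, fixed_counts=True)
        modal = tr.modal_configuration()
        hits += (tuple(modal.row_labels)
                 == tuple(truth.description["row_labels"])
                 and modal.change_points == (4, 8))
    assert hits >= 4


# ---------------------------------------------------------------------------
# summaries

def test_coclustering_single_sample_is_indicator():
    X = np.zeros((3, 2))
    part = gb.BiclusterPartition(np.array([0, 1, 0]), ())
    tr = gb.partition_mcmc(X, 0.0, iterations=2, burn_in=1, seed=1, init=part,
                           fixed_counts=True)
    M = gb.coclustering_matrix(tr)
    assert set(np.unique(M)) <= {0.0, 1.0}
    assert M[0, 2] == 1.0 and np.all(np.diag(M) == 1.0)


def test_coclustering_row_permutation_equivariance():
    X, _ = gb.gen_bicluster(8, 8, 2, (4,), 5.0 * np.arange(4).reshape(2, 2),
                            sigma=1.0, seed=13)
    perm = np.random.default_rng(12).permutation(8)
    w = 0.05
    init1 = gb.BiclusterPartition(np.sort(np.arange(8) % 2), (4,))
    from genbayes.bicluster import _canonical_labels
    init2 = gb.BiclusterPartition(_canonical_labels(init1.row_labels[perm]), (4,))
    t1 = gb.partition_mcmc(X, w, iterations=6000, seed=14, init=init1,
                           fixed_counts=True)
    t2 = gb.partition_mcmc(X[perm], w, iterations=6000, seed=14, init=init2,
                           fixed_counts=True)
    M1 = gb.coclustering_matrix(t1)
    M2 = gb.coclustering_matrix(t2)
    assert np.max(np.abs(M1[np.ix_(perm, perm)] - M2)) < 0.1


def test_changepoint_posterior_constant_trace_is_indicator():
    X = np.zeros((2, 5))
    part = gb.BiclusterPartition(np.array([0, 0]), (2,))
    tr = gb.partition_mcmc(X, 0.0, iterations=2, burn_in=1, seed=1, init=part,
                           fixed_counts=True)
    probs = gb.changepoint_posterior(tr, 5)
    assert probs.tolist() == [0.0, 1.0, 0.0, 0.0]


def test_changepoint_posterior_sums_to_expected_count():
    X, _ = gb.gen_bicluster(6, 10, 2, (5,), np.array([[0.0, 5.0], [5.0, 0.0]]),
                            sigma=1.0, seed=15)
    tr = gb.partition_mcmc(X, 0.05, iterations=6000, seed=16)
    probs = gb.changepoint_posterior(tr, 10)
    _, cps = tr.samples()
    assert probs.sum() == pytest.approx(np.mean([len(c) for c in cps]))
    assert int(np.argmax(probs)) + 1 == 5


def test_zero_weight_changepoints_uniform_over_boundaries():
    # w=0: the sampler targets the prior; position exchangeability makes every
    # boundary equally likely, checked against the MC standard error.
    X = np.zeros((3, 9))
    tr = gb.partition_mcmc(X, 0.0, iterations=40_000, burn_in=10_000, seed=17)
    probs = gb.changepoint_posterior(tr, 9)
    assert np.ptp(probs) < 0.08


def test_model_grid_summary_contract():
    means = 5.0 * np.arange(6).reshape(2, 3)
    X, _ = gb.gen_bicluster(8, 9, 2, (3, 6), means, sigma=1.0, seed=18)
    prior = gb.PartitionPrior()
    w = gb.calibrate_w(
        gb.sos_loss(gb.BiclusterPartition(np.zeros(8, int), ()), X),
        3, X.size, 0.99, 0.01)
    grid = [(ks, kt) for ks in (1, 2, 3) for kt in (0, 1, 2)] + [(99, 0)]
    df = gb.model_grid_summary(X, prior, w, grid, iterations=1500, seed=19)
    # the unique (1,0) partition is deterministic: loss equals the total SS
    row = df[(df.k_s == 1) & (df.k_t == 0)].iloc[0]
    total_ss = float(((X - X.mean()) ** 2).sum())
    assert row.avg_loss == pytest.approx(total_ss)
    assert row.note == "deterministic"
    # infeasible cells are kept but flagged
    assert (df[df.k_s == 99].note == "infeasible").all()
    # average loss cannot rise with extra change points at k_s = 1
    r1 = df[df.k_s == 1].sort_values("k_t").avg_loss.to_numpy()
    assert r1[0] >= r1[1] - 1e-6 and r1[1] >= r1[2] - 20.0
    # normalized posterior over feasible cells
    feas = df.log_posterior.dropna()
    assert np.exp(feas).sum() == pytest.approx(1.0, abs=1e-6)


def test_estimator_two_stage_pipeline():
    means = 5.0 * np.arange(9).reshape(3, 3)
    X, truth = gb.gen_bicluster(12, 12, 3, (4, 8), means, sigma=1.0, seed=42)
    est = gb.ChangePointBicluster(iterations=8000, grid_iterations=1200,
                                  random_state=0)
    est.fit(X)
    assert est.w_ > 0
    assert est.coclustering_.shape == (12, 12)
    assert np.allclose(est.coclustering_, est.coclustering_.T)
    assert est.changepoint_probabilities_.shape == (11,)
    same = np.array(truth.description["row_labels"])
    # planted co-members must co-cluster far above planted non-members (the
    # configuration grid may legitimately prefer one extra group at this small
    # row count, which caps within-pair probabilities below 1)
    within = min(est.coclustering_[np.ix_(np.flatnonzero(same == g),
                                          np.flatnonzero(same == g))].min()
                 for g in range(3))
    between = est.coclustering_[np.ix_(np.flatnonzero(same == 0),
                                       np.flatnonzero(same != 0))].max()
    assert within > between + 0.3
    # change-point probabilities concentrate on the planted boundaries
    top2 = np.argsort(est.changepoint_probabilities_)[-2:] + 1
    assert set(top2) == {4, 8}
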