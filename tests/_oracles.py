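"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: model marginals come
from tensor Gauss-Hermite quadrature, the per-marker Bayes factor from
scipy adaptive quadrature, and partition posteriors from exhaustive
enumeration.
"""

import itertools

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import integrate, stats
from scipy.special import logsumexp

import genbayes as gb
from genbayes.survival import _loss_1d_many


def log_model_marginal_gh(ds, delta, v, a, n_nodes=25):
    """log [ pi(delta) * int exp{-l(beta)} prod N(beta_j|0,v) dbeta ] by
    adaptive Gauss-Hermite quadrature centered at the MAP."""
    delta = np.asarray(delta, bool)
    k = int(delta.sum())
    lp_delta = float(np.sum(np.where(delta, np.log(a), np.log(1 - a))))
    null_loss = gb.cox_partial_loss(
        np.zeros(1), gb.SurvivalDataset(ds.times, ds.events, np.zeros((ds.n, 1))))
    if k == 0:
        return lp_delta - null_loss
    bmap, V = gb.map_and_information(ds, delta, v)
    L = np.linalg.cholesky(V)
    nodes, wts = hermegauss(n_nodes)
    Z = np.stack([g.ravel() for g in np.meshgrid(*([nodes] * k), indexing="ij")],
                 axis=-1)
    W = np.prod(np.stack(np.meshgrid(*([wts] * k), indexing="ij"),
                         axis=-1).reshape(-1, k), axis=1)
    B = bmap + Z @ L.T
    sub = gb.SurvivalDataset(ds.times, ds.events, ds.X[:, np.flatnonzero(delta)])
    logf = np.array([-gb.cox_partial_loss(b, sub) for b in B])
    logf += np.sum(-0.5 * B**2 / v - 0.5 * np.log(2 * np.pi * v), axis=1)
    logint = (logsumexp(logf + 0.5 * np.sum(Z**2, axis=1) + np.log(W))
              + np.sum(np.log(np.diag(L))))
    return lp_delta + logint


def exact_model_probabilities(ds, v, a):
    """Posterior over all 2^p inclusion states by enumeration + quadrature."""
    logms = {d: log_model_marginal_gh(ds, d, v, a)
             for d in itertools.product([0, 1], repeat=ds.p)}
    lz = logsumexp(list(logms.values()))
    return {d: float(np.exp(val - lz)) for d, val in logms.items()}


def log_gbf_quadrature(ds, j, v):
    """1-D adaptive-quadrature general Bayes factor for marker j."""
    x = ds.X[:, j]
    l0 = _loss_1d_many(x, ds.times, ds.events, np.array([0.0]))[0]
    def f(b):
        lb = _loss_1d_many(x, ds.times, ds.events, np.array([b]))[0]
        return np.exp(-(lb - l0)) * stats.norm.pdf(b, 0, np.sqrt(v))
    val, err = integrate.quad(f, -8, 8, limit=200)
    return float(np.log(val))


def enumerate_2x2_partition_posterior(X, w, prior):
    """Exact partition posterior on a 2-row, 2-column matrix (4 states)."""
    out = {}
    logps = []
    states = []
    for labels in ([0, 0], [0, 1]):
        for cps in [(), (1,)]:
            part = gb.BiclusterPartition(np.array(labels), cps)
            states.append((tuple(labels), cps))
            logps.append(gb.partition_log_posterior(part, X, w, prior))
    logps = np.array(logps)
    probs = np.exp(logps - logsumexp(logps))
    for s, p in zip(states, probs):
        out[s] = float(p)
    return out
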