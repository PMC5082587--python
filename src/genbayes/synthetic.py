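"""Synthetic data with the statistical structure each analysis assumes.

Every generator returns the dataset together with a :class:`SyntheticTruth`
recording the generating distribution, the true parameter and the seed, so
recovery can always be checked and regeneration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import optimize

from .survival import SurvivalDataset

__all__ = ["SyntheticTruth", "gen_iid", "gen_survival", "gen_bicluster"]


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Record of how a synthetic dataset was generated."""

    description: dict
    seed: int | None

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps({"description": self.description, "seed": self.seed},
                          default=_default, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SyntheticTruth":
        d = json.loads(s)
        return cls(description=d["description"], seed=d["seed"])


def gen_iid(n: int, family: str, params: dict | None = None,
            seed: int | None = None):
    """IID draws from a location-scale family with recorded truth.

    Families: ``normal`` (loc, scale), ``laplace`` (loc, scale), ``t`` (df,
    loc, scale).  Student-t with df <= 4 sets a heavy-tail flag in the truth
    record (its variance is infinite or barely finite), flagging data meant
    for robust-loss demonstrations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    loc = float(params.get("loc", 0.0))
    scale = float(params.get("scale", 1.0))
    if family == "normal":
        x = rng.normal(loc, scale, size=n)
        var = scale**2
        heavy = False
    elif family == "laplace":
        x = rng.laplace(loc, scale, size=n)
        var = 2 * scale**2
        heavy = False
    elif family == "t":
        df = float(params.get("df", 3))
        x = loc + scale * rng.standard_t(df, size=n)
        var = scale**2 * df / (df - 2) if df > 2 else np.inf
        heavy = df <= 4
    else:
        raise ValueError(f"unknown family {family!r}")
    truth = SyntheticTruth(
        description={"family": family, "params": {"loc": loc, "scale": scale,
                                                  **params},
                     "mean": loc, "median": loc, "variance": var,
                     "heavy_tail": heavy, "n": n},
        seed=seed,
    )
    return x, truth


def _solve_censor_rate(lam_subject: np.ndarray, censor_rate: float) -> float:
    """Rate c of independent exponential censoring achieving the target
    expected censored fraction: mean_i c/(c + lambda_i) = censor_rate."""
    def frac(c):
        return float(np.mean(c / (c + lam_subject))) - censor_rate
    lo, hi = 1e-12, float(lam_subject.max())
    while frac(hi) < 0:
        hi *= 4.0
        if hi > 1e12:
            break
    return float(optimize.brentq(frac, lo, hi))


def gen_survival(
    n: int,
    p: int,
    maf: float = 0.3,
    beta_true=None,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.3,
    seed: int | None = None,
):
    """Proportional-hazards survival data with sparse genotype effects.

    Genotypes are Binomial(2, maf) per marker (independent markers — no
    linkage disequilibrium); event times are exponential with hazard
    baseline_rate · exp(x'beta); right censoring is independent exponential
    with its rate solved so the expected censored fraction equals
    ``censor_rate``.  ``beta_true`` may be a dense length-p vector or a dict
    {marker_index: effect}.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    beta = np.zeros(p)
    if beta_true is not None:
        if isinstance(beta_true, dict):
            for j, b in beta_true.items():
                beta[int(j)] = float(b)
        else:
            beta = np.asarray(beta_true, float)
            if beta.size != p:
                raise ValueError("beta_true must have length p")
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        X = rng.binomial(2, maf, size=(n, p)).astype(float)
        lam = baseline_rate * np.exp(X @ beta)
        times = rng.exponential(1.0 / lam)
        if censor_rate > 0:
            c = _solve_censor_rate(lam, censor_rate)
            ctimes = rng.exponential(1.0 / c, size=n)
            events = (times <= ctimes).astype(int)
            times = np.minimum(times, ctimes)
        else:
            events = np.ones(n, int)
        if events.sum() > 0:
            break
    else:
        raise RuntimeError("all draws fully censored after 5 attempts")
    ds = SurvivalDataset(times=times, events=events, X=X)
    truth = SyntheticTruth(
        description={"kind": "survival", "n": n, "p": p, "maf": maf,
                     "beta_true": beta, "baseline_rate": baseline_rate,
                     "censor_rate": censor_rate},
        seed=seed,
    )
    return ds, truth


def gen_bicluster(
    n_rows: int,
    n_cols: int,
    k_s: int,
    change_points,
    group_segment_means,
    sigma: float = 1.0,
    seed: int | None = None,
    row_labels=None,
):
    """Blocked mean-shift matrix with common column change points.

    ``group_segment_means`` must be shaped (k_s, k_t + 1); entry (g, s) is
    the mean of row group g in time segment s, and Gaussian noise with
    standard deviation sigma is added cell-wise.  Row group sizes are as
    equal as possible unless ``row_labels`` is given.
    """
    change_points = tuple(int(c) for c in change_points)
    means = np.asarray(group_segment_means, float)
    if means.shape != (k_s, len(change_points) + 1):
        raise ValueError(
            f"means must be shaped ({k_s}, {len(change_points) + 1}), got {means.shape}"
        )
    if any(c < 1 or c > n_cols - 1 for c in change_points):
        raise ValueError("change points must lie in 1..n_cols-1")
    if row_labels is None:
        row_labels = np.sort(np.arange(n_rows) % k_s)
    else:
        row_labels = np.asarray(row_labels, int)
    rng = np.random.default_rng(seed)
    bounds = np.asarray(change_points, int)
    seg = np.searchsorted(bounds, np.arange(1, n_cols + 1), side="left")
    signal = means[row_labels[:, None], seg[None, :]]
    X = signal + rng.normal(0.0, sigma, size=(n_rows, n_cols))
    truth = SyntheticTruth(
        description={"kind": "bicluster", "n_rows": n_rows, "n_cols": n_cols,
                     "k_s": k_s, "change_points": list(change_points),
                     "row_labels": row_labels, "means": means, "sigma": sigma},
        seed=seed,
    )
    return X, truth
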