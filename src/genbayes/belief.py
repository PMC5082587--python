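"""Belief distributions over parameter space.

A :class:`BeliefState` is the basic container the whole package works with: a
probability distribution over a parameter space, represented either on a dense
rectangular grid (1-D or small-D) or as a cloud of weighted particles.  All
density arithmetic happens in the log domain; normalization uses trapezoid
quadrature on grids and a weight sum on particles.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["BeliefState", "gaussian_grid_axis"]


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Composite-trapezoid quadrature weights for an ordered 1-D grid."""
    x = np.asarray(x, dtype=float)
    if x.size == 1:
        # Point mass: the single point carries unit weight.
        return np.ones(1)
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return w


def gaussian_grid_axis(mean: float, sd: float, num: int = 2048, span: float = 8.0) -> np.ndarray:
    """Default grid axis: ``num`` points spanning ``mean ± span·sd``."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return np.linspace(mean - span * sd, mean + span * sd, num)


@dataclasses.dataclass(frozen=True)
class BeliefState:
    """A probability distribution over a parameter space.

    Parameters
    ----------
    axes
        For grids: a tuple of strictly increasing 1-D coordinate arrays, one
        per parameter dimension.  For particles: a single ``(n, d)`` array of
        particle locations (``kind="particles"``).
    log_density
        Log density evaluated on the grid (shape = axis lengths) or the log
        weight per particle.  ``-inf`` entries (zero density) are allowed;
        ``+inf`` and NaN are not.
    kind
        ``"grid"`` or ``"particles"``.
    normalized
        Whether the represented measure integrates/sums to one.
    """

    axes: tuple
    log_density: np.ndarray
    kind: str = "grid"
    normalized: bool = False

    def __post_init__(self):
        log_density = np.asarray(self.log_density, dtype=float)
        object.__setattr__(self, "log_density", log_density)
        if self.kind == "grid":
            axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
            object.__setattr__(self, "axes", axes)
            for a in axes:
                if a.ndim != 1:
                    raise ValueError("grid axes must be 1-D arrays")
                if a.size > 1 and not np.all(np.diff(a) > 0):
                    raise ValueError("grid axes must be strictly increasing")
            if log_density.shape != tuple(a.size for a in axes):
                raise ValueError(
                    f"log_density shape {log_density.shape} does not match axes "
                    f"{tuple(a.size for a in axes)}"
                )
        elif self.kind == "particles":
            pts = np.atleast_2d(np.asarray(self.axes[0], dtype=float))
            object.__setattr__(self, "axes", (pts,))
            if log_density.shape != (pts.shape[0],):
                raise ValueError("particle log weights must be 1-D, one per particle")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        if np.any(np.isnan(log_density)) or np.any(np.isposinf(log_density)):
            raise ValueError("log densities must be finite or -inf")

    # -- geometry -----------------------------------------------------------

    @property
    def ndim(self) -> int:
        if self.kind == "grid":
            return len(self.axes)
        return self.axes[0].shape[1]

    @property
    def points(self) -> np.ndarray:
        """All support points as an ``(n_points, ndim)`` array (C order)."""
        if self.kind == "particles":
            return self.axes[0]
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def _log_quad_weights(self) -> np.ndarray:
        """Log quadrature weight per support point, same shape as log_density."""
        if self.kind == "particles":
            return np.zeros_like(self.log_density)
        logw = np.zeros(self.log_density.shape)
        for k, a in enumerate(self.axes):
            w = _trapezoid_weights(a)
            shape = [1] * len(self.axes)
            shape[k] = a.size
            with np.errstate(divide="ignore"):
                logw = logw + np.log(w).reshape(shape)
        return logw

    # -- mass and normalization --------------------------------------------

    def log_mass(self) -> float:
        """Log of the total integrated (grid) or summed (particle) mass."""
        return float(logsumexp(self.log_density + self._log_quad_weights()))

    def normalize(self) -> "BeliefState":
        logz = self.log_mass()
        if not np.isfinite(logz):
            raise ValueError("belief state has zero or non-finite total mass")
        return dataclasses.replace(
            self, log_density=self.log_density - logz, normalized=True
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_logpdf(cls, axes: Sequence[np.ndarray], logpdf: Callable) -> "BeliefState":
        """Grid belief from a vectorized log-density of the stacked coordinates."""
        axes = tuple(np.asarray(a, dtype=float) for a in axes)
        mesh = np.meshgrid(*axes, indexing="ij")
        if len(axes) == 1:
            vals = logpdf(mesh[0])
        else:
            vals = logpdf(*mesh)
        return cls(axes=axes, log_density=np.asarray(vals, float), kind="grid").normalize()

    @classmethod
    def gaussian(cls, mean: float = 0.0, sd: float = 1.0, num: int = 2048,
                 span: float = 8.0) -> "BeliefState":
        """Normal prior N(mean, sd²) on its default grid."""
        axis = gaussian_grid_axis(mean, sd, num=num, span=span)
        return cls.from_logpdf(
            (axis,), lambda t: -0.5 * ((t - mean) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))
        )

    @classmethod
    def point_mass(cls, value: float) -> "BeliefState":
        return cls(axes=(np.array([float(value)]),), log_density=np.zeros(1),
                   kind="grid", normalized=True)

    @classmethod
    def particles(cls, points: np.ndarray, log_weights: np.ndarray | None = None) -> "BeliefState":
        points = np.atleast_2d(np.asarray(points, float))
        if log_weights is None:
            log_weights = np.zeros(points.shape[0])
        return cls(axes=(points,), log_density=np.asarray(log_weights, float),
                   kind="particles").normalize()

    # -- summaries (1-D grid unless noted) -----------------------------------

    def _require_1d_grid(self):
        if self.kind != "grid" or len(self.axes) != 1:
            raise ValueError("operation requires a 1-D grid belief")

    def pdf(self) -> np.ndarray:
        return np.exp(self.log_density)

    def _masses(self) -> np.ndarray:
        """Per-point probability masses (quadrature weight × density)."""
        m = np.exp(self.log_density + self._log_quad_weights())
        return m / m.sum()

    def mean(self) -> np.ndarray:
        m = self._masses().ravel()
        return m @ self.points

    def var(self) -> np.ndarray:
        m = self._masses().ravel()
        pts = self.points
        mu = m @ pts
        return m @ (pts - mu) ** 2

    def mode(self) -> np.ndarray:
        idx = np.unravel_index(np.argmax(self.log_density), self.log_density.shape)
        if self.kind == "particles":
            return self.points[idx[0]]
        return np.array([a[i] for a, i in zip(self.axes, idx)])

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval from the grid CDF (1-D only)."""
        self._require_1d_grid()
        x = self.axes[0]
        m = self._masses()
        cdf = np.cumsum(m)
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        lo = float(np.interp(lo_q, cdf, x))
        hi = float(np.interp(hi_q, cdf, x))
        return lo, hi

    def marginal(self, axis: int) -> "BeliefState":
        """Marginal belief over one grid dimension (integrating out the rest)."""
        if self.kind != "grid":
            raise ValueError("marginals are defined for grid beliefs")
        keep = self.axes[axis]
        logw = np.zeros(self.log_density.shape)
        for k, a in enumerate(self.axes):
            if k == axis:
                continue
            w = _trapezoid_weights(a)
            shape = [1] * len(self.axes)
            shape[k] = a.size
            with np.errstate(divide="ignore"):
                logw = logw + np.log(w).reshape(shape)
        other = tuple(k for k in range(len(self.axes)) if k != axis)
        marg = logsumexp(self.log_density + logw, axis=other)
        return BeliefState(axes=(keep,), log_density=marg, kind="grid").normalize()

    def restrict(self, mask: np.ndarray) -> "BeliefState":
        """Condition on a subset of the support (grid: boolean mask per point).

        For 1-D grids the mask selects grid points; the restricted belief is
        renormalized on the surviving points.
        """
        self._require_1d_grid()
        mask = np.asarray(mask, bool)
        return BeliefState(axes=(self.axes[0][mask],),
                           log_density=self.log_density[mask], kind="grid").normalize()

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        pts = self.points
        cols = {f"theta_{k}": pts[:, k] for k in range(pts.shape[1])}
        cols["log_density"] = self.log_density.ravel()
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BeliefState":
        df = pd.read_csv(path, sep="\t")
        coord_cols = [c for c in df.columns if c.startswith("theta_")]
        if len(coord_cols) == 1:
            axis = df[coord_cols[0]].to_numpy()
            return cls(axes=(axis,), log_density=df["log_density"].to_numpy(),
                       kind="grid", normalized=False)
        # Reconstruct a rectangular grid from the stacked coordinates.
        axes = []
        for c in coord_cols:
            axes.append(np.unique(df[c].to_numpy()))
        shape = tuple(a.size for a in axes)
        ld = df["log_density"].to_numpy().reshape(shape)
        return cls(axes=tuple(axes), log_density=ld, kind="grid", normalized=False)
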