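"""Analytic model potentials over collective-variable space.

These play the role of the physical free-energy landscape for the
surrogate sampler: every potential exposes an energy (kcal/mol) and an
analytic gradient over 1D or 2D CV space, with optional periodic
dimensions and one-sided quartic confinement walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelPotential",
    "Harmonic",
    "DoubleWell1D",
    "GaussianComponent",
    "ArcGaussianComponent",
    "GaussianLandscape",
    "Restraint",
    "check_gradient",
]


class ModelPotential:
    """Base class: subclasses implement ``energy`` and ``gradient``.

    Both accept a point of shape ``(ndim,)`` or a batch ``(n, ndim)``.
    ``periods`` holds the period per dimension (``None`` = aperiodic).
    """

    ndim: int = 1
    periods: tuple = (None,)

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def _atleast2d(self, x):
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        return (x[None, :] if squeeze else x), squeeze

    def displacement(self, x: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Minimum-image displacement x − center, respecting periodic dims."""
        d = x - center
        for k, p in enumerate(self.periods):
            if p is not None:
                d[..., k] -= p * np.round(d[..., k] / p)
        return d


@dataclass
class Harmonic(ModelPotential):
    """Isotropic (or per-dimension) harmonic well ½ k (x − x0)²."""

    k: float | Sequence[float] = 1.0
    center: Sequence[float] = (0.0,)

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.ndim = self.center.size
        self.k_arr = np.broadcast_to(np.atleast_1d(np.asarray(self.k, float)), (self.ndim,))
        self.periods = (None,) * self.ndim

    def energy(self, x):
        xb, sq = self._atleast2d(x)
        e = 0.5 * (self.k_arr * (xb - self.center) ** 2).sum(axis=1)
        return e[0] if sq else e

    def gradient(self, x):
        xb, sq = self._atleast2d(x)
        g = self.k_arr * (xb - self.center)
        return g[0] if sq else g


@dataclass
class DoubleWell1D(ModelPotential):
    """Symmetric quartic double well: barrier ``b`` at 0, minima at ±a."""

    barrier: float = 5.0
    a: float = 1.0

    def __post_init__(self):
        self.ndim = 1
        self.periods = (None,)

    def energy(self, x):
        xb, sq = self._atleast2d(x)
        u = xb[:, 0]
        e = self.barrier * (u**2 - self.a**2) ** 2 / self.a**4
        return e[0] if sq else e

    def gradient(self, x):
        xb, sq = self._atleast2d(x)
        u = xb[:, 0]
        g = (4.0 * self.barrier / self.a**4) * u * (u**2 - self.a**2)
        g = g[:, None]
        return g[0] if sq else g


@dataclass
class GaussianComponent:
    """One (optionally rotated, anisotropic) Gaussian ``amp·exp(−½ dᵀM d)``."""

    amp: float
    center: np.ndarray
    sigma: np.ndarray  # principal-axis widths
    angle: float = 0.0  # rotation of principal axes (radians, 2D only)

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, float))
        d = self.center.size
        rot = np.eye(d)
        if d == 2 and self.angle != 0.0:
            c, s = np.cos(self.angle), np.sin(self.angle)
            rot = np.array([[c, -s], [s, c]])
        self.M = rot @ np.diag(1.0 / self.sigma**2) @ rot.T


@dataclass
class ArcGaussianComponent:
    """A Gaussian trough/ridge segment bent along a circular arc (2D).

    ``amp·exp(−(r−R)²/2σr² − Δθ²/2σθ²)`` in polar coordinates about
    ``origin``; Δθ is wrapped.  Because the component is radially
    symmetric about its arc, the gradient perpendicular to the arc
    vanishes on the circle — which is what lets a curved reaction
    channel carry exact stationary points.
    """

    amp: float
    origin: np.ndarray
    radius: float
    theta0: float  # arc azimuth of the component center (radians)
    sigma_r: float
    sigma_theta: float  # radians

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)

    def _polar(self, x):
        d = x - self.origin
        r = np.hypot(d[..., 0], d[..., 1])
        th = np.arctan2(d[..., 1], d[..., 0])
        dth = np.angle(np.exp(1j * (th - self.theta0)))
        return d, r, dth

    def energy(self, x):
        _, r, dth = self._polar(x)
        return self.amp * np.exp(
            -0.5 * ((r - self.radius) / self.sigma_r) ** 2
            - 0.5 * (dth / self.sigma_theta) ** 2
        )

    def gradient(self, x):
        d, r, dth = self._polar(x)
        v = self.energy(x)
        r_safe = np.where(r > 1e-12, r, 1e-12)
        u_r = d / r_safe[..., None]
        u_t = np.stack([-u_r[..., 1], u_r[..., 0]], axis=-1)
        dr = (r - self.radius) / self.sigma_r**2
        dt = dth / self.sigma_theta**2
        return -v[..., None] * (dr[..., None] * u_r + dt[..., None] * u_t / r_safe[..., None])


@dataclass
class GaussianLandscape(ModelPotential):
    """constant + quadratic bowl + quartic walls + a set of Gaussians.

    The workhorse for surrogate free-energy landscapes: wells are
    negative Gaussians, ridges/passes positive ones.
    """

    components: list = field(default_factory=list)
    const: float = 0.0
    bowl_k: float | Sequence[float] = 0.0
    bowl_center: Optional[Sequence[float]] = None
    walls: list = field(default_factory=list)  # (dim, lo, hi, k_wall)
    ndim: int = 2
    periods: tuple = ()

    def __post_init__(self):
        if not self.periods:
            self.periods = (None,) * self.ndim
        if self.bowl_center is not None:
            self.bowl_center = np.asarray(self.bowl_center, float)
        self.bowl_k_arr = np.broadcast_to(
            np.atleast_1d(np.asarray(self.bowl_k, float)), (self.ndim,)
        )

    def energy(self, x):
        xb, sq = self._atleast2d(x)
        e = np.full(xb.shape[0], self.const)
        if self.bowl_center is not None:
            d = self.displacement(xb, self.bowl_center)
            e += 0.5 * (self.bowl_k_arr * d**2).sum(axis=1)
        for g in self.components:
            if isinstance(g, ArcGaussianComponent):
                e += g.energy(xb)
                continue
            d = self.displacement(xb, g.center)
            e += g.amp * np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, g.M, d))
        for dim, lo, hi, kw in self.walls:
            u = xb[:, dim]
            if lo is not None:
                e += kw * np.clip(lo - u, 0.0, None) ** 4
            if hi is not None:
                e += kw * np.clip(u - hi, 0.0, None) ** 4
        return e[0] if sq else e

    def gradient(self, x):
        xb, sq = self._atleast2d(x)
        grad = np.zeros_like(xb)
        if self.bowl_center is not None:
            d = self.displacement(xb, self.bowl_center)
            grad += self.bowl_k_arr * d
        for g in self.components:
            if isinstance(g, ArcGaussianComponent):
                grad += g.gradient(xb)
                continue
            d = self.displacement(xb, g.center)
            md = d @ g.M.T
            w = g.amp * np.exp(-0.5 * np.einsum("ni,ni->n", d, md))
            grad += -w[:, None] * md
        for dim, lo, hi, kw in self.walls:
            u = xb[:, dim]
            if lo is not None:
                grad[:, dim] += -4.0 * kw * np.clip(lo - u, 0.0, None) ** 3
            if hi is not None:
                grad[:, dim] += 4.0 * kw * np.clip(u - hi, 0.0, None) ** 3
        return grad[0] if sq else grad

    def hessian(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Numerical Hessian (central differences on the analytic gradient)."""
        x = np.asarray(x, dtype=float)
        H = np.zeros((self.ndim, self.ndim))
        for k in range(self.ndim):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            H[:, k] = (self.gradient(xp) - self.gradient(xm)) / (2 * h)
        return 0.5 * (H + H.T)


@dataclass
class Restraint:
    """Harmonic umbrella restraint ½k(s·axis − center)² on one CV dimension."""

    k: float
    center: float
    dim: int = 0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.k * (x[..., self.dim] - self.center) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., self.dim] = self.k * (x[..., self.dim] - self.center)
        return g


def check_gradient(pot: ModelPotential, points: np.ndarray, h: float = 1e-6) -> float:
    """Max |analytic − finite-difference| gradient error over ``points``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    worst = 0.0
    for x in points:
        g = np.atleast_1d(pot.gradient(x))
        for k in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fd = (pot.energy(xp) - pot.energy(xm)) / (2 * h)
            worst = max(worst, abs(g[k] - fd))
    return worst
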