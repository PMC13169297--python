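"""Langevin dynamics and a well-tempered metadynamics engine.

The sampler propagates a fictitious particle directly in CV space on an
analytic model potential (a surrogate for ab initio forces) with a
BAOAB-discretised Langevin thermostat.  Metadynamics layers a history of
repulsive Gaussian hills on top; hill heights decay with the accumulated
bias according to the well-tempered rule h = h0·exp(−V_bias/ΔT), where
the well-tempered parameter ΔT carries energy units (kcal/mol).  The
equivalent bias factor γ = 1 + ΔT/(kB·T) is reported alongside.

Internal units: kcal/mol, ps, and a fictitious CV-space mass in
kcal/mol·ps²/(CV unit)² (default 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .errors import IntegrationError, PuckerPathError
from .potentials import ModelPotential

__all__ = [
    "Hill",
    "BiasState",
    "MetadParams",
    "deposit_hill",
    "run_langevin",
    "run_metadynamics",
    "reconstruct_fes",
    "count_basin_transitions",
]


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: center, per-dimension widths, height, step."""

    center: np.ndarray
    sigma: np.ndarray
    height: float
    step: int

    def __post_init__(self):
        if np.any(np.asarray(self.sigma) <= 0):
            raise PuckerPathError("hill widths must be > 0")
        if self.height <= 0:
            raise PuckerPathError("hill height must be > 0")


class BiasState:
    """Accumulated well-tempered bias: ordered hills + schedule metadata.

    Hills are stored in flat arrays so that bias energies and gradients
    are exact vectorised sums over the full history (no grids/splines);
    at desk-scale hill counts (≲10⁴) this is cheap.
    """

    def __init__(
        self,
        sigma: Sequence[float],
        delta_T: float,
        stride: int = 100,
        temperature: float = DEFAULT_TEMPERATURE,
        periods: Optional[Sequence[Optional[float]]] = None,
        dt: float = 0.005,
    ):
        self.sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise PuckerPathError("hill widths must be > 0")
        if delta_T <= 0:
            raise PuckerPathError("well-tempered parameter must be > 0")
        self.ndim = self.sigma.size
        self.delta_T = float(delta_T)  # kcal/mol
        self.stride = int(stride)
        self.temperature = float(temperature)
        self.dt = float(dt)
        self.periods = tuple(periods) if periods is not None else (None,) * self.ndim
        self._cap = 1024
        self._centers = np.empty((self._cap, self.ndim))
        self._heights = np.empty(self._cap)
        self._steps = np.empty(self._cap, dtype=np.int64)
        self.n_hills = 0
        # cache periodic bookkeeping for the hot loop
        self._pdims = [k for k, p in enumerate(self.periods) if p is not None]
        self._inv2s2 = 1.0 / (2.0 * self.sigma**2)

    # -- properties -------------------------------------------------------
    @property
    def bias_factor(self) -> float:
        """γ = (T + ΔT/kB)/T, the dimensionless well-tempered bias factor."""
        return 1.0 + self.delta_T / (KB * self.temperature)

    @property
    def hills(self) -> list[Hill]:
        return [
            Hill(self._centers[i].copy(), self.sigma.copy(), float(self._heights[i]),
                 int(self._steps[i]))
            for i in range(self.n_hills)
        ]

    @property
    def total_time(self) -> float:
        """Bookkeeping identity n_hills × stride × dt (ps)."""
        return self.n_hills * self.stride * self.dt

    # -- mutation ---------------------------------------------------------
    def _grow(self):
        self._cap *= 2
        self._centers = np.resize(self._centers, (self._cap, self.ndim))
        self._heights = np.resize(self._heights, self._cap)
        self._steps = np.resize(self._steps, self._cap)

    def add_hill(self, center: Sequence[float], height: float, step: int = 0) -> Hill:
        if height <= 0:
            raise PuckerPathError("hill height must be > 0")
        if self.n_hills == self._cap:
            self._grow()
        i = self.n_hills
        self._centers[i] = np.asarray(center, dtype=float)
        self._heights[i] = height
        self._steps[i] = step
        self.n_hills += 1
        return Hill(self._centers[i].copy(), self.sigma.copy(), float(height), int(step))

    # -- evaluation -------------------------------------------------------
    def _disp(self, x: np.ndarray) -> np.ndarray:
        d = self._centers[: self.n_hills] - x
        for k in self._pdims:
            p = self.periods[k]
            d[:, k] -= p * np.round(d[:, k] / p)
        return d

    def bias_energy(self, s: Sequence[float], weights: Optional[np.ndarray] = None) -> float:
        """Sum of Gaussian hills at point ``s`` (kcal/mol)."""
        if self.n_hills == 0:
            return 0.0
        d = self._disp(np.asarray(s, dtype=float))
        e = np.exp(-(d**2 * self._inv2s2).sum(axis=1))
        h = self._heights[: self.n_hills]
        if weights is not None:
            h = h * weights
        return float(np.dot(h, e))

    def bias_gradient(self, s: Sequence[float]) -> np.ndarray:
        if self.n_hills == 0:
            return np.zeros(self.ndim)
        d = self._disp(np.asarray(s, dtype=float))
        e = self._heights[: self.n_hills] * np.exp(-(d**2 * self._inv2s2).sum(axis=1))
        # dV/ds = Σ h·exp(...)·(d/σ²), d = center − s
        return (e[:, None] * d * (2.0 * self._inv2s2)).sum(axis=0)

    def bias_energy_grid(
        self, points: np.ndarray, weights: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Vectorised bias over many points, shape (npts, ndim) → (npts,)."""
        if self.n_hills == 0:
            return np.zeros(points.shape[0])
        h = self._heights[: self.n_hills]
        if weights is not None:
            h = h * weights
        out = np.zeros(points.shape[0])
        # chunk over hills to bound memory
        step = max(1, int(4e6 // max(points.shape[0], 1)))
        for i0 in range(0, self.n_hills, step):
            d = self._centers[i0 : min(i0 + step, self.n_hills), None, :] - points[None, :, :]
            for k in self._pdims:
                p = self.periods[k]
                d[:, :, k] -= p * np.round(d[:, :, k] / p)
            e = np.exp(-(d**2 * self._inv2s2).sum(axis=2))
            out += h[i0 : i0 + e.shape[0]] @ e
        return out


def deposit_hill(bias: BiasState, s: Sequence[float], h0: float, step: int = 0) -> Hill:
    """Deposit one well-tempered hill of nominal height ``h0`` at ``s``."""
    if h0 <= 0:
        raise PuckerPathError("h0 must be > 0")
    v = bias.bias_energy(s)
    return bias.add_hill(s, h0 * math.exp(-v / bias.delta_T), step)


@dataclass
class MetadParams:
    """Hill schedule + integrator settings for a metadynamics run."""

    sigma: Sequence[float]
    height: float  # h0, kcal/mol
    delta_T: float  # kcal/mol
    stride: int = 100
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0  # ps^-1
    dt: float = 0.005  # ps
    mass: float = 1.0
    x0: Sequence[float] = field(default_factory=lambda: (0.0,))


def _baoab_coeffs(friction, dt, temperature, mass):
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(KB * temperature * (1.0 - c1 * c1) / mass)
    return c1, c2


def run_langevin(
    pot: ModelPotential,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    dt: float = 0.005,
    n_steps: int = 1000,
    seed: int = 0,
    x0: Optional[Sequence[float]] = None,
    mass: float = 1.0,
    bias: Optional[BiasState] = None,
    restraint=None,
    save_stride: int = 1,
) -> np.ndarray:
    """BAOAB Langevin trajectory in CV space; bitwise reproducible per seed.

    Returns positions with shape (n_saved, ndim).  Raises
    :class:`IntegrationError` on energy overflow.
    """
    if dt <= 0 or n_steps < 1 or temperature < 0:
        raise PuckerPathError("need dt > 0, n_steps >= 1, temperature >= 0")
    rng = np.random.default_rng(seed)
    ndim = pot.ndim
    x = np.zeros(ndim) if x0 is None else np.asarray(x0, dtype=float).copy()
    v = rng.normal(0.0, math.sqrt(KB * temperature / mass) if temperature > 0 else 0.0, ndim)
    c1, c2 = _baoab_coeffs(friction, dt, temperature, mass)

    def force(p):
        f = -pot.gradient(p)
        if bias is not None and bias.n_hills:
            f = f - bias.bias_gradient(p)
        if restraint is not None:
            f = f - restraint.gradient(p)
        return f

    f = force(x)
    out = np.empty((n_steps // save_stride + 1, ndim))
    out[0] = x
    nsaved = 1
    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        v += half * f / mass
        x += half * v
        if temperature > 0:
            v = c1 * v + c2 * rng.standard_normal(ndim)
        else:
            v = c1 * v
        x += half * v
        f = force(x)
        v += half * f / mass
        if step % save_stride == 0:
            out[nsaved] = x
            nsaved += 1
        if step % 1000 == 0 or step == n_steps:
            if not np.all(np.isfinite(x)) or abs(pot.energy(x)) > 1e8:
                raise IntegrationError(
                    f"integration unstable at step {step} (dt={dt} ps too large?)"
                )
    return out[:nsaved]


def run_metadynamics(
    pot: ModelPotential,
    params: MetadParams,
    n_hills: int,
    seed: int = 0,
) -> tuple[np.ndarray, BiasState]:
    """Well-tempered metadynamics: Langevin propagation with hill deposition.

    One hill every ``params.stride`` steps (first deposit at the starting
    point), n_hills total.  Returns the CV positions at every hill
    deposition plus the full hill history.
    """
    if n_hills < 1:
        raise PuckerPathError("n_hills must be >= 1")
    rng = np.random.default_rng(seed)
    bias = BiasState(
        params.sigma,
        params.delta_T,
        stride=params.stride,
        temperature=params.temperature,
        periods=pot.periods,
        dt=params.dt,
    )
    ndim = pot.ndim
    x = np.asarray(params.x0, dtype=float).copy()
    mass = params.mass
    v = rng.normal(0.0, math.sqrt(KB * params.temperature / mass), ndim)
    c1, c2 = _baoab_coeffs(params.friction, params.dt, params.temperature, mass)
    half = 0.5 * params.dt
    traj = np.empty((n_hills, ndim))

    f = -pot.gradient(x)
    for h in range(n_hills):
        deposit_hill(bias, x, params.height, step=h * params.stride)
        traj[h] = x
        for _ in range(params.stride):
            v += half * f / mass
            x += half * v
            v = c1 * v + c2 * rng.standard_normal(ndim)
            x += half * v
            f = -pot.gradient(x) - bias.bias_gradient(x)
            v += half * f / mass
        if not np.all(np.isfinite(x)) or abs(pot.energy(x)) > 1e8:
            raise IntegrationError(
                f"metadynamics unstable after hill {h + 1} (dt={params.dt} ps too large?)"
            )
    return traj, bias


def reconstruct_fes(bias: BiasState, grid_spec, average_from: Optional[float] = None):
    """Free-energy surface estimate F(s) = −(kB·T + ΔT)/ΔT · V_bias(s).

    ``grid_spec`` is a sequence of (lo, hi, n) per dimension (or a
    :class:`~puckerpath.fes.FESGrid` axes spec).  With ``average_from``
    in (0, 1), the estimate is the time average of the instantaneous FES
    over the last (1 − average_from) fraction of hill depositions, which
    damps hill-granularity ripple; the average over checkpoints reduces
    to a single weighted hill sum.  Result is anchored to min F = 0.
    """
    from .fes import FESGrid

    if bias.n_hills == 0:
        raise PuckerPathError("cannot reconstruct an FES from an empty bias")
    axes = [np.linspace(lo, hi, int(n)) for lo, hi, n in grid_spec]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    weights = None
    if average_from is not None:
        n = bias.n_hills
        n0 = max(1, int(math.floor(average_from * n)))
        # hill i (1-based) contributes to checkpoints m >= max(i, n0)
        i = np.arange(1, n + 1)
        weights = np.clip((n - np.maximum(i, n0) + 1) / (n - n0 + 1), 0.0, 1.0)
    v = bias.bias_energy_grid(pts, weights=weights)
    scale = (KB * bias.temperature + bias.delta_T) / bias.delta_T
    f = (-scale * v).reshape([len(a) for a in axes])
    periodic = tuple(p is not None for p in bias.periods)
    return FESGrid(axes=tuple(axes), values=f - f.min(), periodic=periodic)


def count_basin_transitions(series: np.ndarray, basins: dict) -> int:
    """Completed transitions between labeled basins along a CV series.

    ``basins`` maps label → (lo, hi) per-dimension bounds.  A hysteresis
    rule applies: the walker must fully enter a basin box for it to
    count; grazing the region between basins changes nothing.  Boxes
    must be pairwise disjoint.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    labels = list(basins)
    if len(labels) < 2:
        raise PuckerPathError("need at least 2 basins")
    boxes = {}
    for lab in labels:
        lo, hi = basins[lab]
        lo = np.atleast_1d(np.asarray(lo, dtype=float))
        hi = np.atleast_1d(np.asarray(hi, dtype=float))
        if np.any(hi <= lo):
            raise PuckerPathError(f"basin {lab!r} has empty extent")
        boxes[lab] = (lo, hi)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            la, ha = boxes[a]
            lb, hb = boxes[b]
            if np.all(np.maximum(la, lb) < np.minimum(ha, hb)):
                raise PuckerPathError(f"basins {a!r} and {b!r} overlap")
    current = None
    n = 0
    for x in series:
        for lab, (lo, hi) in boxes.items():
            if np.all(x >= lo) and np.all(x <= hi):
                if current is not None and lab != current:
                    n += 1
                current = lab
                break
    return n
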