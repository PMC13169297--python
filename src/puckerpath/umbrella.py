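"""Umbrella-sampling window placement, biased sampling, and WHAM.

Windows restrain the reaction coordinate with a harmonic spring; the
weighted histogram analysis method stitches the biased histograms into a
potential of mean force.  The default force constant follows the
standard design rule k = kB·T/(spacing/2)², which makes the restrained
standard deviation about half the window spacing at 300 K and so
guarantees histogram overlap between neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .errors import ConvergenceError, OverlapError, PuckerPathError
from .potentials import ModelPotential, Restraint
from .sampler import run_langevin

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "default_force_constant",
    "make_windows",
    "sample_window",
    "wham_solve",
    "overlap_report",
    "histogram_overlap",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic restraint + (optionally) its samples."""

    center: float
    k: float  # kcal/mol/Å²
    samples: Optional[np.ndarray] = None
    equilibration_fraction: float = 1.0 / 3.0

    def __post_init__(self):
        if self.k <= 0:
            raise PuckerPathError("force constant must be > 0")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise PuckerPathError("equilibration fraction must be in [0, 1)")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def retained(self) -> np.ndarray:
        """Samples after discarding the equilibration fraction."""
        if self.samples is None:
            raise PuckerPathError("window has not been sampled")
        n0 = int(np.floor(self.equilibration_fraction * self.samples.size))
        return self.samples[n0:]


def default_force_constant(spacing: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k = kB·T/(spacing/2)² — restrained σ ≈ spacing/2."""
    return KB * temperature / (0.5 * spacing) ** 2


def make_windows(
    start: float,
    stop: float,
    spacing: float,
    k: Optional[float] = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[UmbrellaWindow]:
    """Inclusive, evenly spaced window centers from ``start`` to ``stop``."""
    if spacing <= 0:
        raise PuckerPathError("spacing must be > 0")
    if stop <= start:
        raise PuckerPathError("stop must exceed start")
    n = int(round((stop - start) / spacing)) + 1
    if k is None:
        k = default_force_constant(spacing, temperature)
    return [UmbrellaWindow(center=start + i * spacing, k=k) for i in range(n)]


def sample_window(
    pot: ModelPotential,
    w: UmbrellaWindow,
    n_steps: int = 20000,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    dt: float = 0.005,
    mass: float = 1.0,
) -> UmbrellaWindow:
    """Langevin sampling of pot + ½k(s − center)²; stores the CV series.

    The first ``equilibration_fraction`` of the run (default one third,
    mirroring a 2.5/7.5 ps protocol) is discarded downstream via
    :attr:`UmbrellaWindow.retained`.
    """
    restr = Restraint(k=w.k, center=w.center, dim=0)
    traj = run_langevin(
        pot,
        temperature=temperature,
        friction=friction,
        dt=dt,
        n_steps=n_steps,
        seed=seed,
        x0=[w.center] + [0.0] * (pot.ndim - 1),
        mass=mass,
        restraint=restr,
    )
    w.samples = traj[:, 0].copy()
    return w


@dataclass
class PMFProfile:
    """WHAM result: anchored PMF, bin populations, window constants."""

    bin_centers: np.ndarray
    free_energy: np.ndarray  # kcal/mol, min = 0
    counts: np.ndarray
    window_f: np.ndarray  # per-window free-energy constants (kcal/mol)
    n_iterations: int = 0
    residual: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        finite = np.isfinite(self.free_energy)
        if finite.any():
            self.free_energy = self.free_energy - np.nanmin(self.free_energy[finite])

    @property
    def barrier(self) -> float:
        """max − min of the PMF over bins with samples."""
        finite = np.isfinite(self.free_energy)
        return float(self.free_energy[finite].max())


def histogram_overlap(a: np.ndarray, b: np.ndarray, n_bins: int = 50) -> float:
    """Overlap coefficient Σ min(p, q) of two sample sets on shared bins."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=False)
    pb, _ = np.histogram(b, bins=edges, density=False)
    return float(np.minimum(pa / a.size, pb / b.size).sum())


def overlap_report(windows: Sequence[UmbrellaWindow], n_bins: int = 50) -> np.ndarray:
    """Histogram overlap coefficient for each adjacent window pair."""
    if len(windows) < 2:
        raise PuckerPathError("need at least 2 windows")
    return np.array(
        [
            histogram_overlap(windows[i].retained, windows[i + 1].retained, n_bins)
            for i in range(len(windows) - 1)
        ]
    )


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    n_bins: int = 101,
    tol: float = 1e-8,
    max_iter: int = 100000,
    overlap_floor: float = 0.01,
    f_init: Optional[np.ndarray] = None,
) -> PMFProfile:
    """Self-consistent WHAM over the retained samples of all windows.

    Direct iteration of the WHAM equations until the window constants
    move by less than ``tol`` (kcal/mol).  Adjacent windows must share
    histogram support (overlap coefficient above ``overlap_floor``).
    """
    if len(windows) < 1:
        raise PuckerPathError("need at least one window")
    kbt = KB * temperature
    samples = [w.retained for w in windows]
    if len(windows) >= 2:
        ov = overlap_report(windows)
        bad = np.where(ov < overlap_floor)[0]
        if bad.size:
            i = int(bad[0])
            raise OverlapError(
                f"no histogram overlap between windows {i} (center {windows[i].center}) "
                f"and {i + 1} (center {windows[i + 1].center}): coefficient {ov[i]:.4f}"
            )
    allx = np.concatenate(samples)
    edges = np.linspace(allx.min(), allx.max() + 1e-12, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ib = np.array([np.histogram(s, bins=edges)[0] for s in samples], dtype=float)
    N_i = n_ib.sum(axis=1)
    n_b = n_ib.sum(axis=0)
    # bias energies of every window at every bin center
    w_ib = np.array([0.5 * w.k * (centers - w.center) ** 2 for w in windows])
    exp_w = np.exp(-w_ib / kbt)
    f = np.zeros(len(windows)) if f_init is None else np.asarray(f_init, dtype=float).copy()
    resid = np.inf
    for it in range(1, max_iter + 1):
        denom = (N_i[:, None] * np.exp(f[:, None] / kbt) * exp_w).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_b / denom, 0.0)
        z = exp_w @ p
        f_new = -kbt * np.log(np.where(z > 0, z, np.nan))
        f_new -= f_new[0]
        resid = float(np.nanmax(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise ConvergenceError(f"WHAM did not converge: residual {resid:.3e} after {max_iter}")
    with np.errstate(divide="ignore"):
        pmf = np.where(p > 0, -kbt * np.log(np.where(p > 0, p, 1.0)), np.inf)
    pmf = np.where(n_b > 0, pmf, np.inf)
    return PMFProfile(
        bin_centers=centers,
        free_energy=pmf,
        counts=n_b,
        window_f=f,
        n_iterations=it,
        residual=resid,
        temperature=temperature,
    )
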