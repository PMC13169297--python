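"""Synthetic fixtures: ideal ring geometries, pucker trajectories, and
surrogate free-energy landscapes.

The surrogate landscapes are analytic sums of (anisotropic) Gaussians
whose stationary points are placed at the reported layout of the
β-elimination reaction surface — Michaelis complex at (−1.0, 1.1) Å
with F = 0, transition state at (0.7, 0.3) Å with F = 19, intermediate
complex at (1.8, 1.7) Å with F = −1, product complex at (1.8, 3.4) Å
with F = −5 kcal/mol — and of the conformational (φ, θ) surface, with
minima at 1C4 (0), 5S1 (+0.5) and OS2 (+2.0).  A hand-built layout is
refined by solving the stationarity system (target values, zero
gradients) with a deterministic least-squares root solve, and every
landscape passes a build-time audit (gradient, Hessian signature,
value, dense-grid minimum scan) before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares

from .constants import AMPLITUDE_FLOOR, BOND_CC, BOND_CO
from .cv import eval_cv1, eval_cv2
from .errors import PuckerPathError
from .potentials import ArcGaussianComponent, GaussianComponent, GaussianLandscape
from .ring import (
    ConformerLabel,
    RingGeometry,
    compute_cremer_pople,
    get_conformer,
    z_from_cp,
)

__all__ = [
    "SurrogateLandscape",
    "ideal_conformer_geometry",
    "geometry_from_cp",
    "pucker_trajectory",
    "reaction_pucker_series",
    "build_surrogate_reaction_landscape",
    "build_surrogate_pucker_landscape",
    "build_surrogate_pmf_1d",
    "reaction_distance_series",
    "audit_stationary_points",
]


# ---------------------------------------------------------------------------
# ring geometry generation (inverse Cremer–Pople)
# ---------------------------------------------------------------------------

_BOND_TARGETS = np.array([BOND_CO, BOND_CC, BOND_CC, BOND_CC, BOND_CC, BOND_CO])
_BETA = -2.0 * np.pi * np.arange(6) / 6.0  # clockwise placement → mean-plane normal +z


def geometry_from_cp(Q: float, theta: float, phi: float) -> RingGeometry:
    """Build a six-membered ring with exactly the requested (Q, θ, φ).

    The out-of-plane pattern is fixed by the forward Cremer–Pople map;
    in-plane polar radii are then relaxed (least squares) toward ideal
    C–C/C–O bond lengths, which leaves the puckering coordinates exactly
    invariant because the radii do not enter the mean-plane definition.
    """
    q2 = Q * math.sin(math.radians(theta))
    q3 = Q * math.cos(math.radians(theta))
    z = z_from_cp(q2, phi, q3)

    def residual(r):
        xy = np.column_stack([r * np.cos(_BETA), r * np.sin(_BETA)])
        pos = np.column_stack([xy, z])
        d = np.linalg.norm(pos - np.roll(pos, -1, axis=0), axis=1)
        return d - _BOND_TARGETS

    sol = least_squares(residual, x0=np.full(6, 1.48), method="lm")
    r = sol.x
    coords = np.column_stack([r * np.cos(_BETA), r * np.sin(_BETA), z])
    geom = RingGeometry(coords)
    p = compute_cremer_pople(geom)
    if abs(p.Q - Q) > 1e-6:
        raise PuckerPathError(f"inverse CP construction failed: Q {p.Q} != {Q}")
    return geom


def ideal_conformer_geometry(label: ConformerLabel | str, Q: float = 0.57) -> RingGeometry:
    """Ideal ring geometry of a canonical conformer at amplitude ``Q`` (Å)."""
    if not AMPLITUDE_FLOOR < Q < 1.0:
        raise PuckerPathError(f"Q must lie in ({AMPLITUDE_FLOOR}, 1.0) Å, got {Q}")
    c = label if isinstance(label, ConformerLabel) else get_conformer(label)
    return geometry_from_cp(Q, c.canonical_theta, c.canonical_phi)


def _unit(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])


def _angles(u: np.ndarray) -> tuple[float, float]:
    theta = math.degrees(math.acos(np.clip(u[2], -1.0, 1.0)))
    phi = math.degrees(math.atan2(u[1], u[0])) % 360.0
    return theta, phi


def _slerp(u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return u.copy()
    return (math.sin((1 - t) * omega) * u + math.sin(t * omega) * v) / math.sin(omega)


def pucker_trajectory(
    a: ConformerLabel | str,
    b: ConformerLabel | str,
    n_frames: int,
    noise: float = 0.0,
    seed: int = 0,
    Q: float = 0.57,
) -> list[RingGeometry]:
    """Great-circle (slerp) interpolation between two conformers on the CP
    sphere at fixed Q, with optional Gaussian angular noise (degrees).

    Endpoints are exact (noise-free), so they classify back to ``a`` and
    ``b``; the whole series is seed-deterministic.
    """
    if n_frames < 2:
        raise PuckerPathError("need at least 2 frames")
    ca = a if isinstance(a, ConformerLabel) else get_conformer(a)
    cb = b if isinstance(b, ConformerLabel) else get_conformer(b)
    rng = np.random.default_rng(seed)
    u = _unit(ca.canonical_theta, ca.canonical_phi)
    v = _unit(cb.canonical_theta, cb.canonical_phi)
    geoms = []
    for i in range(n_frames):
        t = i / (n_frames - 1)
        w = _slerp(u, v, t)
        if noise > 0 and 0 < i < n_frames - 1:
            w = w + rng.normal(0.0, math.radians(noise), 3)
            w = w / np.linalg.norm(w)
        theta, phi = _angles(w)
        geoms.append(geometry_from_cp(Q, theta, phi))
    return geoms


def reaction_pucker_series(
    n_frames: int = 41,
    noise: float = 1.0,
    seed: int = 0,
    hold_fraction: float = 0.45,
) -> tuple[list[RingGeometry], dict]:
    """Ring-geometry series emulating the catalytic itinerary 1C4→1C4→1H2.

    The ring holds the 1C4 chair from the Michaelis complex through the
    transition state (the conformational change follows the chemistry)
    and then moves along the CP geodesic to the 1H2 product half-chair.
    Returns (geometries, stage markers MC/TS/PC as frame indices).
    """
    if n_frames < 5:
        raise PuckerPathError("need at least 5 frames")
    i_ts = int(round(hold_fraction * (n_frames - 1)))
    hold = pucker_trajectory("1C4", "1C4", i_ts + 1, noise=noise, seed=seed)
    move = pucker_trajectory("1C4", "1H2", n_frames - i_ts, noise=noise, seed=seed + 1)
    geoms = hold + move[1:]
    markers = {"MC": 0, "TS": i_ts, "PC": n_frames - 1}
    return geoms, markers


# ---------------------------------------------------------------------------
# surrogate landscapes
# ---------------------------------------------------------------------------


@dataclass
class SurrogateLandscape:
    """An analytic model landscape plus its constructed stationary points."""

    potential: GaussianLandscape
    stationary: dict  # name -> (coords array, F kcal/mol)
    domain: tuple  # ((lo, hi), ...) per dimension
    periodic: tuple = ()

    def __post_init__(self):
        if not self.periodic:
            self.periodic = (None,) * self.potential.ndim

    def grid_spec(self, n: int = 101):
        return [(lo, hi, n) for lo, hi in self.domain]

    def energy(self, x):
        return self.potential.energy(x)

    def gradient(self, x):
        return self.potential.gradient(x)

    def fes_grid(self, n: int = 101):
        from .fes import FESGrid

        return FESGrid.from_function(
            self.potential,
            self.grid_spec(n),
            periodic=tuple(p is not None for p in self.periodic),
        )

    def relative_energies(self, reference: str) -> dict:
        f0 = self.stationary[reference][1]
        return {k: v - f0 for k, (_, v) in self.stationary.items()}


def audit_stationary_points(
    sl: SurrogateLandscape,
    value_tol: float = 0.1,
    grad_tol: float = 1e-5,
    grid_n: int = 151,
    band_minima: frozenset = frozenset(),
) -> None:
    """Independent audit of a surrogate landscape; raises on failure.

    Checks, for every constructed stationary point: zero analytic
    gradient, value within ``value_tol`` of the declared free energy,
    correct Hessian signature (minima positive definite, saddles index
    1), and — via a dense-grid scan — that no grid value within one cell
    of a declared minimum undercuts it.  Names in ``band_minima`` are
    degenerate line minima (e.g. chair bands on the Mercator plane):
    their flat direction is exempt from the curvature check.
    """
    pot = sl.potential
    axes = [np.linspace(lo, hi, grid_n) for lo, hi in sl.domain]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = pot.energy(pts).reshape([grid_n] * pot.ndim)
    for name, (xs, f_target) in sl.stationary.items():
        xs = np.asarray(xs, dtype=float)
        g = np.linalg.norm(np.atleast_1d(pot.gradient(xs)))
        if g > grad_tol:
            raise PuckerPathError(f"{name}: |grad| = {g:.2e} > {grad_tol}")
        f = float(pot.energy(xs))
        if abs(f - f_target) > value_tol:
            raise PuckerPathError(f"{name}: F = {f:.3f}, expected {f_target}")
        H = pot.hessian(xs)
        ev = np.linalg.eigvalsh(H)
        if name.upper().startswith("TS"):
            if not (ev[0] < 0 < ev[-1]):
                raise PuckerPathError(f"{name}: not an index-1 saddle, eigs {ev}")
            continue
        if name in band_minima:
            if not (ev[-1] > 0 and ev[0] > -1e-3):
                raise PuckerPathError(f"{name}: not a band minimum, eigs {ev}")
        elif not np.all(ev > 0):
            raise PuckerPathError(f"{name}: not a minimum, eigs {ev}")
        # dense-grid check: nothing lower within one cell of the declared point
        idx = tuple(int(np.argmin(np.abs(axes[k] - xs[k]))) for k in range(pot.ndim))
        region = tuple(slice(max(0, i - 1), min(grid_n, i + 2)) for i in idx)
        if vals[region].min() < f - 1e-3:
            raise PuckerPathError(f"{name}: grid scan found lower value nearby")


# -- reaction landscape -----------------------------------------------------

_RXN_TARGETS = {
    "MC": (np.array([-1.0, 1.1]), 0.0),
    "TS": (np.array([0.7, 0.3]), 19.0),
    "IC": (np.array([1.8, 1.7]), -1.0),
    "PC": (np.array([1.8, 3.4]), -5.0),
}


def _circumcenter(a, b, c):
    (ax, ay), (bx, by), (cx, cy) = a, b, c
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return np.array([ux, uy])


# reaction channel geometry: MC, TS and IC are concyclic by construction,
# so the MC→TS→IC trough can be carved as arc Gaussians on their
# circumcircle — the perpendicular gradient then vanishes on the channel
# and the bend carries an exact saddle.
_ARC_O = _circumcenter(_RXN_TARGETS["MC"][0], _RXN_TARGETS["TS"][0], _RXN_TARGETS["IC"][0])
_ARC_R = float(np.linalg.norm(_RXN_TARGETS["TS"][0] - _ARC_O))
_TH = {
    k: math.atan2(_RXN_TARGETS[k][0][1] - _ARC_O[1], _RXN_TARGETS[k][0][0] - _ARC_O[0])
    for k in ("MC", "TS", "IC")
}


def _rxn_landscape(params: np.ndarray) -> GaussianLandscape:
    a_mc, a_ic, a_pc, arc1, arc2, r_g = params[:6]
    mc = params[6:8]
    ic = params[8:10]
    pc = params[10:12]
    comps = [
        GaussianComponent(a_mc, mc, (0.42, 0.42)),
        GaussianComponent(a_ic, ic, (0.45, 0.45)),
        GaussianComponent(a_pc, pc, (0.45, 0.45)),
        ArcGaussianComponent(arc1, _ARC_O, r_g, 0.5 * (_TH["MC"] + _TH["TS"]), 0.40, 0.60),
        ArcGaussianComponent(arc2, _ARC_O, r_g, 0.5 * (_TH["TS"] + _TH["IC"]), 0.40, 0.42),
        GaussianComponent(-20.0, (1.8, 2.55), (0.36, 0.65), angle=math.pi / 2),
    ]
    return GaussianLandscape(
        components=comps,
        const=26.0,
        bowl_k=3.0,
        bowl_center=tuple(_ARC_O),
        ndim=2,
    )


@lru_cache(maxsize=1)
def _solve_rxn_params() -> np.ndarray:
    mc, ic, pc = (_RXN_TARGETS[k][0] for k in ("MC", "IC", "PC"))
    x0 = np.concatenate([[-25.0, -22.0, -36.0, -14.0, -14.0, _ARC_R + 0.06], mc, ic, pc])
    lo = np.concatenate([[-45, -45, -45, -25, -25, _ARC_R - 0.3], mc - 0.35, ic - 0.35, pc - 0.35])
    hi = np.concatenate([[-10, -10, -10, -5, -5, _ARC_R + 0.4], mc + 0.35, ic + 0.35, pc + 0.35])

    def residual(p):
        pot = _rxn_landscape(p)
        res = []
        for name, (xs, f_t) in _RXN_TARGETS.items():
            res.append(pot.energy(xs) - f_t)
            res.extend(pot.gradient(xs))
        return np.array(res)

    sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.abs(sol.fun).max() > 1e-6:
        raise PuckerPathError(
            f"reaction-landscape construction failed: residual {np.abs(sol.fun).max():.2e}"
        )
    return sol.x


@lru_cache(maxsize=1)
def build_surrogate_reaction_landscape() -> SurrogateLandscape:
    """2D surrogate of the β-elimination free-energy surface over (CV1, CV2).

    Stationary points: MC (−1.0, 1.1)/0, TS (0.7, 0.3)/19, IC (1.8,
    1.7)/−1, PC (1.8, 3.4)/−5 kcal/mol.  Audited at build time.
    """
    pot = _rxn_landscape(_solve_rxn_params())
    sl = SurrogateLandscape(
        potential=pot,
        stationary={k: (v[0].copy(), v[1]) for k, v in _RXN_TARGETS.items()},
        domain=((-2.2, 3.2), (-0.8, 4.8)),
    )
    audit_stationary_points(sl)
    return sl


# -- conformational (pucker) landscape --------------------------------------


class _BandedLandscape(GaussianLandscape):
    """Gaussian landscape plus φ-independent Gaussian bands in θ (dim 1).

    Used for chair basins, which are points on the CP sphere but lines on
    the (φ, θ) Mercator plane.
    """

    def __init__(self, bands, **kw):
        super().__init__(**kw)
        self.bands = bands  # list of (amp, theta0, sigma)

    def energy(self, x):
        e = super().energy(x)
        xb, sq = self._atleast2d(x)
        extra = np.zeros(xb.shape[0])
        for amp, t0, s in self.bands:
            extra += amp * np.exp(-0.5 * ((xb[:, 1] - t0) / s) ** 2)
        return e + (extra[0] if sq else extra)

    def gradient(self, x):
        g = super().gradient(x)
        xb, sq = self._atleast2d(x)
        extra = np.zeros_like(xb)
        for amp, t0, s in self.bands:
            d = (xb[:, 1] - t0) / s**2
            extra[:, 1] += -amp * np.exp(-0.5 * ((xb[:, 1] - t0) / s) ** 2) * d
        return g + (extra[0] if sq else extra)


_S1 = get_conformer("5S1")
_OS2 = get_conformer("OS2")
#: (φ, θ) in radians of the pucker-surrogate minima
_PUCKER_POINTS = {
    "1C4": np.array([math.pi, math.pi]),  # θ = π band; φ representative only
    "5S1": np.radians([_S1.canonical_phi, _S1.canonical_theta]),
    "OS2": np.radians([_OS2.canonical_phi, _OS2.canonical_theta]),
}
_PUCKER_F = {"1C4": 0.0, "5S1": 0.5, "OS2": 2.0}


def _pucker_landscape(params: np.ndarray) -> _BandedLandscape:
    a_band, a_s1, a_os2, t_band = params[:4]
    s1 = params[4:6]
    os2 = params[6:8]
    comps = [
        GaussianComponent(a_s1, s1, (0.50, 0.38)),
        GaussianComponent(a_os2, os2, (0.50, 0.38)),
    ]
    return _BandedLandscape(
        bands=[(a_band, t_band, 0.38)],
        components=comps,
        const=4.5,
        ndim=2,
        periods=(2.0 * math.pi, None),
        walls=[(1, 0.85, math.pi + 0.35, 60.0)],
    )


@lru_cache(maxsize=1)
def _solve_pucker_params() -> np.ndarray:
    x0 = np.array(
        [-4.5, -4.0, -2.5, math.pi,
         _PUCKER_POINTS["5S1"][0], _PUCKER_POINTS["5S1"][1],
         _PUCKER_POINTS["OS2"][0], _PUCKER_POINTS["OS2"][1]]
    )

    def residual(p):
        pot = _pucker_landscape(p)
        res = []
        for name in ("1C4", "5S1", "OS2"):
            xs = _PUCKER_POINTS[name]
            res.append(pot.energy(xs) - _PUCKER_F[name])
            g = pot.gradient(xs)
            if name == "1C4":
                res.append(g[1])  # band: θ stationarity only (flat in φ)
            else:
                res.extend(g)
        return np.array(res)

    sol = least_squares(residual, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if np.abs(sol.fun).max() > 1e-6:
        raise PuckerPathError(
            f"pucker-landscape construction failed: residual {np.abs(sol.fun).max():.2e}"
        )
    return sol.x


@lru_cache(maxsize=1)
def build_surrogate_pucker_landscape() -> SurrogateLandscape:
    """Periodic (φ, θ) surrogate of the conformational free-energy surface.

    Radians; φ periodic.  Minima: the 1C4 chair band at θ = π (0), the
    5S1 twist-boat (+0.5) and the OS2 twist-boat (+2.0 kcal/mol), per
    the reported conformational landscape of the +1 GlcA sugar.
    """
    pot = _pucker_landscape(_solve_pucker_params())
    sl = SurrogateLandscape(
        potential=pot,
        stationary={k: (_PUCKER_POINTS[k].copy(), _PUCKER_F[k]) for k in _PUCKER_POINTS},
        domain=((0.0, 2.0 * math.pi), (0.95, math.pi + 0.1)),
        periodic=(2.0 * math.pi, None),
    )
    audit_stationary_points(sl, grad_tol=5e-4, band_minima=frozenset({"1C4"}))
    return sl


# -- 1D PMF surrogate for umbrella sampling ---------------------------------


@lru_cache(maxsize=4)
def build_surrogate_pmf_1d(barrier: float = 17.7) -> SurrogateLandscape:
    """1D free-energy profile along CV1 with exactly the given barrier.

    A broad Gaussian transition ridge at CV1 ≈ 0.8 Å over a left
    confinement wall near the Michaelis minimum; the ridge amplitude is
    calibrated (Brent root find on a dense grid) so max − min equals
    ``barrier`` exactly.
    """
    grid = np.linspace(-1.4, 1.8, 2001)

    def make(amp):
        return GaussianLandscape(
            components=[GaussianComponent(amp, (0.8,), (1.0,))],
            const=0.0,
            ndim=1,
            walls=[(0, -0.75, None, 200.0)],
        )

    def forward(amp):
        """(i_min, i_max, barrier): forward barrier seen from the minimum,
        ignoring the confinement wall to its left."""
        v = make(amp).energy(grid[:, None])
        i_min = int(np.argmin(v))
        i_max = i_min + int(np.argmax(v[i_min:]))
        return i_min, i_max, float(v[i_max] - v[i_min])

    amp = brentq(lambda a: forward(a)[2] - barrier, 0.5 * barrier, 2.5 * barrier, xtol=1e-12)
    pot = make(amp)
    v = pot.energy(grid[:, None])
    i_min, i_max, _ = forward(amp)
    sl = SurrogateLandscape(
        potential=pot,
        stationary={
            "MIN": (np.array([grid[i_min]]), float(v[i_min])),
            "TS": (np.array([grid[i_max]]), float(v[i_max])),
        },
        domain=((-1.4, 1.8),),
    )
    return sl


# ---------------------------------------------------------------------------
# reaction distance fixture
# ---------------------------------------------------------------------------

#: stage anchors (Å) at MC, TS, IC, PC — chosen so that the CVs land on the
#: reported stationary-point coordinates while the bond-forming/breaking
#: distances follow the reported evolution (C5–C6: 1.54 → 1.45 → single
#: bond again; C4–C5: 1.50 single → 1.37 double).
_STAGE_S = np.array([0.0, 0.4, 0.7, 1.0])
_STAGE_NAMES = ("MC", "TS", "IC", "PC")
_DIST_ANCHORS = {
    "d1": [1.10, 1.80, 2.85, 3.70],
    "d2": [2.10, 1.13, 1.05, 1.90],
    "d3": [2.45, 2.30, 2.35, 0.98],
    "d4": [1.45, 1.47, 3.00, 2.48],
    "dC5C6": [1.54, 1.45, 1.52, 1.52],
    "dC4C5": [1.50, 1.43, 1.37, 1.37],
}


def reaction_distance_series(n_frames: int = 201, seed: int = 0, noise: float = 0.01):
    """Frames of active-site distances + CVs along the reaction pathway.

    Distances interpolate the stage anchors with monotone cubics
    (PCHIP); Gaussian noise of σ = ``noise`` Å is added everywhere except
    at the four stage frames, which stay exact.  CV1/CV2 columns are
    computed from the (noisy) distance columns, so they are internally
    consistent by construction.  Returns a DataFrame with a ``stage``
    column marking the MC/TS/IC/PC rows.
    """
    import pandas as pd

    if n_frames < 3:
        raise PuckerPathError("need at least 3 frames")
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_frames)
    stage_idx = [int(np.argmin(np.abs(s - f))) for f in _STAGE_S]
    data = {"s": s}
    for name, anchors in _DIST_ANCHORS.items():
        vals = PchipInterpolator(_STAGE_S, anchors)(s)
        if noise > 0:
            jitter = rng.normal(0.0, noise, n_frames)
            jitter[stage_idx] = 0.0
            vals = vals + jitter
        data[name] = vals
    df = pd.DataFrame(data)
    df["cv1"] = [eval_cv1(r) for r in df[["d1", "d2"]].to_dict("records")]
    df["cv2"] = [eval_cv2(r) for r in df[["d2", "d3", "d4"]].to_dict("records")]
    stage = np.array([""] * n_frames, dtype=object)
    for name, i in zip(_STAGE_NAMES, stage_idx):
        stage[i] = name
    df["stage"] = stage
    df.insert(0, "frame", np.arange(1, n_frames + 1))
    return df
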