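"""Cremer–Pople puckering analysis of six-membered (pyranose) rings.

The ring is taken in the order O5 → C1 → C2 → C3 → C4 → C5, with O5 as
atom 1 of the Cremer–Pople construction.  In this convention the ``4C1``
chair sits at the north pole (θ = 0°) and ``1C4`` at the south pole
(θ = 180°); boats and skew-boats lie on the equator.

Canonical conformer positions are not tabulated ad hoc: each of the 38
canonical pyranose conformers has an ideal out-of-plane displacement
pattern (alternating for chairs, a para pair for boats, a single atom
for envelopes, an adjacent up/down pair for half-chairs, and the pure
q2-mode phases for skew-boats).  Pushing those patterns through the
Cremer–Pople Fourier analysis yields the canonical (θ, φ) grid with the
familiar class latitudes 0 / 50.8 / 54.7 / 90 / 125.3 / 129.2 / 180°.

The "PL path" is the great circle-like curve θ = 90 + 39·cos(φ − 270°)
on which every conformer compatible with a planar C3–C4–C5–O5 fragment
(the restriction imposed by the C4=C5 double bond of unsaturated
lyase products) must lie.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import AMPLITUDE_FLOOR
from .errors import InvalidGeometryError, PlanarRingError

__all__ = [
    "RING_ATOM_ORDER",
    "RingGeometry",
    "PuckerCoords",
    "ConformerLabel",
    "CANONICAL_CONFORMERS",
    "PL_PATH_CONFORMERS",
    "compute_cremer_pople",
    "classify_conformer",
    "pl_path_theta",
    "distance_to_pl_path",
    "great_circle_distance",
    "normalize_conformer_name",
    "get_conformer",
    "build_canonical_table",
]

#: Cyclic atom order; O5 is Cremer–Pople atom 1.
RING_ATOM_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")

#: One-character tags used inside conformer names, in ring order.
_TAGS = ("O", "1", "2", "3", "4", "5")

_J = np.arange(6)
_ANG = 2.0 * np.pi * _J / 6.0  # Fourier angles 2π(j-1)/N
_SIGNS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])


# ---------------------------------------------------------------------------
# geometry container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingGeometry:
    """Six ring-atom positions (Å), cyclically ordered O5→C1→…→C5."""

    coords: np.ndarray
    labels: tuple = RING_ATOM_ORDER

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (6, 3):
            raise InvalidGeometryError(
                f"ring needs exactly 6 atoms with xyz, got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise InvalidGeometryError("non-finite coordinates")
        d = np.linalg.norm(coords - np.roll(coords, -1, axis=0), axis=1)
        if np.any(d < 1e-6):
            raise InvalidGeometryError("coincident consecutive ring atoms")
        object.__setattr__(self, "coords", coords)

    @classmethod
    def from_labeled(
        cls, coords: np.ndarray, labels: Sequence[str], order: Sequence[str] = RING_ATOM_ORDER
    ) -> "RingGeometry":
        """Reorder arbitrarily-ordered labeled atoms into the ring convention."""
        labels = [str(l).strip() for l in labels]
        try:
            idx = [labels.index(name) for name in order]
        except ValueError as exc:
            raise InvalidGeometryError(
                f"missing ring atom: {exc}; have {labels}, need {list(order)}"
            ) from None
        return cls(np.asarray(coords, dtype=float)[idx], tuple(order))


# ---------------------------------------------------------------------------
# Cremer–Pople coordinates
# ---------------------------------------------------------------------------


class PuckerCoords:
    """(Q, θ, φ) Cremer–Pople state of a six-membered ring.

    θ and φ are exposed in degrees.  For rings whose total amplitude Q
    falls below the floor (default 0.05 Å) the angular coordinates are
    noise-dominated: accessing ``theta``/``phi`` then raises
    :class:`PlanarRingError`, while ``Q``, ``q2``, ``q3`` stay available.
    """

    __slots__ = ("Q", "q2", "q3", "phi2", "_theta", "_phi", "planar")

    def __init__(self, q2: float, phi2_deg: float, q3: float, floor: float = AMPLITUDE_FLOOR):
        self.q2 = float(q2)
        self.q3 = float(q3)
        self.phi2 = float(phi2_deg) % 360.0
        self.Q = float(np.hypot(q2, q3))
        self.planar = self.Q < floor
        self._theta = float(np.degrees(np.arctan2(self.q2, self.q3)))
        self._phi = self.phi2

    @property
    def theta(self) -> float:
        if self.planar:
            raise PlanarRingError(f"Q = {self.Q:.4f} Å below amplitude floor; theta undefined")
        return self._theta

    @property
    def phi(self) -> float:
        if self.planar:
            raise PlanarRingError(f"Q = {self.Q:.4f} Å below amplitude floor; phi undefined")
        return self._phi

    def __repr__(self):  # pragma: no cover - cosmetic
        if self.planar:
            return f"PuckerCoords(Q={self.Q:.4f}, planar)"
        return f"PuckerCoords(Q={self.Q:.4f}, theta={self._theta:.2f}, phi={self._phi:.2f})"


def _cp_from_z(z: np.ndarray) -> tuple[float, float, float]:
    """Return (q2, phi2_deg, q3) from out-of-plane displacements."""
    c = np.sqrt(1.0 / 3.0)
    a = c * float(np.dot(z, np.cos(2.0 * _ANG)))  # q2 cos φ2
    b = -c * float(np.dot(z, np.sin(2.0 * _ANG)))  # q2 sin φ2
    q3 = float(np.dot(z, _SIGNS)) * np.sqrt(1.0 / 6.0)
    q2 = float(np.hypot(a, b))
    phi2 = float(np.degrees(np.arctan2(b, a))) % 360.0
    return q2, phi2, q3


def z_from_cp(q2: float, phi2_deg: float, q3: float) -> np.ndarray:
    """Out-of-plane displacements generated by (q2, φ2, q3) — the forward map."""
    phi2 = np.radians(phi2_deg)
    return np.sqrt(1.0 / 3.0) * q2 * np.cos(phi2 + 2.0 * _ANG) + np.sqrt(1.0 / 6.0) * q3 * _SIGNS


def compute_cremer_pople(geometry: RingGeometry | np.ndarray) -> PuckerCoords:
    """Cremer–Pople (Q, θ, φ) of a six-membered ring.

    Invariant to rigid rotation and translation of the input.  Raises
    :class:`InvalidGeometryError` for degenerate rings; a planar ring
    yields a :class:`PuckerCoords` whose angular accessors raise
    :class:`PlanarRingError`.
    """
    if not isinstance(geometry, RingGeometry):
        geometry = RingGeometry(np.asarray(geometry, dtype=float))
    r = geometry.coords - geometry.coords.mean(axis=0)
    rp = (r * np.sin(_ANG)[:, None]).sum(axis=0)
    rpp = (r * np.cos(_ANG)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise InvalidGeometryError("collinear/degenerate ring: mean plane undefined")
    z = r @ (n / nn)
    q2, phi2, q3 = _cp_from_z(z)
    return PuckerCoords(q2, phi2, q3)


# ---------------------------------------------------------------------------
# canonical conformer table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformerLabel:
    """A canonical pyranose conformer and its position on the CP sphere."""

    name: str
    ring_class: str  # C, B, S, E, H
    canonical_theta: float  # degrees
    canonical_phi: float  # degrees (0 for the poles, where φ is degenerate)

    def __str__(self):
        return self.name


def _ideal_z_patterns() -> Iterable[tuple[str, str, np.ndarray]]:
    """(name, class, z-pattern) for all 38 canonical conformers.

    Superscript atoms (before the class letter) lie above the reference
    plane, subscript atoms below; the pattern amplitude is arbitrary.
    """
    e = np.eye(6)
    # chairs: alternating pattern; +O5 ⇒ C4 up / C1 down ⇒ 4C1
    yield "4C1", "C", _SIGNS.copy()
    yield "1C4", "C", -_SIGNS.copy()
    # boats: para pair (j, j+3) displaced together
    # names list the displaced atoms digits-first with O last; flipping the
    # ring turns superscripts into subscripts ("3OB" ↔ "B3O")
    boat_names = {(0, 3): "3O", (1, 4): "14", (2, 5): "25"}
    for (i, j), tags in boat_names.items():
        pat = e[i] + e[j]
        yield tags + "B", "B", pat
        yield "B" + tags, "B", -pat
    # skew-boats: pure q2 modes at odd multiples of 30°
    skews = {30: "3S1", 90: "5S1", 150: "2SO", 210: "1S3", 270: "1S5", 330: "OS2"}
    for phi2, name in skews.items():
        pat = np.cos(np.radians(120.0 * _J + phi2))
        yield name, "S", pat
    # envelopes: one atom out of plane
    for j in range(6):
        yield _TAGS[j] + "E", "E", e[j]
        yield "E" + _TAGS[j], "E", -e[j]
    # half-chairs: adjacent pair, opposite sides
    for j in range(6):
        k = (j + 1) % 6
        yield _TAGS[j] + "H" + _TAGS[k], "H", e[j] - e[k]
        yield _TAGS[k] + "H" + _TAGS[j], "H", e[k] - e[j]


def _build_labels() -> tuple[ConformerLabel, ...]:
    out = []
    for name, cls, pat in _ideal_z_patterns():
        q2, phi2, q3 = _cp_from_z(pat)
        theta = float(np.degrees(np.arctan2(q2, q3)))
        phi = 0.0 if q2 < 1e-12 else phi2
        out.append(ConformerLabel(name, cls, round(theta, 6), round(phi, 6) % 360.0))
    assert len(out) == 38
    return tuple(out)


#: The 38 canonical pyranose conformers; tuple order is the classification
#: tie-break order.
CANONICAL_CONFORMERS: tuple[ConformerLabel, ...] = _build_labels()

_BY_NAME = {c.name: c for c in CANONICAL_CONFORMERS}

#: Conformers compatible with a planar C3–C4–C5–O5 fragment: the eight
#: possible product conformations of a polysaccharide-lyase β-elimination.
PL_PATH_CONFORMERS = ("3OB", "E1", "2H1", "2E", "B3O", "1E", "1H2", "E2")


def normalize_conformer_name(name: str) -> str:
    """Canonicalise conformer spellings like ``B3,O`` or ``os2`` → ``B3O``/``OS2``."""
    cleaned = name.replace(",", "").replace(" ", "").replace("°", "O").upper()
    if cleaned not in _BY_NAME:
        raise KeyError(f"unknown conformer name {name!r}")
    return cleaned


def get_conformer(name: str) -> ConformerLabel:
    return _BY_NAME[normalize_conformer_name(name)]


def build_canonical_table() -> str:
    """The packaged conformer table as TSV text (name, class, theta, phi)."""
    lines = ["name\tring_class\ttheta_deg\tphi_deg"]
    for c in CANONICAL_CONFORMERS:
        lines.append(f"{c.name}\t{c.ring_class}\t{c.canonical_theta:.6f}\t{c.canonical_phi:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# classification and the PL path
# ---------------------------------------------------------------------------


def great_circle_distance(theta1, phi1, theta2, phi2) -> float:
    """Angular distance (degrees) between points on the (θ, φ) sphere."""
    t1, p1, t2, p2 = np.radians([theta1, phi1, theta2, phi2])
    c = np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * np.cos(p1 - p2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def classify_conformer(p: PuckerCoords | tuple) -> ConformerLabel:
    """Nearest canonical conformer by great-circle distance; ties broken by
    table order.  Raises :class:`PlanarRingError` for planar input."""
    if isinstance(p, PuckerCoords):
        theta, phi = p.theta, p.phi  # raises PlanarRingError if planar
    else:
        theta, phi = float(p[0]), float(p[1])
    best, best_d = None, np.inf
    for c in CANONICAL_CONFORMERS:
        d = great_circle_distance(theta, phi, c.canonical_theta, c.canonical_phi)
        if d < best_d - 1e-12:
            best, best_d = c, d
    return best


def pl_path_theta(phi: float) -> float:
    """θ(φ) of the PL product path: 90 + 39·cos(φ − 270°), degrees."""
    return 90.0 + 39.0 * float(np.cos(np.radians(np.asarray(phi) - 270.0)))


def distance_to_pl_path(p: PuckerCoords | tuple) -> float:
    """Minimum great-circle distance (degrees) from (θ, φ) to the PL path."""
    if isinstance(p, PuckerCoords):
        theta, phi = p.theta, p.phi
    else:
        theta, phi = float(p[0]), float(p[1])

    def d(phi_c):
        return great_circle_distance(theta, phi, pl_path_theta(phi_c), phi_c % 360.0)

    grid = np.arange(0.0, 360.0, 0.25)
    vals = np.array([d(g) for g in grid])
    i = int(np.argmin(vals))
    res = minimize_scalar(d, bounds=(grid[i] - 0.5, grid[i] + 0.5), method="bounded")
    return float(min(res.fun, vals[i]))
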