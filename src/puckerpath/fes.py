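"""Post-processing of gridded free-energy surfaces.

Stationary points are found by persistence (union-find over cells in
order of increasing free energy), the minimum free-energy path by a
lowest-maximum (minimax) search on the 8-connected grid graph followed
by steepest-descent relaxation from each saddle, and barriers/reaction
free energies are read off the labelled path.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import PuckerPathError

__all__ = [
    "FESGrid",
    "Minimum",
    "MFEPResult",
    "find_minima",
    "minimax_path",
    "find_mfep",
    "barrier_and_dg",
    "project_1d",
    "tube_average",
]


@dataclass
class FESGrid:
    """Free energies (kcal/mol) on a rectilinear 1D/2D grid.

    Anchored so that the global minimum is exactly 0.
    """

    axes: tuple
    values: np.ndarray
    periodic: tuple = ()
    names: tuple = ()

    def __post_init__(self):
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise PuckerPathError("FES values must be finite")
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise PuckerPathError(
                f"value shape {self.values.shape} does not match axes "
                f"{tuple(len(a) for a in self.axes)}"
            )
        if not self.periodic:
            self.periodic = (False,) * self.ndim
        if not self.names:
            self.names = tuple(f"cv{i + 1}" for i in range(self.ndim))
        self.values = self.values - self.values.min()

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def coords(self, idx) -> np.ndarray:
        return np.array([self.axes[k][i] for k, i in enumerate(idx)])

    @classmethod
    def from_function(cls, f, spec, periodic=()) -> "FESGrid":
        """Evaluate a callable/potential on a (lo, hi, n) per-dim spec."""
        axes = [np.linspace(lo, hi, int(n)) for lo, hi, n in spec]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        fun = f.energy if hasattr(f, "energy") else f
        vals = np.asarray(fun(pts)).reshape([len(a) for a in axes])
        return cls(axes=tuple(axes), values=vals, periodic=periodic)

    def neighbors(self, idx):
        """8-connected (2D) or 2-connected (1D) neighbours, lexicographic."""
        shape = self.values.shape
        if self.ndim == 1:
            (i,) = idx
            for di in (-1, 1):
                j = i + di
                if self.periodic[0]:
                    j %= shape[0]
                if 0 <= j < shape[0]:
                    yield (j,)
            return
        i, j = idx
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if self.periodic[0]:
                    a %= shape[0]
                if self.periodic[1]:
                    b %= shape[1]
                if 0 <= a < shape[0] and 0 <= b < shape[1]:
                    yield (a, b)


@dataclass(frozen=True)
class Minimum:
    """A grid-local minimum with its persistence (depth to lowest escape)."""

    idx: tuple
    coords: np.ndarray
    F: float
    prominence: float


def find_minima(f: FESGrid, depth_floor: float = 0.5) -> list[Minimum]:
    """All grid-local minima deeper than ``depth_floor``.

    Depth is measured by persistence: the gap between a minimum and the
    lowest saddle through which its basin merges into a deeper one.  The
    global minimum has infinite persistence.  Sorted by energy.
    """
    vals = f.values
    order = np.argsort(vals, axis=None, kind="stable")
    flat = vals.ravel()
    shape = vals.shape
    parent = {}
    root_min = {}  # root -> (F_min, flat_idx of basin minimum)
    persistence = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for fi in order:
        idx = np.unravel_index(fi, shape)
        lower_roots = set()
        for nb in f.neighbors(idx):
            nfi = np.ravel_multi_index(nb, shape)
            if nfi in parent:
                lower_roots.add(find(nfi))
        if not lower_roots:
            parent[fi] = fi
            root_min[fi] = (flat[fi], fi)
            continue
        roots = sorted(lower_roots, key=lambda r: (root_min[r][0], root_min[r][1]))
        survivor = roots[0]
        parent[fi] = survivor
        for r in roots[1:]:
            # basin r dies at this level
            persistence[root_min[r][1]] = flat[fi] - root_min[r][0]
            parent[r] = survivor

    out = []
    for root, (fmin, mi) in root_min.items():
        prom = persistence.get(mi, np.inf)
        if prom >= depth_floor:
            idx = np.unravel_index(mi, shape)
            out.append(Minimum(tuple(int(i) for i in idx), f.coords(idx), float(flat[mi]), prom))
    out.sort(key=lambda m: (m.F, m.idx))
    return out


def minimax_path(f: FESGrid, a: tuple, b: tuple) -> list[tuple]:
    """Lowest-maximum path on the grid graph from node ``a`` to ``b``.

    Dijkstra-like search with lexicographic key (bottleneck energy,
    cumulative energy, node index) — the spec'd deterministic tie-break.
    """
    vals = f.values
    shape = vals.shape
    a = tuple(int(i) for i in a)
    b = tuple(int(i) for i in b)
    start_key = (float(vals[a]), float(vals[a]))
    best = {a: start_key}
    prev = {}
    heap = [(start_key[0], start_key[1], a)]
    while heap:
        bot, cum, node = heapq.heappop(heap)
        if (bot, cum) > best.get(node, (np.inf, np.inf)):
            continue
        if node == b:
            break
        for nb in f.neighbors(node):
            nkey = (max(bot, float(vals[nb])), cum + float(vals[nb]))
            if nkey < best.get(nb, (np.inf, np.inf)):
                best[nb] = nkey
                prev[nb] = node
                heapq.heappush(heap, (nkey[0], nkey[1], nb))
    if b not in best:
        raise PuckerPathError("endpoints are not connected on the grid")
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    return path[::-1]


def _descend(f: FESGrid, start: tuple) -> list[tuple]:
    """Greedy steepest-descent to a local minimum (lowest neighbour, lex ties)."""
    path = [start]
    while True:
        cur = path[-1]
        nbs = sorted(f.neighbors(cur))
        vals = [(float(f.values[n]), n) for n in nbs]
        fmin, nmin = min(vals)
        if fmin >= float(f.values[cur]):
            return path
        path.append(nmin)


@dataclass
class MFEPResult:
    """Ordered MFEP with energies, arclength and labelled stationary points."""

    path: list  # grid index tuples
    coords: np.ndarray  # (n, ndim) CV coordinates
    F: np.ndarray  # kcal/mol along the path
    arclength: np.ndarray
    stations: dict = field(default_factory=dict)  # label -> position along path

    def station_coords(self, label: str) -> np.ndarray:
        return self.coords[self.stations[label]]

    def station_F(self, label: str) -> float:
        return float(self.F[self.stations[label]])

    def reversed(self) -> "MFEPResult":
        n = len(self.path)
        st = {k: n - 1 - v for k, v in self.stations.items()}
        return MFEPResult(
            self.path[::-1],
            self.coords[::-1].copy(),
            self.F[::-1].copy(),
            (self.arclength[-1] - self.arclength)[::-1].copy(),
            st,
        )


def _segment(f: FESGrid, a: tuple, b: tuple, depth: int = 0) -> list[tuple]:
    """Minimax backbone refined by steepest descent from its saddle."""
    if a == b:
        return [a]
    raw = minimax_path(f, a, b)
    prof = np.array([f.values[p] for p in raw])
    imax = int(np.argmax(prof))
    if imax in (0, len(raw) - 1) or depth > 8:
        return raw
    saddle = raw[imax]
    left = _descend(f, raw[imax - 1])
    right = _descend(f, raw[imax + 1])
    m1, m2 = left[-1], right[-1]
    pre = _segment(f, a, m1, depth + 1) if m1 != a else [a]
    post = _segment(f, m2, b, depth + 1) if m2 != b else [b]
    full = pre[:-1] + left[::-1] + [saddle] + right + post[1:]
    # drop accidental immediate repeats
    dedup = [full[0]]
    for p in full[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return dedup


def find_mfep(
    f: FESGrid,
    a,
    b,
    ic_depth: float = 0.5,
    labels: Sequence[str] = ("MC", "TS", "IC", "PC"),
) -> MFEPResult:
    """Minimum free-energy path between two minima of a gridded FES.

    ``a`` and ``b`` may be grid index tuples or :class:`Minimum` objects.
    The path maximum is labelled TS; interior shoulder basins at least
    ``ic_depth`` kcal/mol below both flanking path maxima are labelled IC
    (IC2, … if several).  Endpoints get the first/last label.
    """
    ia = a.idx if isinstance(a, Minimum) else tuple(int(i) for i in a)
    ib = b.idx if isinstance(b, Minimum) else tuple(int(i) for i in b)
    if ia == ib:
        raise PuckerPathError("endpoints must differ")
    path = _segment(f, ia, ib)
    coords = np.array([f.coords(p) for p in path])
    F = np.array([float(f.values[p]) for p in path])
    if len(path) > 1:
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
    else:
        arc = np.zeros(1)
    stations = {labels[0]: 0, labels[-1]: len(path) - 1}
    imax = int(np.argmax(F))
    stations[labels[1]] = imax
    # intermediate shoulder detection
    interior = _interior_minima(F)
    ics = []
    for i, depth in interior:
        if i not in (0, len(F) - 1, imax) and depth >= ic_depth:
            ics.append(i)
    for n, i in enumerate(sorted(ics)):
        stations[labels[2] if n == 0 else f"{labels[2]}{n + 1}"] = i
    return MFEPResult(path, coords, F, arc, stations)


def _interior_minima(F: np.ndarray) -> list[tuple[int, float]]:
    """(index, depth-below-flanking-maxima) for interior local minima."""
    out = []
    n = len(F)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and F[j + 1] == F[i]:
            j += 1
        if F[i] < F[i - 1] and j + 1 < n and F[i] < F[j + 1]:
            lmax = F[:i].max()
            rmax = F[j + 1 :].max()
            out.append((int(i + (j - i) // 2), float(min(lmax, rmax) - F[i])))
        i = j + 1
    return out


def barrier_and_dg(path: MFEPResult) -> tuple[float, float, dict]:
    """(ΔG‡, ΔG⁰, intermediates) from a labelled MFEP.

    ΔG‡ = F(TS) − F(start), ΔG⁰ = F(end) − F(start); intermediates maps
    each IC label to its energy relative to the start.
    """
    f0 = float(path.F[0])
    dg_act = float(path.F.max()) - f0
    dg0 = float(path.F[-1]) - f0
    inter = {
        lab: float(path.F[i]) - f0
        for lab, i in path.stations.items()
        if lab.startswith("IC")
    }
    return dg_act, dg0, inter


def project_1d(path: MFEPResult) -> tuple[np.ndarray, np.ndarray]:
    """Free energy versus normalised arclength (reaction coordinate)."""
    total = path.arclength[-1] if path.arclength[-1] > 0 else 1.0
    return path.arclength / total, path.F.copy()


def tube_average(
    frames,
    path: MFEPResult,
    tol: Sequence[float],
    cv_cols: Optional[Sequence[str]] = None,
    observables: Optional[Sequence[str]] = None,
):
    """Mean of observables over frames inside a CV-space box at each path node.

    ``frames`` is a DataFrame carrying CV columns and observable columns;
    a frame contributes to a node when every CV lies within ±tol of the
    node's CV coordinates.  Nodes whose box is empty report NaN (never
    silently interpolated); if every box is empty an error is raised.
    """
    import pandas as pd

    tol = np.atleast_1d(np.asarray(tol, dtype=float))
    if np.any(tol <= 0):
        raise PuckerPathError("tube half-widths must be > 0")
    ndim = path.coords.shape[1]
    if cv_cols is None:
        cv_cols = [f"cv{i + 1}" for i in range(ndim)]
    if observables is None:
        observables = [c for c in frames.columns if c not in cv_cols]
    cvs = frames[list(cv_cols)].to_numpy()
    obs = frames[list(observables)].to_numpy()
    rows = []
    any_hit = False
    for node in path.coords:
        mask = np.all(np.abs(cvs - node) <= tol, axis=1)
        if mask.any():
            any_hit = True
            rows.append(np.concatenate([obs[mask].mean(axis=0), [mask.sum()]]))
        else:
            rows.append(np.concatenate([np.full(len(observables), np.nan), [0]]))
    if not any_hit:
        raise PuckerPathError("no frames fall inside the MFEP tube at any node")
    out = pd.DataFrame(rows, columns=list(observables) + ["n_frames"])
    out.insert(0, "arclength", path.arclength)
    for k in range(ndim):
        out.insert(1 + k, cv_cols[k], path.coords[:, k])
    return out
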