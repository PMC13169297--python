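"""Text I/O: HILLS/COLVAR dialects, gridded FES files, XYZ/PDB rings.

The HILLS and COLVAR formats follow the PLUMED convention of a
``#! FIELDS …`` header line followed by whitespace-separated numeric
rows; ``#! SET key value`` lines carry scalar metadata.  All files use
Å, kcal/mol and degrees; radians are never serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, PuckerPathError
from .fes import FESGrid
from .ring import RING_ATOM_ORDER, RingGeometry
from .sampler import BiasState

__all__ = [
    "RunConfig",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
    "read_fes_grid",
    "write_fes_grid",
    "read_ring_frames",
    "write_xyz_frames",
]


# ---------------------------------------------------------------------------
# FIELDS-table primitives
# ---------------------------------------------------------------------------


def _parse_fields_table(path) -> tuple[list[str], dict, np.ndarray]:
    """Parse a ``#! FIELDS``-headed whitespace table → (fields, sets, data)."""
    fields: Optional[list[str]] = None
    sets: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                parts = s[2:].split()
                if parts and parts[0] == "FIELDS":
                    fields = parts[1:]
                elif parts and parts[0] == "SET" and len(parts) >= 3:
                    sets[parts[1]] = parts[2]
                continue
            if s.startswith("#"):
                continue
            if fields is None:
                raise ParseError(f"{path}:{ln}: data before '#! FIELDS' header")
            vals = s.split()
            if len(vals) != len(fields):
                raise ParseError(
                    f"{path}:{ln}: expected {len(fields)} columns, got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
    if fields is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    return fields, sets, np.array(rows, dtype=float)


def _write_fields_table(path, fields: Sequence[str], data: np.ndarray, sets: dict = ()):
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for k, v in dict(sets or {}).items():
            fh.write(f"#! SET {k} {v}\n")
        for row in np.atleast_2d(data):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# HILLS
# ---------------------------------------------------------------------------


def write_hills(path, bias: BiasState, cv_names: Optional[Sequence[str]] = None) -> None:
    """One hill per line: time, centers, sigmas, height, bias factor."""
    ndim = bias.ndim
    if cv_names is None:
        cv_names = [f"cv{i + 1}" for i in range(ndim)]
    fields = (
        ["time"]
        + list(cv_names)
        + [f"sigma_{n}" for n in cv_names]
        + ["height", "biasf"]
    )
    hills = bias.hills
    data = np.zeros((len(hills), len(fields)))
    for i, h in enumerate(hills):
        t = h.step * bias.dt
        data[i] = [t, *h.center, *h.sigma, h.height, bias.bias_factor]
    sets = {
        "delta_T": f"{bias.delta_T:.10g}",
        "temperature": f"{bias.temperature:.10g}",
        "stride": str(bias.stride),
        "dt": f"{bias.dt:.10g}",
    }
    for k, p in enumerate(bias.periods):
        if p is not None:
            sets[f"period_{cv_names[k]}"] = f"{p:.10g}"
    _write_fields_table(path, fields, data, sets)


def read_hills(path) -> BiasState:
    """Parse a HILLS file back into a :class:`BiasState` (order preserved)."""
    fields, sets, data = _parse_fields_table(path)
    if data.size == 0:
        raise ParseError(f"{path}: no hills in file")
    ncv = sum(1 for f in fields if f.startswith("sigma_"))
    if ncv == 0 or "height" not in fields:
        raise ParseError(f"{path}: not a HILLS table (fields: {fields})")
    cv_names = fields[1 : 1 + ncv]
    sigma = data[0, 1 + ncv : 1 + 2 * ncv]
    delta_T = float(sets.get("delta_T", 1.0))
    temperature = float(sets.get("temperature", 300.0))
    stride = int(sets.get("stride", 100))
    dt = float(sets.get("dt", 0.005))
    periods = tuple(
        float(sets[f"period_{n}"]) if f"period_{n}" in sets else None for n in cv_names
    )
    bias = BiasState(
        sigma, delta_T, stride=stride, temperature=temperature, periods=periods, dt=dt
    )
    i_h = fields.index("height")
    for row in data:
        step = int(round(row[0] / dt)) if dt > 0 else 0
        bias.add_hill(row[1 : 1 + ncv], row[i_h], step=step)
    return bias


# ---------------------------------------------------------------------------
# COLVAR
# ---------------------------------------------------------------------------


def write_colvar(path, df: pd.DataFrame) -> None:
    """COLVAR-style table; first column should be ``time``."""
    _write_fields_table(path, list(df.columns), df.to_numpy(dtype=float))


def read_colvar(path) -> pd.DataFrame:
    fields, _, data = _parse_fields_table(path)
    if data.size == 0:
        raise ParseError(f"{path}: empty COLVAR file")
    return pd.DataFrame(data, columns=fields)


# ---------------------------------------------------------------------------
# gridded FES
# ---------------------------------------------------------------------------


def write_fes_grid(path, grid: FESGrid) -> None:
    names = list(grid.names)
    mesh = np.meshgrid(*grid.axes, indexing="ij")
    data = np.column_stack([m.ravel() for m in mesh] + [grid.values.ravel()])
    sets = {}
    for k, ax in enumerate(grid.axes):
        sets[f"min_{names[k]}"] = f"{ax[0]:.10g}"
        sets[f"max_{names[k]}"] = f"{ax[-1]:.10g}"
        sets[f"nbins_{names[k]}"] = str(len(ax))
        sets[f"periodic_{names[k]}"] = "true" if grid.periodic[k] else "false"
    _write_fields_table(path, names + ["free"], data, sets)


def read_fes_grid(path) -> FESGrid:
    fields, sets, data = _parse_fields_table(path)
    if data.size == 0:
        raise ParseError(f"{path}: empty FES file")
    names = fields[:-1]
    axes, periodic = [], []
    for n in names:
        try:
            nb = int(sets[f"nbins_{n}"])
            axes.append(np.linspace(float(sets[f"min_{n}"]), float(sets[f"max_{n}"]), nb))
        except KeyError as exc:
            raise ParseError(f"{path}: missing grid metadata {exc}") from None
        periodic.append(sets.get(f"periodic_{n}", "false").lower() == "true")
    values = data[:, -1].reshape([len(a) for a in axes])
    return FESGrid(axes=tuple(axes), values=values, periodic=tuple(periodic), names=tuple(names))


# ---------------------------------------------------------------------------
# ring coordinates (XYZ / PDB)
# ---------------------------------------------------------------------------


def write_xyz_frames(path, geoms: Sequence[RingGeometry], comment: str = "ring") -> None:
    """Multi-frame XYZ; atom names follow the ring convention."""
    with open(path, "w") as fh:
        for i, g in enumerate(geoms):
            fh.write("6\n")
            fh.write(f"{comment} frame {i + 1}\n")
            for name, xyz in zip(g.labels, g.coords):
                fh.write(f"{name:<4s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")


def _read_xyz(path) -> list[tuple[list[str], np.ndarray]]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from None
        block = lines[i + 2 : i + 2 + nat]
        if len(block) < nat:
            raise ParseError(f"{path}:{i + 1}: truncated frame")
        names, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: bad XYZ atom line")
            names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append((names, np.array(coords)))
        i += 2 + nat
    return frames


def _read_pdb(path) -> list[tuple[list[str], np.ndarray]]:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = []
        names = [a.name for a in u.atoms]
        for _ in u.trajectory:
            frames.append((list(names), u.atoms.positions.astype(float).copy()))
    return frames


def read_ring_frames(
    path, selection: Sequence[str] = RING_ATOM_ORDER
) -> list[RingGeometry]:
    """Ordered :class:`RingGeometry` per frame from an XYZ or PDB file.

    Atoms are selected by name and reordered into the ring convention;
    a frame missing one of the six names raises, naming frame and atom.
    """
    path = Path(path)
    raw = _read_pdb(path) if path.suffix.lower() in (".pdb", ".ent") else _read_xyz(path)
    if not raw:
        raise ParseError(f"{path}: no frames found")
    out = []
    for i, (names, coords) in enumerate(raw, start=1):
        for want in selection:
            if want not in names:
                raise ParseError(f"{path}: frame {i} is missing atom {want!r}")
        out.append(RingGeometry.from_labeled(coords, names, order=selection))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """YAML-backed run configuration for the CLI."""

    potential: str = "reaction"  # reaction | pucker | pmf1d | double_well
    sigma: tuple = (0.15, 0.15)
    height: float = 1.0
    delta_T: float = 30.0
    stride: int = 100
    n_hills: int = 1000
    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 0.005
    mass: float = 1.0
    x0: Optional[tuple] = None
    seed: int = 0
    n_steps: int = 10000
    # umbrella protocol
    us_start: float = -0.75
    us_stop: float = 1.25
    us_spacing: float = 0.25
    us_force_constant: Optional[float] = None
    us_steps: int = 22500
    # grids
    grid_n: int = 101
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("height", "delta_T", "stride", "temperature", "friction", "dt", "mass"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise PuckerPathError(f"config parameter {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        for key in ("sigma", "x0"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        d.update(self.extra)
        for key in ("sigma", "x0"):
            if d.get(key) is not None:
                d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
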