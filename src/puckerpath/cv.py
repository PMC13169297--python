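"""Reaction collective variables built from active-site distances.

The β-elimination of the Rha-GlcA disaccharide is driven by two proton
transfers plus glycosidic bond cleavage, tracked by four distances:
d1 = d(H5–C5), d2 = d(H5–N of the catalytic histidine), d3 = d(H5–O4)
and d4 = d(C4–O4), the glycosidic bond.  The biased coordinates are

    CV1 = d1 − d2          (proton abstraction from C5 by the base)
    CV2 = d2 − d3 + d4     (proton delivery to O4 + bond cleavage)

with d2 appearing in both symmetric and antisymmetric form so that both
proton transfers can activate without prescribing their order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import PuckerPathError

__all__ = ["DistanceSet", "CVDefinition", "CV1", "CV2", "eval_cv1", "eval_cv2", "evaluate_cvs"]


@dataclass(frozen=True)
class DistanceSet:
    """Named active-site distances (Å); extras hold e.g. d(C5–C6)."""

    d1: float | None = None
    d2: float | None = None
    d3: float | None = None
    d4: float | None = None
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("d1", "d2", "d3", "d4"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise PuckerPathError(f"distance {name} must be > 0, got {v}")
        for name, v in self.extras.items():
            if v <= 0:
                raise PuckerPathError(f"distance {name} must be > 0, got {v}")

    def get(self, name: str) -> float:
        v = getattr(self, name, None) if name in ("d1", "d2", "d3", "d4") else None
        if v is None:
            v = self.extras.get(name)
        if v is None:
            raise PuckerPathError(f"missing distance {name!r}")
        return float(v)


@dataclass(frozen=True)
class CVDefinition:
    """A signed linear combination of named distances (or a pucker angle)."""

    name: str
    terms: Mapping[str, float] = field(default_factory=dict)
    unit: str = "A"
    periodic: bool = False

    def __post_init__(self):
        if not self.terms:
            raise PuckerPathError("CV needs at least one term")
        if any(c == 0 for c in self.terms.values()):
            raise PuckerPathError("CV coefficients must be nonzero")

    def evaluate(self, d: DistanceSet | Mapping[str, float]) -> float:
        getter = d.get if isinstance(d, DistanceSet) else lambda k: _from_mapping(d, k)
        return float(sum(c * getter(k) for k, c in self.terms.items()))


def _from_mapping(d: Mapping[str, float], key: str) -> float:
    if key not in d or d[key] is None or (isinstance(d[key], float) and np.isnan(d[key])):
        raise PuckerPathError(f"missing distance {key!r}")
    return float(d[key])


CV1 = CVDefinition("cv1", {"d1": 1.0, "d2": -1.0})
CV2 = CVDefinition("cv2", {"d2": 1.0, "d3": -1.0, "d4": 1.0})


def eval_cv1(d: DistanceSet | Mapping[str, float]) -> float:
    """CV1 = d1 − d2 (Å)."""
    return CV1.evaluate(d)


def eval_cv2(d: DistanceSet | Mapping[str, float]) -> float:
    """CV2 = d2 − d3 + d4 (Å)."""
    return CV2.evaluate(d)


def evaluate_cvs(
    traj: Iterable[DistanceSet | Mapping[str, float]] | pd.DataFrame,
    cvs: Iterable[CVDefinition] = (CV1, CV2),
) -> pd.DataFrame:
    """Batch CV evaluation: one row per frame, one column per CV.

    Raises naming the offending frame and distance if an atom-pair
    distance a CV references is missing anywhere.
    """
    cvs = list(cvs)
    if isinstance(traj, pd.DataFrame):
        frames = traj.to_dict("records")
    else:
        frames = list(traj)
    if not frames:
        raise PuckerPathError("empty trajectory")
    rows = []
    for i, fr in enumerate(frames):
        row = {}
        for cv in cvs:
            try:
                row[cv.name] = cv.evaluate(fr)
            except PuckerPathError as exc:
                raise PuckerPathError(f"frame {i + 1}: {exc}") from None
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "frame", np.arange(1, len(rows) + 1))
    return out
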