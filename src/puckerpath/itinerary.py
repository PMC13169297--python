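"""Conformational itineraries and PL-family classification.

A catalytic itinerary is the ordered sequence of canonical ring
conformers a sugar visits along a reaction path (for this lyase:
1C4 → 1C4 → 1H2, read off at the MC/TS/PC stations of the MFEP).
Polysaccharide-lyase mechanisms are classified by where the product
ring conformation falls on the PL path θ = 90 + 39·cos(φ − 270°).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import PuckerPathError
from .ring import (
    PL_PATH_CONFORMERS,
    ConformerLabel,
    PuckerCoords,
    classify_conformer,
    get_conformer,
    normalize_conformer_name,
)

__all__ = ["ItineraryResult", "assign_itinerary", "classify_pl_family"]


@dataclass
class ItineraryResult:
    """Per-frame conformer labels, collapsed sequence, stage assignments."""

    frame_labels: list  # ConformerLabel per frame
    collapsed: list  # consecutive duplicates merged
    stages: dict = field(default_factory=dict)  # stage name -> ConformerLabel

    @property
    def itinerary(self) -> str:
        """Arrow-joined stage string (falls back to the collapsed sequence)."""
        seq = (
            [self.stages[k] for k in self.stages]
            if self.stages
            else self.collapsed
        )
        return " -> ".join(c.name for c in seq)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": range(1, len(self.frame_labels) + 1),
                "conformer": [c.name for c in self.frame_labels],
            }
        )


def assign_itinerary(
    series: Sequence[PuckerCoords | tuple],
    stage_markers: Optional[Mapping[str, int]] = None,
) -> ItineraryResult:
    """Nearest-conformer label per frame; duplicates collapsed.

    ``stage_markers`` maps stage names (MC/TS/IC/PC …) to frame indices;
    the stage labels are reported in marker order.  Planar frames must be
    filtered out beforehand (they raise).
    """
    if len(series) == 0:
        raise PuckerPathError("empty pucker series")
    labels = [classify_conformer(p) for p in series]
    collapsed = [labels[0]]
    for lab in labels[1:]:
        if lab.name != collapsed[-1].name:
            collapsed.append(lab)
    stages = {}
    if stage_markers:
        for name, idx in stage_markers.items():
            if not 0 <= idx < len(labels):
                raise PuckerPathError(f"stage {name!r} index {idx} out of range")
            stages[name] = labels[idx]
    return ItineraryResult(labels, collapsed, stages)


def classify_pl_family(product: ConformerLabel | str) -> dict:
    """Is a product-ring conformer on the PL path, and where?

    Returns a dict with ``on_path`` (bool), ``phi`` (the conformer's
    meridian, degrees) and ``distance`` (great-circle distance to the
    path, degrees).  Chairs and other off-path conformers cannot host
    the planar C3–C4–C5–O5 fragment of an unsaturated product.
    """
    from .ring import distance_to_pl_path

    if isinstance(product, ConformerLabel):
        label = product
    else:
        label = get_conformer(normalize_conformer_name(str(product)))
    d = distance_to_pl_path((label.canonical_theta, label.canonical_phi))
    return {
        "name": label.name,
        "on_path": label.name in PL_PATH_CONFORMERS,
        "phi": label.canonical_phi,
        "distance": d,
    }
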