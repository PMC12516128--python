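"""Debris-engulfment modality classification after laser ablation.

Phagocytes engulf laser-generated keratinocyte debris in two ways: by
reaching out a single long dendrite while the soma stays put
("dendritic"), or by migrating the whole cell body next to the debris
("motility").  The qualitative distinction is operationalized by a
distance-closure rule: an event is motility-based when the cell-body
centroid closes more than ``closure_threshold`` (default 50%) of its
initial centroid-debris distance between ablation and engulfment.

Engulfment itself is annotation- or ground-truth-driven (it would require
a phagosome marker on real data); this module classifies and summarizes
annotated events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tracking import Track

__all__ = ["EngulfmentEvent", "classify_modality", "engulfment_summary"]


@dataclass
class EngulfmentEvent:
    cell_id: int
    debris_xy_um: np.ndarray
    ablation_time_s: float
    contact_time_s: Optional[float] = None
    contact_structure: Optional[str] = None  # dendrite | cell_body
    engulf_time_s: Optional[float] = None
    modality: Optional[str] = None  # dendritic | motility
    success: bool = False
    distance_closure: Optional[float] = None


def classify_modality(
    cell_track: Track,
    debris_xy_um: np.ndarray,
    ablation_time_s: float,
    engulf_time_s: Optional[float] = None,
    contact_time_s: Optional[float] = None,
    contact_structure: Optional[str] = None,
    closure_threshold: float = 0.5,
    cell_id: int = 0,
) -> EngulfmentEvent:
    """Classify one annotated engulfment event.

    ``modality`` is "motility" when the centroid-debris distance closes by
    more than ``closure_threshold`` of its value at ablation before
    engulfment, else "dendritic".  With no engulfment in the observation,
    the modality is undefined and success is False.
    """
    debris = np.asarray(debris_xy_um, dtype=float)
    d_t = np.hypot(*(cell_track.xy_um - debris).T)
    k0 = int(np.argmin(np.abs(cell_track.t_s - ablation_time_s)))
    d0 = float(d_t[k0])
    ev = EngulfmentEvent(
        cell_id=cell_id,
        debris_xy_um=debris,
        ablation_time_s=ablation_time_s,
        contact_time_s=contact_time_s,
        contact_structure=contact_structure,
        engulf_time_s=engulf_time_s,
    )
    if engulf_time_s is None:
        return ev  # no engulfment observed: modality undefined
    ke = int(np.argmin(np.abs(cell_track.t_s - engulf_time_s)))
    de = float(d_t[ke])
    closure = 1.0 - de / d0 if d0 > 0 else 1.0
    ev.distance_closure = closure
    ev.modality = "motility" if closure > closure_threshold else "dendritic"
    ev.success = True
    return ev


def engulfment_summary(events: Sequence[EngulfmentEvent]) -> dict:
    """Percent dendritic (over classified events), percent successful
    (over all events), and the raw counts for a Fisher's exact test."""
    events = list(events)
    if not events:
        raise ValueError("no engulfment events")
    classified = [e for e in events if e.modality is not None]
    n_dend = sum(e.modality == "dendritic" for e in classified)
    n_mot = len(classified) - n_dend
    n_succ = sum(e.success for e in events)
    return dict(
        pct_dendritic=100.0 * n_dend / len(classified) if classified else np.nan,
        pct_success=100.0 * n_succ / len(events),
        counts=dict(
            dendritic=n_dend,
            motility=n_mot,
            success=n_succ,
            failure=len(events) - n_succ,
        ),
        n_classified=len(classified),
        n_events=len(events),
    )
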