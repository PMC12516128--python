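"""Obstacle-encounter detection and MTOC-vs-nucleus navigation scoring.

During directed migration toward a wound, a cell "encounters" an obstacle
keratinocyte nucleus when its MTOC comes within ``encounter_dist_um`` of
the obstacle boundary with the obstacle ahead along the approach axis.
A structure has "passed" once its projection onto the approach axis
exceeds the obstacle centroid projection plus the obstacle radius.  The
decision is MTOC-first or nucleus-first by whichever structure passes
first (a same-frame tie counts as MTOC-first); a navigation succeeds when
the MTOC passes within the observation window (55 min), fails when it is
observed at least that long without passing, and is censored when the
movie ends earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points

from .tracking import Track

__all__ = [
    "NavigationEvent",
    "detect_encounters",
    "score_event",
    "navigation_summary",
    "NAVIGATION_WINDOW_S",
]

NAVIGATION_WINDOW_S = 3300.0  # 55 min observation window


@dataclass
class NavigationEvent:
    cell_id: int
    obstacle_id: int
    obstacle_xy_um: np.ndarray
    obstacle_radius_um: float
    axis: np.ndarray  # unit approach vector at encounter
    encounter_frame: int
    encounter_time_s: float
    mtoc_pass_time_s: Optional[float] = None
    nucleus_pass_time_s: Optional[float] = None
    decision: str = "none"  # mtoc_first | nucleus_first | none
    outcome: str = "open"  # success | failure | censored | open
    navigation_time_s: Optional[float] = None


def _approach_axis(xy: np.ndarray, wound_polygon_um) -> np.ndarray:
    pt = nearest_points(Polygon(np.asarray(wound_polygon_um)).exterior, Point(xy))[0]
    v = np.asarray(pt.coords[0]) - xy
    n = np.hypot(*v)
    if n == 0:
        raise ValueError("position coincides with the wound boundary")
    return v / n


def detect_encounters(
    cell_track: Track,
    mtoc_track: Optional[Track],
    nucleus_track: Track,
    obstacles: np.ndarray,
    approach_axis: Optional[np.ndarray] = None,
    wound_polygon_um: Optional[np.ndarray] = None,
    encounter_dist_um: float = 5.0,
    cell_id: int = 0,
) -> list[NavigationEvent]:
    """Open one event per cell-obstacle pair at the first frame the MTOC
    is within ``encounter_dist_um`` of the obstacle boundary with the
    obstacle ahead along the approach axis.

    The axis is taken from ``approach_axis`` when given, otherwise
    computed per frame as the unit vector toward the nearest wound-polygon
    point; one of the two must be supplied.
    """
    if mtoc_track is None:
        raise ValueError("MTOC track is required for encounter detection")
    if approach_axis is None and wound_polygon_um is None:
        raise ValueError("supply approach_axis or wound_polygon_um")
    obstacles = np.asarray(obstacles, dtype=float).reshape(-1, 3)
    events: list[NavigationEvent] = []
    seen: set[int] = set()
    for k in range(len(mtoc_track)):
        m = mtoc_track.xy_um[k]
        if approach_axis is not None:
            u = np.asarray(approach_axis, dtype=float)
            u = u / np.hypot(*u)
        else:
            u = _approach_axis(m, wound_polygon_um)
        for oi, (ox, oy, r) in enumerate(obstacles):
            if oi in seen:
                continue
            C = np.array([ox, oy])
            if (
                np.hypot(*(m - C)) <= r + encounter_dist_um
                and float(np.dot(C - m, u)) > 0
            ):
                seen.add(oi)
                events.append(
                    NavigationEvent(
                        cell_id=cell_id,
                        obstacle_id=oi,
                        obstacle_xy_um=C,
                        obstacle_radius_um=float(r),
                        axis=u.copy(),
                        encounter_frame=int(mtoc_track.frames[k]),
                        encounter_time_s=float(mtoc_track.t_s[k]),
                    )
                )
    return events


def score_event(
    event: NavigationEvent,
    mtoc_track: Track,
    nucleus_track: Track,
    window_s: float = NAVIGATION_WINDOW_S,
) -> NavigationEvent:
    """Close an open event: pass times, decision, outcome and navigation
    time per the axial-projection passage rule."""
    u, C, r = event.axis, event.obstacle_xy_um, event.obstacle_radius_um

    def first_pass(track: Track) -> Optional[float]:
        sel = track.t_s >= event.encounter_time_s
        proj = (track.xy_um[sel] - C) @ u
        hits = np.nonzero(proj > r)[0]
        if not len(hits):
            return None
        return float(track.t_s[sel][hits[0]])

    mp = first_pass(mtoc_track)
    npass = first_pass(nucleus_track)
    event.mtoc_pass_time_s = mp
    event.nucleus_pass_time_s = npass
    if mp is None and npass is None:
        event.decision = "none"
    elif npass is None or (mp is not None and mp <= npass):
        event.decision = "mtoc_first"  # ties go to the MTOC
    else:
        event.decision = "nucleus_first"
    observed_s = float(mtoc_track.t_s[-1] - event.encounter_time_s)
    if mp is not None and mp - event.encounter_time_s <= window_s:
        event.outcome = "success"
        event.navigation_time_s = mp - event.encounter_time_s
    elif observed_s >= window_s:
        event.outcome = "failure"
    else:
        event.outcome = "censored"
    return event


def navigation_summary(events: Sequence[NavigationEvent]) -> dict:
    """Percent MTOC-first (over decided events), success rate (over
    success+failure; censored events are excluded) and mean navigation
    time (over successes, None when there are none)."""
    events = list(events)
    if not events:
        raise ValueError("no navigation events")
    decided = [e for e in events if e.decision != "none"]
    closed = [e for e in events if e.outcome in ("success", "failure")]
    successes = [e for e in events if e.outcome == "success"]
    pct_mtoc_first = (
        100.0 * sum(e.decision == "mtoc_first" for e in decided) / len(decided)
        if decided
        else np.nan
    )
    success_rate = 100.0 * len(successes) / len(closed) if closed else np.nan
    mean_time = (
        float(np.mean([e.navigation_time_s for e in successes]))
        if successes
        else None
    )
    return dict(
        pct_mtoc_first=pct_mtoc_first,
        success_rate_pct=success_rate,
        mean_navigation_time_s=mean_time,
        n_decided=len(decided),
        n_closed=len(closed),
        n_success=len(successes),
        n_censored=sum(e.outcome == "censored" for e in events),
    )
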