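"""Encounter detection, MTOC-vs-nucleus scoring and navigation summaries."""

import numpy as np
import pytest

from epinav import (
    NAVIGATION_WINDOW_S,
    Track,
    condition_preset,
    detect_encounters,
    generate_scene,
    navigation_summary,
    score_event,
    with_scratch,
)
from epinav.navigation import NavigationEvent


def make_track(points, dt=30.0, kind="mtoc"):
    pts = np.asarray(points, dtype=float)
    return Track(kind=kind, id=0, frames=np.arange(len(pts)),
                 t_s=np.arange(len(pts)) * dt, xy_um=pts)


AXIS = np.array([1.0, 0.0])
OBSTACLE = np.array([[30.0, 0.0, 4.0]])  # at x=30, radius 4


def approach_then_pass(pass_frame, lead=0.0, n=150, dt=30.0, speed=1.0):
    """Straight track toward the obstacle that crosses the pass plane
    (x = 34) at ``pass_frame``; before that it waits at x = 20."""
    xs = np.full(n, 20.0)
    xs[pass_frame:] = 36.0 + np.arange(n - pass_frame) * 0.5
    return make_track(np.c_[xs + lead, np.zeros(n)], dt=dt)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------


def test_distant_path_yields_no_events():
    tr = make_track([(0.0, 20.0), (10.0, 20.0), (20.0, 20.0)])
    events = detect_encounters(tr, tr, tr, OBSTACLE, approach_axis=AXIS)
    assert events == []


def test_encounter_opens_at_first_frame_within_reach():
    # MTOC stops 3 um before the obstacle boundary (x = 23), ahead of it
    pts = [(10.0, 0.0), (16.0, 0.0), (23.0, 0.0), (23.0, 0.0)]
    tr = make_track(pts)
    events = detect_encounters(tr, tr, tr, OBSTACLE, approach_axis=AXIS)
    assert len(events) == 1
    assert events[0].encounter_frame == 2  # first frame within r + 5 um


def test_one_event_per_cell_obstacle_pair():
    pts = [(23.0, 0.0)] * 5  # inside the encounter shell every frame
    tr = make_track(pts)
    events = detect_encounters(tr, tr, tr, OBSTACLE, approach_axis=AXIS)
    assert len(events) == 1


def test_obstacle_behind_is_ignored():
    pts = [(35.5, 0.0)] * 3  # within 5 um of boundary but already past
    tr = make_track(pts)
    assert detect_encounters(tr, tr, tr, OBSTACLE, approach_axis=AXIS) == []


def test_missing_mtoc_track_rejected():
    tr = make_track([(0.0, 0.0), (1.0, 0.0)])
    with pytest.raises(ValueError, match="MTOC"):
        detect_encounters(tr, None, tr, OBSTACLE, approach_axis=AXIS)
    with pytest.raises(ValueError, match="approach_axis"):
        detect_encounters(tr, tr, tr, OBSTACLE)


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------


def _open_event(encounter_frame=0, dt=30.0):
    return NavigationEvent(
        cell_id=0, obstacle_id=0, obstacle_xy_um=np.array([30.0, 0.0]),
        obstacle_radius_um=4.0, axis=AXIS.copy(),
        encounter_frame=encounter_frame, encounter_time_s=encounter_frame * dt,
    )


def test_mtoc_first_success_with_navigation_time():
    mtoc = approach_then_pass(pass_frame=20)  # passes at 600 s
    nucleus = approach_then_pass(pass_frame=30)  # passes at 900 s
    ev = score_event(_open_event(), mtoc, nucleus)
    assert ev.decision == "mtoc_first"
    assert ev.outcome == "success"
    assert ev.navigation_time_s == pytest.approx(600.0)


def test_nucleus_first_decision():
    ev = score_event(
        _open_event(), approach_then_pass(30), approach_then_pass(20)
    )
    assert ev.decision == "nucleus_first"
    assert ev.outcome == "success"  # the MTOC still passed within the window


def test_same_frame_tie_goes_to_mtoc():
    ev = score_event(
        _open_event(), approach_then_pass(20), approach_then_pass(20)
    )
    assert ev.decision == "mtoc_first"


def test_no_pass_after_full_window_is_failure():
    still = make_track([(20.0, 0.0)] * 121)  # 3600 s observed, never passes
    ev = score_event(_open_event(), still, still)
    assert ev.outcome == "failure"
    assert ev.decision == "none" and ev.navigation_time_s is None


def test_short_observation_is_censored():
    still = make_track([(20.0, 0.0)] * 61)  # 1800 s < 55 min window
    ev = score_event(_open_event(), still, still)
    assert ev.outcome == "censored"


def test_pass_after_window_is_failure():
    late = approach_then_pass(pass_frame=115)  # 3450 s > 3300 s window
    observed = make_track([(20.0, 0.0)] * 150)
    ev = score_event(_open_event(), late, observed)
    assert ev.outcome == "failure"


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------


def test_summary_of_21_vs_4_is_84_percent():
    events = []
    for k in range(25):
        mtoc = approach_then_pass(20 if k < 21 else 30)
        nucleus = approach_then_pass(30 if k < 21 else 20)
        events.append(score_event(_open_event(), mtoc, nucleus))
    s = navigation_summary(events)
    assert s["pct_mtoc_first"] == 84.0
    assert s["n_decided"] == 25


def test_all_failures_give_zero_rate_and_no_time():
    still = make_track([(20.0, 0.0)] * 121)
    events = [score_event(_open_event(), still, still) for _ in range(5)]
    s = navigation_summary(events)
    assert s["success_rate_pct"] == 0.0
    assert s["mean_navigation_time_s"] is None


def test_censored_events_excluded_from_rate_denominator():
    still_long = make_track([(20.0, 0.0)] * 121)
    still_short = make_track([(20.0, 0.0)] * 10)
    events = [
        score_event(_open_event(), approach_then_pass(20), approach_then_pass(30)),
        score_event(_open_event(), still_long, still_long),
        score_event(_open_event(), still_short, still_short),
    ]
    s = navigation_summary(events)
    assert s["n_closed"] == 2 and s["n_censored"] == 1
    assert s["success_rate_pct"] == 50.0
    # success + failure rates add to one over non-censored events
    failure_rate = 100.0 * (s["n_closed"] - s["n_success"]) / s["n_closed"]
    assert s["success_rate_pct"] + failure_rate == 100.0


def test_empty_event_list_rejected():
    with pytest.raises(ValueError):
        navigation_summary([])


def test_rigid_rotation_leaves_decision_and_outcome_invariant():
    theta = np.deg2rad(37.0)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mtoc, nucleus = approach_then_pass(20), approach_then_pass(30)
    base = score_event(_open_event(), mtoc, nucleus)
    ev_r = _open_event()
    ev_r.obstacle_xy_um = R @ ev_r.obstacle_xy_um
    ev_r.axis = R @ ev_r.axis
    mtoc_r = make_track(mtoc.xy_um @ R.T)
    nuc_r = make_track(nucleus.xy_um @ R.T)
    rot = score_event(ev_r, mtoc_r, nuc_r)
    assert rot.decision == base.decision
    assert rot.outcome == base.outcome
    assert rot.navigation_time_s == pytest.approx(base.navigation_time_s)


# ----------------------------------------------------------------------
# against the generator
# ----------------------------------------------------------------------


def _scored_events(gt):
    events = []
    for _, r in gt.passages.iterrows():
        i, oi = int(r["cell"]), int(r["obstacle"])
        mtoc, nuc = gt.track("mtoc", i), gt.track("nucleus", i)
        evs = detect_encounters(
            gt.track("cell", i), mtoc, nuc, gt.obstacles[[oi]],
            wound_polygon_um=gt.wound_polygon_t[0], cell_id=i,
        )
        events += [score_event(e, mtoc, nuc) for e in evs]
    return events


def test_detected_encounters_match_generator_records():
    cfg = with_scratch(
        condition_preset("vehicle").replace(
            rng_seed=17, n_cells=30, width_um=380, height_um=380, channels=(),
        ),
        n_frames=160,
    )
    _, gt = generate_scene(cfg)
    assert len(gt.passages) >= 30
    events = _scored_events(gt)
    by_cell = {e.cell_id: e for e in events}
    agree = 0
    for _, r in gt.passages.iterrows():
        e = by_cell.get(int(r["cell"]))
        if e is None:
            continue
        want = {"mtoc": "mtoc_first", "nucleus": "nucleus_first"}.get(
            r["leading"], "none"
        )
        if (
            abs(e.encounter_frame - r["encounter_frame"]) <= 3
            and (e.outcome == "success") == bool(r["success"])
            and (want == "none" or e.decision == want)
        ):
            agree += 1
    assert agree / len(gt.passages) >= 0.9


def test_forced_counts_reproduced_exactly_through_the_pipeline():
    forced = (True,) * 21 + (False,) * 4
    cfg = with_scratch(
        condition_preset("vehicle").replace(
            rng_seed=4, n_cells=25, width_um=350, height_um=350, channels=(),
            mtoc_first_p=forced, navigation_success_p=(True,) * 25,
        ),
        n_frames=160,
    )
    _, gt = generate_scene(cfg)
    s = navigation_summary(_scored_events(gt))
    assert s["pct_mtoc_first"] == 84.0
    assert s["success_rate_pct"] == 100.0


def test_paclitaxel_impairs_navigation_relative_to_vehicle():
    out = {}
    for cond in ("vehicle", "paclitaxel"):
        cfg = with_scratch(
            condition_preset(cond).replace(
                rng_seed=19, n_cells=40, width_um=420, height_um=420, channels=(),
            ),
            n_frames=160,
        )
        _, gt = generate_scene(cfg)
        out[cond] = navigation_summary(_scored_events(gt))
    assert (
        out["paclitaxel"]["success_rate_pct"] < out["vehicle"]["success_rate_pct"]
    )
    assert (
        out["paclitaxel"]["mean_navigation_time_s"]
        > out["vehicle"]["mean_navigation_time_s"]
    )
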