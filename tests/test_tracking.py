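"""Linking, motility metrics, speed statistics and MTOC detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinav import (
    LinkingConfig,
    SceneConfig,
    Track,
    detect_mtoc_foci,
    distance_to_target,
    generate_scene,
    link_frames,
    mtoc_position,
    speed_histogram_fit,
    speed_series,
    track_metrics,
)


def make_track(points, dt=30.0, kind="cell"):
    pts = np.asarray(points, dtype=float)
    return Track(
        kind=kind, id=0, frames=np.arange(len(pts)),
        t_s=np.arange(len(pts)) * dt, xy_um=pts,
    )


# ----------------------------------------------------------------------
# linking
# ----------------------------------------------------------------------


def test_unambiguous_nearest_neighbour_linking():
    dets = [np.array([[0.0, 0.0], [10.0, 0.0]]), np.array([[1.0, 0.0], [9.0, 0.0]])]
    tracks = link_frames(dets, LinkingConfig(max_link_um=5))
    assert len(tracks) == 2
    ends = sorted(tuple(t.xy_um[-1]) for t in tracks)
    assert ends == [(1.0, 0.0), (9.0, 0.0)]
    starts = {tuple(t.xy_um[0]): tuple(t.xy_um[-1]) for t in tracks}
    assert starts[(0.0, 0.0)] == (1.0, 0.0)
    assert starts[(10.0, 0.0)] == (9.0, 0.0)


def test_global_optimum_beats_greedy_assignment():
    # A=(0,0), B=(10,0) -> {(4,0),(6,0)}: optimal is A->4, B->6 (cost 32 vs 72)
    dets = [np.array([[0.0, 0.0], [10.0, 0.0]]), np.array([[4.0, 0.0], [6.0, 0.0]])]
    tracks = link_frames(dets, LinkingConfig(max_link_um=10))
    starts = {tuple(t.xy_um[0]): tuple(t.xy_um[-1]) for t in tracks}
    assert starts[(0.0, 0.0)] == (4.0, 0.0)
    assert starts[(10.0, 0.0)] == (6.0, 0.0)


def test_jump_beyond_gate_terminates_track():
    dets = [np.array([[0.0, 0.0]]), np.array([[25.0, 0.0]])]
    tracks = link_frames(dets, LinkingConfig(max_link_um=10))
    assert len(tracks) == 2
    assert all(len(t) == 1 for t in tracks)


def test_gap_closing_bridges_missing_detection():
    dets = [np.array([[0.0, 0.0]]), np.empty((0, 2)), np.array([[2.0, 0.0]])]
    bridged = link_frames(dets, LinkingConfig(max_link_um=10, max_gap=1))
    assert len(bridged) == 1 and list(bridged[0].frames) == [0, 2]
    broken = link_frames(dets, LinkingConfig(max_link_um=10, max_gap=0))
    assert len(broken) == 2


def _brute_force_cost(a, b, gate):
    """Exhaustive optimum of gated assignment with birth/death cost gate^2."""
    n, m = len(a), len(b)
    best = np.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                d2 = [((a[i] - b[j]) ** 2).sum() for i, j in zip(rows, cols)]
                if any(d > gate**2 for d in d2):
                    continue
                cost = sum(d2) + gate**2 * (n - k + m - k)
                best = min(best, cost)
    return best


def _linked_cost(a, b, gate):
    from epinav.tracking import _assign_pair

    links = _assign_pair(a, b, gate)
    cost = sum(((a[i] - b[j]) ** 2).sum() for i, j in links)
    return cost + gate**2 * (len(a) - len(links) + len(b) - len(links))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(0, 6), m=st.integers(0, 6), seed=st.integers(0, 10_000),
    gate=st.sampled_from([3.0, 8.0, 15.0]),
)
def test_lap_equals_exhaustive_optimum(n, m, seed, gate):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 20, size=(n, 2))
    b = rng.uniform(0, 20, size=(m, 2))
    if n == 0 or m == 0:
        assert _linked_cost(a, b, gate) == gate**2 * (n + m)
        return
    assert _linked_cost(a, b, gate) == pytest.approx(
        _brute_force_cost(a, b, gate), rel=1e-9
    )


# ----------------------------------------------------------------------
# track metrics
# ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "pts,total,disp,mi,included",
    [
        ([(0, 0), (3, 4)], 5.0, 5.0, 1.0, False),
        ([(0, 0), (1, 0), (0, 0)], 2.0, 0.0, 0.0, False),
        ([(0, 0), (9, 0), (9, 12)], 21.0, 15.0, 15.0 / 21.0, True),
    ],
)
def test_track_metric_worked_examples(pts, total, disp, mi, included):
    tm = track_metrics(make_track(pts))
    assert tm.total_distance_um == pytest.approx(total)
    assert tm.displacement_um == pytest.approx(disp)
    assert tm.meandering_index == pytest.approx(mi)
    assert tm.included is included


def test_single_point_track_rejected():
    with pytest.raises(ValueError):
        track_metrics(make_track([(0, 0)]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 30))
def test_meandering_index_bounds(seed, n):
    rng = np.random.default_rng(seed)
    tm = track_metrics(make_track(rng.normal(size=(n, 2)) * 5))
    assert 0.0 <= tm.meandering_index <= 1.0 + 1e-12


def test_mi_is_one_iff_collinear_monotone():
    straight = make_track([(0, 0), (1, 1), (2.5, 2.5), (4, 4)])
    assert track_metrics(straight).meandering_index == pytest.approx(1.0)
    backtrack = make_track([(0, 0), (2, 2), (1, 1), (4, 4)])  # collinear, not monotone
    assert track_metrics(backtrack).meandering_index < 1.0
    bent = make_track([(0, 0), (1, 0), (1, 1)])
    assert track_metrics(bent).meandering_index < 1.0


# ----------------------------------------------------------------------
# speeds
# ----------------------------------------------------------------------


def test_constant_steps_give_constant_speed():
    pts = [(0.7 * k, 0.0) for k in range(11)]
    speeds, windowed = speed_series(make_track(pts), window_s=300.0)
    assert np.allclose(speeds, 1.4)  # 0.7 um / 30 s = 1.4 um/min
    assert windowed[-1] == pytest.approx(7.0)  # ten 0.7 um steps in 5 min


def test_windowed_path_length_equals_direct_summation():
    rng = np.random.default_rng(0)
    pts = np.cumsum(rng.normal(scale=0.5, size=(40, 2)), axis=0)
    tr = make_track(pts)
    _, windowed = speed_series(tr, window_s=240.0)
    steps = np.hypot(*np.diff(pts, axis=0).T)
    for k in range(1, len(tr)):
        expect = sum(
            steps[j]
            for j in range(len(steps))
            if tr.t_s[k] - 240.0 < tr.t_s[j + 1] <= tr.t_s[k]
        )
        assert windowed[k] == pytest.approx(expect)


def test_zero_step_interval_rejected():
    tr = make_track([(0, 0), (1, 0)])
    tr.t_s = np.array([0.0, 0.0])
    with pytest.raises(ValueError):
        speed_series(tr)


def test_degenerate_speeds_flagged():
    fit = speed_histogram_fit([2.0] * 20)
    assert fit["mean"] == 2.0 and fit["sd"] == 0.0 and fit["flagged"]


def test_gaussian_sample_recovers_parameters():
    rng = np.random.default_rng(1)
    fit = speed_histogram_fit(rng.normal(1.4, 0.4, size=10_000), bin_width=0.1)
    assert fit["mean"] == pytest.approx(1.4, abs=0.05)
    assert fit["sd"] == pytest.approx(0.4, abs=0.05)
    assert not fit["flagged"]


def test_bimodal_sample_flagged_as_poor_fit():
    rng = np.random.default_rng(2)
    sample = np.r_[rng.normal(1.0, 0.05, 3000), rng.normal(4.0, 0.05, 3000)]
    fit = speed_histogram_fit(sample, bin_width=0.1)
    assert fit["flagged"] and (np.isnan(fit["r_squared"]) or fit["r_squared"] < 0.8)


def test_too_few_speeds_rejected():
    with pytest.raises(ValueError):
        speed_histogram_fit([1.0] * 5)


# ----------------------------------------------------------------------
# distance to target
# ----------------------------------------------------------------------


def test_linear_approach_normalizes_to_unit_start():
    pts = [(10.0 - k, 0.0) for k in range(11)]
    out = distance_to_target(make_track(pts), np.array([0.0, 0.0]), window_s=300.0)
    assert out["relative_distance"][0] == pytest.approx(1.0)
    assert out["relative_distance"][-1] == pytest.approx(0.0)
    assert np.all(np.diff(out["relative_distance"]) < 0)
    assert not out["flagged"]


def test_stationary_pair_stays_at_unity():
    out = distance_to_target(make_track([(5.0, 0.0)] * 6), np.array([0.0, 0.0]))
    assert np.allclose(out["relative_distance"], 1.0)


def test_zero_initial_distance_flagged():
    out = distance_to_target(make_track([(0.0, 0.0), (1.0, 0.0)]), np.array([0.0, 0.0]))
    assert out["flagged"]
    assert np.isfinite(out["relative_distance"]).all()


def test_engulfing_cells_close_most_of_the_distance():
    """Motility-mode engulfment: relative cell-debris distance ends low."""
    from epinav import with_ablation

    cfg = with_ablation(
        SceneConfig(
            rng_seed=6, n_cells=6, n_frames=30, width_um=260, height_um=260,
            channels=(), modality_dendritic_p=0.0, engulf_success_p=1.0,
        )
    )
    _, gt = generate_scene(cfg)
    finals = []
    for _, row in gt.engulfments.iterrows():
        if row["engulf_frame"] is None or np.isnan(row["engulf_frame"]):
            continue
        i = int(row["cell"])
        tr = gt.track("cell", i)
        out = distance_to_target(
            tr, gt.debris_xy[i], window_s=tr.t_s[-1] - row["ablation_frame"] * 30.0
        )
        finals.append(out["relative_distance"][-1])
    assert finals and np.mean(finals) < 0.3


# ----------------------------------------------------------------------
# MTOC detection and speed recovery
# ----------------------------------------------------------------------


def test_mtoc_detection_subpixel_accuracy(steady_scene):
    cfg, tl, gt = steady_scene
    dets = detect_mtoc_foci(tl.channel("emtb")[0], tl.pixel_size_um)
    assert len(dets) == cfg.n_cells
    for i in range(cfg.n_cells):
        err = np.min(np.hypot(*(dets - gt.mtoc_xy[0, i]).T))
        assert err < 0.5  # one pixel


def test_per_cell_mtoc_is_brightest_focus(steady_scene):
    cfg, tl, gt = steady_scene
    lab = gt.masks[0]
    for i in range(cfg.n_cells):
        x, y = mtoc_position(tl.channel("emtb")[0], lab == i + 1, tl.pixel_size_um)
        assert np.hypot(x - gt.mtoc_xy[0, i, 0], y - gt.mtoc_xy[0, i, 1]) < 0.5


def test_steady_state_speed_recovered_from_images():
    """Detection + linking recovers the configured MTOC speed within 10%."""
    cfg = SceneConfig(
        rng_seed=7, n_cells=5, n_frames=60, width_um=150, height_um=150,
        channels=("emtb",), mtoc_speed_um_min=1.4,
    )
    tl, _ = generate_scene(cfg)
    dets = [
        detect_mtoc_foci(tl.channel("emtb")[t], tl.pixel_size_um)
        for t in range(tl.n_frames)
    ]
    tracks = link_frames(dets, LinkingConfig(max_link_um=5), cfg.frame_interval_s)
    speeds = np.concatenate(
        [speed_series(t)[0] for t in tracks if len(t) >= 20]
    )
    assert np.mean(speeds) == pytest.approx(1.4, rel=0.1)
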