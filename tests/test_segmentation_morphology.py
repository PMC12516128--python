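"""Segmentation, dendrite extraction, dendrite metrics and Sholl analysis."""

import numpy as np
import pytest

from epinav import (
    SceneConfig,
    condition_preset,
    dendrite_metrics,
    extract_dendrites,
    generate_scene,
    segment_cells,
    sholl_condition_summary,
    sholl_profile,
)
from epinav.morphology import DendriteSet, select_timepoints
from epinav.segmentation import CellMask

from conftest import disk_mask, match_gt_cell

PS = 0.5  # um/px used for hand-built images


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------


def _disk_image(shape, centers, radius_px, value=100.0):
    img = np.zeros(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2] = value
    return img


def test_two_disks_give_two_masks_with_disk_areas():
    img = _disk_image((100, 100), [(30, 30), (70, 70)], radius_px=10)
    masks = segment_cells(img, PS, min_area_um2=10)
    assert len(masks) == 2
    expected = np.pi * (10 * PS) ** 2
    for m in masks:
        assert m.area_um2 == pytest.approx(expected, rel=0.05)
    # deterministic labelling by bounding-box (top, left)
    assert masks[0].bbox[0] < masks[1].bbox[0]


def test_blank_image_yields_empty_list_not_error():
    assert segment_cells(np.zeros((50, 50)), PS) == []


def test_uncalibrated_image_rejected():
    with pytest.raises(ValueError, match="calibrat"):
        segment_cells(np.ones((10, 10)), 0.0)


def test_min_area_filter_removes_small_objects():
    img = _disk_image((100, 100), [(30, 30)], radius_px=10)
    img[70:72, 70:72] = 100.0  # 1 um^2 speck
    assert len(segment_cells(img, PS, min_area_um2=10)) == 1
    assert len(segment_cells(img, PS, min_area_um2=0)) == 2


def test_segmentation_iou_against_ground_truth(steady_scene):
    cfg, tl, gt = steady_scene
    masks = segment_cells(tl.channel("cytosol")[0], tl.pixel_size_um)
    assert len(masks) == cfg.n_cells
    for m in masks:
        gi = match_gt_cell(gt, 0, m.centroid_um)
        g = gt.masks[0] == gi + 1
        iou = (m.mask & g).sum() / (m.mask | g).sum()
        assert iou >= 0.8


# ----------------------------------------------------------------------
# dendrite extraction
# ----------------------------------------------------------------------


def _star_scene():
    cfg = SceneConfig(
        rng_seed=11, n_cells=1, n_frames=1, width_um=80, height_um=80,
        dendrites_per_cell=5, dendrite_length_um=12.0,
        gaussian_noise_sd=0.0, poisson_scale=0.0,
    )
    return generate_scene(cfg)


def test_star_cell_recovers_five_arms_of_twelve_um():
    tl, _ = _star_scene()
    cyto = tl.channel("cytosol")[0]
    m = segment_cells(cyto, tl.pixel_size_um)[0]
    ds = extract_dendrites(m, tl.channel("emtb")[0], cyto)
    assert ds.count == 5
    assert np.all(np.abs(ds.lengths_um - 12.0) <= 1.0)
    # skeleton lengths within 10% of generator arm length on noise-free input
    assert np.all(np.abs(ds.lengths_um / 12.0 - 1.0) <= 0.1)


def _bar_cell(ratio):
    """Soma disk + one horizontal bar dendrite with emtb = ratio * cytosol."""
    shape = (60, 120)
    cyto = _disk_image(shape, [(30, 30)], radius_px=10, value=100.0)
    cyto[28:33, 40:90] = 100.0  # 25 um bar
    emtb = np.zeros(shape)
    emtb[cyto > 0] = ratio * 100.0
    mask = CellMask(frame=0, label=1, mask=cyto > 0, pixel_size_um=PS)
    return mask, emtb, cyto


@pytest.mark.parametrize(
    "ratio,expected",
    [(0.6, True), (0.5, False), (0.49, False)],  # strictly greater than 0.5
)
def test_emtb_positive_threshold_is_strict(ratio, expected):
    mask, emtb, cyto = _bar_cell(ratio)
    ds = extract_dendrites(mask, emtb, cyto)
    assert ds.count == 1
    assert ds.dendrites[0].emtb_positive is expected


def test_emtb_positive_is_monotone_in_emtb_intensity():
    mask, emtb, cyto = _bar_cell(0.6)
    ds_lo = extract_dendrites(mask, emtb, cyto)
    ds_hi = extract_dendrites(mask, emtb * 3.0, cyto)
    assert ds_lo.dendrites[0].emtb_positive
    assert ds_hi.dendrites[0].emtb_positive
    assert ds_hi.dendrites[0].ratio > ds_lo.dendrites[0].ratio


def test_soma_only_mask_reports_zero_dendrites_with_warning():
    img = _disk_image((60, 60), [(30, 30)], radius_px=10)
    mask = CellMask(frame=0, label=1, mask=img > 0, pixel_size_um=PS)
    with pytest.warns(UserWarning, match="zero dendrites"):
        ds = extract_dendrites(mask, img, img)
    assert ds.count == 0


def test_emtb_positive_fraction_recovered_from_batch(steady_scene):
    cfg, tl, gt = steady_scene
    cyto, emtb = tl.channel("cytosol")[0], tl.channel("emtb")[0]
    meas, truth = [], []
    for m in segment_cells(cyto, tl.pixel_size_um):
        gi = match_gt_cell(gt, 0, m.centroid_um)
        ds = extract_dendrites(m, emtb, cyto)
        if ds.count != len(gt.dendrite_emtb_positive[gi]):
            continue
        meas.append(ds.emtb_positive_fraction)
        truth.append(gt.dendrite_emtb_positive[gi].mean())
    assert meas, "no cells with matching dendrite counts"
    assert abs(np.mean(meas) - np.mean(truth)) <= 0.05  # within 5 points


# ----------------------------------------------------------------------
# dendrite time-course metrics
# ----------------------------------------------------------------------


def _fake_set(count, length):
    from epinav.morphology import Dendrite

    dend = [
        Dendrite(
            path_um=np.array([[0.0, 0.0], [length, 0.0]]),
            length_um=length, mean_emtb=1.0, mean_cytosol=1.0,
        )
        for _ in range(count)
    ]
    return DendriteSet(
        cell_label=1, frame=0, soma_centroid_um=(0, 0), soma_radius_um=5,
        dendrites=dend,
    )


def test_constant_series_returns_constant_metrics():
    series = [(t * 600.0, _fake_set(5, 12.0)) for t in range(5)]
    assert dendrite_metrics(series) == (5.0, 12.0, 12.0)


def test_counts_average_across_sampled_timepoints():
    series = [(0.0, _fake_set(4, 10.0)), (600.0, _fake_set(6, 14.0))]
    avg_count, avg_len, max_len = dendrite_metrics(series)
    assert avg_count == 5.0
    assert avg_len == 12.0
    assert max_len == 14.0


def test_sampling_interval_skips_intermediate_frames():
    series = [(t * 60.0, _fake_set(4 if t % 10 else 8, 10.0)) for t in range(21)]
    avg_count, _, _ = dendrite_metrics(series, sample_interval_s=600.0)
    assert avg_count == 8.0  # only t=0, 600, 1200 s sampled


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        dendrite_metrics([])


def test_nocodazole_shifts_measured_dendrite_metrics():
    """Depolymerized cells: fewer, longer dendrites (population means)."""
    out = {}
    for cond in ("vehicle", "nocodazole"):
        cfg = condition_preset(cond).replace(
            rng_seed=21, n_cells=6, n_frames=1, width_um=260, height_um=260,
        )
        tl, _ = generate_scene(cfg)
        cyto, emtb = tl.channel("cytosol")[0], tl.channel("emtb")[0]
        counts, lengths, maxima = [], [], []
        for m in segment_cells(cyto, tl.pixel_size_um):
            ds = extract_dendrites(m, emtb, cyto)
            series = [(0.0, ds)]
            c, a, x = dendrite_metrics(series)
            counts.append(c)
            lengths.append(a)
            maxima.append(x)
        out[cond] = (np.mean(counts), np.mean(lengths), np.mean(maxima))
    assert out["nocodazole"][0] < out["vehicle"][0]
    assert out["nocodazole"][1] > out["vehicle"][1]
    assert out["nocodazole"][2] > out["vehicle"][2]


# ----------------------------------------------------------------------
# Sholl analysis
# ----------------------------------------------------------------------


def _mask_from_bars(shape, bars, soma_rc=(100, 100), soma_r=10):
    """Soma disk plus straight bars given as (angle_deg, length_px)."""
    img = _disk_image(shape, [soma_rc], radius_px=soma_r)
    for ang, length in bars:
        a = np.deg2rad(ang)
        for s in np.linspace(0, length, int(length * 3)):
            r = int(round(soma_rc[0] + s * np.sin(a)))
            c = int(round(soma_rc[1] + s * np.cos(a)))
            img[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2] = 100.0
    return CellMask(frame=0, label=1, mask=img > 0, pixel_size_um=PS)


def test_single_straight_dendrite_crossings():
    # 25 um arm: crosses the 10 and 20 um circles, not 30 um
    m = _mask_from_bars((200, 200), [(0, 50)])
    prof = sholl_profile([m] * 5, step_um=10.0)
    by_r = dict(zip(prof.radii_um, prof.crossings))
    assert by_r[10.0] == 5 and by_r[20.0] == 5  # 1 per timepoint, 5 timepoints
    assert by_r.get(30.0, 0) == 0


def test_two_dendrites_cross_first_circle_twice():
    m = _mask_from_bars((200, 200), [(0, 30), (180, 30)])  # two 15 um arms
    prof = sholl_profile([m] * 5, step_um=10.0)
    assert prof.crossings[0] == 10  # 2 crossings x 5 timepoints


def test_requires_five_timepoints():
    m = _mask_from_bars((200, 200), [(0, 30)])
    with pytest.raises(ValueError, match="timepoints"):
        sholl_profile([m] * 3)
    with pytest.raises(ValueError):
        sholl_profile([m] * 5, step_um=0.0)


def test_branched_skeleton_matches_dense_sampling_oracle():
    """Crossing counts equal sign changes of (distance - r) sampled at
    0.05 um along the analytic center-line polylines."""
    bars = [(0, 44), (100, 36), (215, 52)]
    m = _mask_from_bars((240, 240), bars, soma_rc=(120, 120))
    prof = sholl_profile([m] * 5, step_um=10.0)
    # oracle on the analytic arm geometry (arms radiate from the center)
    for k, r in enumerate(prof.radii_um):
        oracle = 0
        for ang, length in bars:
            a = np.deg2rad(ang)
            s = np.arange(0.0, length * PS, 0.05)
            d = np.hypot(s * np.sin(a), s * np.cos(a))
            signs = np.sign(d - r)
            signs = signs[signs != 0]
            oracle += int(np.count_nonzero(np.diff(signs) != 0))
        assert prof.crossings[k] == 5 * oracle, f"radius {r}"


def test_sholl_total_bounded_below_by_long_dendrites(steady_scene):
    cfg, tl, gt = steady_scene
    masks = segment_cells(tl.channel("cytosol")[0], tl.pixel_size_um)
    m = masks[0]
    gi = match_gt_cell(gt, 0, m.centroid_um)
    prof = sholl_profile([m] * 5, step_um=10.0)
    n_long = int((gt.dendrite_lengths_t[gi][0] + cfg.soma_radius_um > 10.0).sum())
    assert prof.crossings[0] >= 5 * n_long >= 5


def test_condition_summary_percentages():
    m = _mask_from_bars((200, 200), [(0, 50)])
    prof = sholl_profile([m] * 5, step_um=10.0)
    summary = sholl_condition_summary([prof])
    assert summary["mean_pct"].sum() == pytest.approx(100.0)
    with pytest.raises(ValueError):
        sholl_condition_summary([])


def test_select_timepoints_even_spacing():
    assert select_timepoints(5) == (0, 1, 2, 3, 4)
    assert select_timepoints(101) == (0, 25, 50, 75, 100)
    with pytest.raises(ValueError):
        select_timepoints(3)
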