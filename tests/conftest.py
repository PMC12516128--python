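"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from epinav import SceneConfig, WoundSpec, condition_preset, generate_scene
from epinav.segmentation import CellMask


@pytest.fixture(scope="session")
def steady_scene():
    """Small rendered steady-state scene: 3 ramified cells, 6 frames."""
    cfg = SceneConfig(rng_seed=5, n_cells=3, n_frames=6, width_um=140, height_um=140)
    tl, gt = generate_scene(cfg)
    return cfg, tl, gt


@pytest.fixture(scope="session")
def band_wound_scene():
    """Rendered scratch scene with a band-shaped wound crossing all lanes:
    used for margin counting and phenotype recovery."""
    H = 330.0
    band = ((190.0, 10.0), (245.0, 10.0), (245.0, H - 10.0), (190.0, H - 10.0))
    cfg = condition_preset("vehicle").replace(
        rng_seed=12,
        n_cells=8,
        width_um=270.0,
        height_um=H,
        frame_interval_s=120.0,
        n_frames=65,
        wound=WoundSpec(polygon_um=band, closure_rate_per_h=0.15),
        phenotype_engulfing_p=0.35,
        phenotype_stretching_p=0.3,
        unique_lanes=True,
        cell_speed_um_min=2.0,
    )
    tl, gt = generate_scene(cfg)
    return cfg, tl, gt


def make_mask(shape, pixels, pixel_size_um=0.5, frame=0, label=1) -> CellMask:
    """CellMask from explicit (row, col) pixel lists."""
    m = np.zeros(shape, dtype=bool)
    rows, cols = zip(*pixels)
    m[list(rows), list(cols)] = True
    return CellMask(frame=frame, label=label, mask=m, pixel_size_um=pixel_size_um)


def disk_mask(shape, center_rc, radius_px, pixel_size_um=0.5, label=1) -> CellMask:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2
    return CellMask(frame=0, label=label, mask=m, pixel_size_um=pixel_size_um)


def match_gt_cell(gt, frame: int, centroid_um) -> int:
    """Index of the ground-truth cell nearest a measured centroid."""
    c = np.asarray(centroid_um)
    return int(np.argmin(np.hypot(*(gt.cell_xy[frame] - c).T)))
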