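"""Wound ROIs, margin cell counts, closure tracking and phenotype scoring.

The wound margin is the rectangular region used to count responding
cells: 150 um wide and 1.2x the wound length long, centered on the wound
centroid with its long axis along the wound's major axis.  A cell counts
as "in the margin" only when strictly more than half of its mask area
lies inside the rectangle.

At a fixed evaluation time (2 h by default) cells in the margin are
scored as *engulfing* (cell body inside the wound with a rounded,
phagocytic morphology — operationalized as circularity 4*pi*A/P^2 above a
threshold), *stretching* (soma outside but at least one dendrite tip
inside the wound), or *neither*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.measure import perimeter as _mask_perimeter

from .morphology import DendriteSet
from .segmentation import CellMask

__all__ = [
    "WoundROI",
    "build_margin_roi",
    "count_cells_in_margin",
    "wound_area_series",
    "score_phenotypes",
    "MARGIN_WIDTH_UM",
    "MARGIN_LENGTH_FACTOR",
]

MARGIN_WIDTH_UM = 150.0
MARGIN_LENGTH_FACTOR = 1.2


@dataclass
class WoundROI:
    wound_polygon_um: np.ndarray  # (n, 2) (x, y)
    axis: np.ndarray  # unit major-axis vector
    wound_length_um: float  # extent along the major axis
    center_um: np.ndarray  # wound centroid
    frame: int = 0
    axis_degenerate: bool = False  # no unique major axis (e.g. circle)

    @property
    def margin_length_um(self) -> float:
        return MARGIN_LENGTH_FACTOR * self.wound_length_um

    @property
    def margin_width_um(self) -> float:
        return MARGIN_WIDTH_UM

    @property
    def margin_area_um2(self) -> float:
        return self.margin_length_um * self.margin_width_um

    def margin_corners_um(self) -> np.ndarray:
        u = self.axis
        p = np.array([-u[1], u[0]])
        hl, hw = 0.5 * self.margin_length_um, 0.5 * self.margin_width_um
        c = self.center_um
        return np.array(
            [c + hl * u + hw * p, c - hl * u + hw * p,
             c - hl * u - hw * p, c + hl * u - hw * p]
        )

    def contains_points(self, xy_um: np.ndarray) -> np.ndarray:
        """Boolean in-rectangle test for (n, 2) points (closed rectangle)."""
        xy = np.asarray(xy_um, dtype=float) - self.center_um
        u = self.axis
        p = np.array([-u[1], u[0]])
        a = xy @ u
        b = xy @ p
        return (np.abs(a) <= 0.5 * self.margin_length_um + 1e-9) & (
            np.abs(b) <= 0.5 * self.margin_width_um + 1e-9
        )


def build_margin_roi(wound_polygon_um: np.ndarray, frame: int = 0) -> WoundROI:
    """Margin rectangle from a wound outline.

    The major axis is the principal axis of the polygon vertices; for a
    degenerate (near-circular) vertex cloud the principal vector with the
    smallest angle to the x-axis is chosen and the ROI flagged.
    """
    v = np.asarray(wound_polygon_um, dtype=float)
    if v.ndim != 2 or len(v) < 3:
        raise ValueError("wound polygon needs at least 3 vertices")
    poly = Polygon(v)
    if poly.area == 0:
        raise ValueError("wound polygon has zero area")
    centered = v - v.mean(axis=0)
    cov = centered.T @ centered / len(v)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(np.isclose(evals[0], evals[1], rtol=1e-6))
    if degenerate:
        # tie rule: principal vector closest to the x-axis
        angles = np.abs(np.arctan2(evecs[1], evecs[0]))
        angles = np.minimum(angles, np.pi - angles)
        u = evecs[:, int(np.argmin(angles))]
    else:
        u = evecs[:, int(np.argmax(evals))]
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    proj = v @ u
    length = float(proj.max() - proj.min())
    center = np.asarray(poly.centroid.coords[0])
    return WoundROI(
        wound_polygon_um=v,
        axis=u,
        wound_length_um=length,
        center_um=center,
        frame=frame,
        axis_degenerate=degenerate,
    )


def count_cells_in_margin(
    masks_per_frame: list[list[CellMask]], roi: WoundROI
) -> dict:
    """Cells per frame with strictly more than 50% of their area in the
    margin rectangle, normalized to the count at the first frame.

    A zero count at time 0 normalizes by 1 and flags the series.
    """
    counts = []
    for masks in masks_per_frame:
        n = 0
        for m in masks:
            inside = roi.contains_points(m.pixel_xy_um())
            if inside.mean() > 0.5:  # strictly greater
                n += 1
        counts.append(n)
    counts = np.asarray(counts)
    flagged = counts[0] == 0 if len(counts) else True
    norm = counts[0] if len(counts) and counts[0] > 0 else 1
    return dict(
        counts=counts, normalized=counts / norm, flagged_zero_t0=bool(flagged)
    )


def wound_area_series(polygons_um: list[np.ndarray]) -> np.ndarray:
    """Polygon areas normalized to the time-0 area."""
    if not polygons_um:
        raise ValueError("no wound polygons given")
    areas = np.array([Polygon(np.asarray(p)).area for p in polygons_um])
    if areas[0] == 0:
        raise ValueError("time-0 wound area is zero")
    return areas / areas[0]


def _circularity(mask: np.ndarray) -> float:
    area = float(mask.sum())
    per = float(_mask_perimeter(mask, neighborhood=4))
    if per == 0:
        return 1.0
    return 4.0 * np.pi * area / per**2


def score_phenotypes(
    masks: list[CellMask],
    dendrite_sets: list[Optional[DendriteSet]],
    wound_polygon_um: np.ndarray,
    roi: WoundROI,
    round_threshold: float = 0.6,
) -> pd.DataFrame:
    """Score margin cells as engulfing / stretching / neither.

    ``engulfing``: cell-body centroid inside the wound polygon and mask
    circularity above ``round_threshold``.  ``stretching``: centroid
    outside the wound but at least one dendrite tip inside.  Denominators
    are the cells in the margin ROI (the >50 % area rule).
    """
    if wound_polygon_um is None:
        raise ValueError("wound polygon required for phenotype scoring")
    poly = Polygon(np.asarray(wound_polygon_um))
    rows = []
    for m, ds in zip(masks, dendrite_sets):
        in_margin = bool(roi.contains_points(m.pixel_xy_um()).mean() > 0.5)
        cx, cy = m.centroid_um
        centroid_in_wound = poly.contains(Point(cx, cy))
        circ = _circularity(m.mask)
        if centroid_in_wound and circ > round_threshold:
            label = "engulfing"
        elif not centroid_in_wound and ds is not None and any(
            poly.contains(Point(*d.tip_um)) for d in ds.dendrites
        ):
            label = "stretching"
        else:
            label = "neither"
        rows.append(
            dict(
                label_id=m.label,
                in_margin=in_margin,
                circularity=circ,
                centroid_in_wound=bool(centroid_in_wound),
                phenotype=label,
            )
        )
    df = pd.DataFrame(rows)
    return df
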