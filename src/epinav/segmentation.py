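"""Cell segmentation from the cytosolic reporter channel.

Cells are thresholded per frame (Otsu by default), connected components
are labelled and small objects removed.  Labelling order is deterministic:
masks are numbered by the (top, left) corner of their bounding box, so a
re-run on the same image always yields the same ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

__all__ = ["CellMask", "segment_cells", "THRESHOLD_METHODS"]

THRESHOLD_METHODS = ("otsu", "li", "yen", "mean")
_THRESH_FUN = {
    "otsu": filters.threshold_otsu,
    "li": filters.threshold_li,
    "yen": filters.threshold_yen,
    "mean": filters.threshold_mean,
}


@dataclass
class CellMask:
    """One connected cell mask in one frame."""

    frame: int
    label: int
    mask: np.ndarray  # boolean, full image size
    pixel_size_um: float
    bbox: tuple[int, int, int, int] = field(init=False)  # (top, left, bottom, right)
    centroid_rc: tuple[float, float] = field(init=False)
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("empty cell mask")
        rows, cols = np.nonzero(self.mask)
        self.bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
        self.centroid_rc = (float(rows.mean()), float(cols.mean()))
        self.area_px = int(len(rows))

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def centroid_um(self) -> tuple[float, float]:
        """(x, y) centroid in micrometres."""
        r, c = self.centroid_rc
        return (c * self.pixel_size_um, r * self.pixel_size_um)

    def pixel_xy_um(self) -> np.ndarray:
        """(n, 2) pixel-center coordinates in micrometres (x, y)."""
        rows, cols = np.nonzero(self.mask)
        return np.c_[cols, rows] * self.pixel_size_um


def segment_cells(
    frame_image: np.ndarray,
    pixel_size_um: float,
    threshold_method: str = "otsu",
    min_area_um2: float = 30.0,
    frame: int = 0,
) -> list[CellMask]:
    """Threshold one channel image and return per-cell masks.

    A blank (constant) image yields an empty list; a missing or
    non-positive calibration is rejected.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("image must be calibrated (pixel_size_um > 0)")
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    if threshold_method not in _THRESH_FUN:
        raise ValueError(
            f"unknown threshold_method {threshold_method!r}; "
            f"expected one of {THRESHOLD_METHODS}"
        )
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.ptp(img) == 0:
        return []
    thr = _THRESH_FUN[threshold_method](img)
    binary = img > thr
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if region.area * pixel_size_um**2 < min_area_um2:
            continue
        mask = labels == region.label
        out.append((region.bbox[0], region.bbox[1], mask))
    out.sort(key=lambda t: (t[0], t[1]))
    return [
        CellMask(frame=frame, label=k + 1, mask=m, pixel_size_um=pixel_size_um)
        for k, (_, _, m) in enumerate(out)
    ]
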