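"""Detection linking and motility metrics.

Per-frame detections (cells, MTOC foci, nuclei) are linked into tracks by
optimal one-to-one assignment per frame pair — the linear-assignment
(LAP) approach standard in particle tracking.  Linking cost is squared
Euclidean distance; a detection farther than ``max_link_um`` from every
candidate starts or terminates a track (birth/death cost
``max_link_um**2``), and broken tracks are bridged across gaps of up to
``max_gap`` missing frames.

Motility metrics follow the conventions used for wound-response movies:
total distance is the summed step length, displacement the first-to-last
distance, the meandering index their ratio (1 = perfectly straight), and
cells with displacement below 10 um are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit, linear_sum_assignment
from skimage.feature import peak_local_max

__all__ = [
    "Track",
    "LinkingConfig",
    "link_frames",
    "track_metrics",
    "TrackMetrics",
    "speed_series",
    "speed_histogram_fit",
    "distance_to_target",
    "detect_mtoc_foci",
    "mtoc_position",
]

_BIG = 1e12


@dataclass
class Track:
    """Time-ordered positions of one entity (cell, MTOC or nucleus)."""

    kind: str
    id: int
    frames: np.ndarray
    t_s: np.ndarray
    xy_um: np.ndarray  # (n, 2) as (x, y)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")
        if len(self.frames) != len(self.xy_um):
            raise ValueError("frames and coordinates disagree in length")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def spans(self, n_frames: int) -> bool:
        """True when the track covers the whole movie."""
        return self.frames[0] == 0 and self.frames[-1] == n_frames - 1


@dataclass(frozen=True)
class LinkingConfig:
    max_link_um: float = 10.0
    max_gap: int = 2

    def __post_init__(self) -> None:
        if self.max_link_um <= 0:
            raise ValueError("max_link_um must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


# ----------------------------------------------------------------------
# LAP linking
# ----------------------------------------------------------------------


def _assign_pair(
    a: np.ndarray, b: np.ndarray, max_link_um: float
) -> list[tuple[int, int]]:
    """Optimal gated one-to-one assignment between two detection sets.

    Minimizes total squared distance with an alternative cost of
    ``max_link_um**2`` for leaving a detection unmatched; equals the
    exhaustive-enumeration optimum.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    alt = max_link_um**2
    size = n + m
    M = np.full((size, size), _BIG)
    M[:n, :m] = np.where(d2 <= alt, d2, _BIG)
    M[:n, m:][np.arange(n), np.arange(n)] = alt  # deaths
    M[n:, :m][np.arange(m), np.arange(m)] = alt  # births
    M[n:, m:] = 0.0  # dummy-dummy
    rows, cols = linear_sum_assignment(M)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and M[i, j] < _BIG
    ]


def link_frames(
    detections_per_frame: Sequence[np.ndarray],
    config: LinkingConfig = LinkingConfig(),
    frame_interval_s: float = 30.0,
    kind: str = "cell",
) -> list[Track]:
    """Link per-frame centroid lists into tracks, with gap closing."""
    dets = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections_per_frame]
    T = len(dets)
    # segments as lists of (frame, index)
    segments: list[list[tuple[int, int]]] = []
    open_by_idx: dict[int, int] = {}  # detection idx in prev frame -> segment id
    for t in range(T):
        new_open: dict[int, int] = {}
        if t == 0 or not open_by_idx:
            links = []
        else:
            prev_idx = sorted(open_by_idx)
            a = dets[t - 1][prev_idx]
            links = _assign_pair(a, dets[t], config.max_link_um)
            for ia, j in links:
                seg = open_by_idx[prev_idx[ia]]
                segments[seg].append((t, j))
                new_open[j] = seg
        linked_j = {j for _, j in links}
        for j in range(len(dets[t])):
            if j not in linked_j:
                segments.append([(t, j)])
                new_open[j] = len(segments) - 1
        open_by_idx = new_open

    # gap closing between segment ends and starts
    if config.max_gap > 0 and len(segments) > 1:
        merged = _close_gaps(segments, dets, config)
    else:
        merged = segments

    tracks = []
    for k, seg in enumerate(merged):
        frames = np.array([f for f, _ in seg])
        xy = np.array([dets[f][j] for f, j in seg])
        tracks.append(
            Track(
                kind=kind,
                id=k,
                frames=frames,
                t_s=frames * frame_interval_s,
                xy_um=xy,
            )
        )
    return tracks


def _close_gaps(segments, dets, config: LinkingConfig):
    ends = [(s[-1][0], dets[s[-1][0]][s[-1][1]], k) for k, s in enumerate(segments)]
    starts = [(s[0][0], dets[s[0][0]][s[0][1]], k) for k, s in enumerate(segments)]
    cand_rows, cand_cols, costs = [], [], []
    for ei, (fe, pe, ke) in enumerate(ends):
        for si, (fs, ps, ks) in enumerate(starts):
            if ks == ke:
                continue
            gap = fs - fe - 1
            if 1 <= gap <= config.max_gap:
                d2 = float(((pe - ps) ** 2).sum())
                if d2 <= config.max_link_um**2:
                    cand_rows.append(ei)
                    cand_cols.append(si)
                    costs.append(d2)
    if not costs:
        return segments
    n = len(segments)
    M = np.full((2 * n, 2 * n), _BIG)
    alt = config.max_link_um**2
    for r, c, v in zip(cand_rows, cand_cols, costs):
        M[r, c] = v
    M[:n, n:][np.arange(n), np.arange(n)] = alt
    M[n:, :n][np.arange(n), np.arange(n)] = alt
    M[n:, n:] = 0.0
    rows, cols = linear_sum_assignment(M)
    succ: dict[int, int] = {}
    for r, c in zip(rows, cols):
        if r < n and c < n and M[r, c] < _BIG:
            succ[r] = c
    heads = set(range(n)) - set(succ.values())
    merged = []
    for h in sorted(heads):
        seg = list(segments[h])
        k = h
        while k in succ:
            k = succ[k]
            seg.extend(segments[k])
        merged.append(seg)
    return merged


# ----------------------------------------------------------------------
# motility metrics
# ----------------------------------------------------------------------


@dataclass
class TrackMetrics:
    total_distance_um: float
    displacement_um: float
    meandering_index: float
    included: bool  # displacement >= 10 um
    degenerate: bool = False  # zero path length (MI set to 0 by convention)


def track_metrics(track: Track, min_displacement_um: float = 10.0) -> TrackMetrics:
    """Total distance, displacement and meandering index of one track."""
    if len(track) < 2:
        raise ValueError("track metrics need at least two points")
    steps = np.diff(track.xy_um, axis=0)
    total = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    disp = float(np.hypot(*(track.xy_um[-1] - track.xy_um[0])))
    degenerate = total == 0.0
    mi = 0.0 if degenerate else disp / total
    return TrackMetrics(
        total_distance_um=total,
        displacement_um=disp,
        meandering_index=mi,
        included=disp >= min_displacement_um,
        degenerate=degenerate,
    )


def speed_series(
    track: Track, window_s: Optional[float] = None
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-step speeds (um/min) and, optionally, the path length traveled
    within a trailing window ``(t - window_s, t]`` at each timepoint."""
    if len(track) < 2:
        raise ValueError("speed series needs at least two points")
    dt = np.diff(track.t_s)
    if np.any(dt <= 0):
        raise ValueError("zero or negative step interval")
    steps = np.hypot(*np.diff(track.xy_um, axis=0).T)
    speeds = steps / dt * 60.0
    windowed = None
    if window_s is not None:
        if window_s > track.duration_s:
            raise ValueError("window_s exceeds the track duration")
        windowed = np.zeros(len(track))
        for k in range(1, len(track)):
            t = track.t_s[k]
            sel = (track.t_s[1:] > t - window_s) & (track.t_s[1:] <= t)
            windowed[k] = steps[sel].sum()
    return speeds, windowed


def speed_histogram_fit(
    speeds: Sequence[float], bin_width: float = 0.2
) -> dict:
    """Frequency histogram of speeds with a least-squares Gaussian fit.

    Returns the histogram, fitted mean and sd, and a flag when the fit is
    degenerate (all speeds equal) or poor (R^2 < 0.8).
    """
    speeds = np.asarray(list(speeds), dtype=float)
    if len(speeds) < 10:
        raise ValueError("need at least 10 speeds for a histogram fit")
    if np.ptp(speeds) == 0:
        return dict(
            bin_centers=np.array([speeds[0]]),
            counts=np.array([len(speeds)]),
            mean=float(speeds[0]),
            sd=0.0,
            r_squared=np.nan,
            flagged=True,
        )
    lo = np.floor(speeds.min() / bin_width) * bin_width
    hi = np.ceil(speeds.max() / bin_width) * bin_width + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    p0 = [counts.max(), float(speeds.mean()), float(speeds.std()) or bin_width]
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=20000)
        fit = gauss(centers, *popt)
        ss_res = float(((counts - fit) ** 2).sum())
        ss_tot = float(((counts - counts.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        mu, sd = float(popt[1]), abs(float(popt[2]))
        flagged = not np.isfinite(r2) or r2 < 0.8
    except RuntimeError:
        mu, sd, r2, flagged = float(speeds.mean()), float(speeds.std()), np.nan, True
    return dict(
        bin_centers=centers, counts=counts, mean=mu, sd=sd, r_squared=r2,
        flagged=flagged,
    )


def distance_to_target(
    track: Track,
    target_xy_um: np.ndarray,
    window_s: Optional[float] = None,
    eps_um: float = 0.1,
) -> dict:
    """Distance to a fixed point or per-frame target series, normalized to
    the distance at the window start (1.0 at t = -window)."""
    target = np.asarray(target_xy_um, dtype=float)
    if target.ndim == 1:
        target = np.tile(target, (len(track), 1))
    if len(target) != len(track):
        raise ValueError("target series must be defined on the track's frames")
    d = np.hypot(*(track.xy_um - target).T)
    if window_s is not None:
        t_end = track.t_s[-1]
        sel = track.t_s >= t_end - window_s
    else:
        sel = np.ones(len(track), dtype=bool)
    dw = d[sel]
    flagged = dw[0] < eps_um
    norm = max(dw[0], eps_um)
    return dict(
        t_s=track.t_s[sel] - track.t_s[sel][0],
        relative_distance=dw / norm,
        flagged=flagged,
    )


# ----------------------------------------------------------------------
# MTOC detection
# ----------------------------------------------------------------------


def _com_refine(img: np.ndarray, r: int, c: int, half: int = 3) -> tuple[float, float]:
    r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
    w = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
    if w.sum() <= 0:
        return float(r), float(c)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    return float((w * rows).sum() / w.sum()), float((w * cols).sum() / w.sum())


def detect_mtoc_foci(
    emtb_image: np.ndarray,
    pixel_size_um: float,
    min_separation_um: float = 8.0,
    threshold_rel: float = 0.5,
) -> np.ndarray:
    """Detect bright EMTB foci (MTOC candidates) in one frame.

    A 3-px median prefilter suppresses shot noise; local maxima above
    ``threshold_rel`` of the frame maximum are kept and refined to
    sub-pixel precision by intensity-weighted centre of mass.  Returns
    (n, 2) positions as (x_um, y_um).
    """
    if pixel_size_um <= 0:
        raise ValueError("image must be calibrated")
    img = ndimage.median_filter(np.asarray(emtb_image, dtype=float), size=3)
    bg = float(np.median(img))
    peak_img = img - bg
    if peak_img.max() <= 0:
        return np.empty((0, 2))
    md = max(1, int(round(min_separation_um / pixel_size_um)))
    peaks = peak_local_max(
        peak_img, min_distance=md, threshold_abs=threshold_rel * peak_img.max()
    )
    out = []
    for r, c in peaks:
        rr, cc = _com_refine(img, int(r), int(c))
        out.append((cc * pixel_size_um, rr * pixel_size_um))
    return np.asarray(out).reshape(-1, 2)


def mtoc_position(
    emtb_image: np.ndarray, mask: np.ndarray, pixel_size_um: float
) -> tuple[float, float]:
    """MTOC of one cell: the brightest (median-filtered) EMTB pixel inside
    the cell mask, refined by centre of mass.  Returns (x_um, y_um)."""
    img = ndimage.median_filter(np.asarray(emtb_image, dtype=float), size=3)
    masked = np.where(mask, img, -np.inf)
    r, c = np.unravel_index(int(np.argmax(masked)), masked.shape)
    rr, cc = _com_refine(img, r, c)
    return (cc * pixel_size_um, rr * pixel_size_um)
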