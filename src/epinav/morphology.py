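"""Dendrite extraction, dendrite metrics and Sholl profiles.

A ramified cell is decomposed into a soma — the maximal inscribed disk of
its mask — and skeleton branches running from the soma boundary to
endpoint tips.  Each root keeps its longest root-to-tip path as a primary
dendrite; side branches count separately only when at least
``min_branch_um`` long (default 2 um), which suppresses skeleton spurs.

A dendrite is microtubule-positive when the mean EMTB reporter intensity
along its path, divided by the mean cytosolic reporter intensity, is
strictly greater than 0.5.

Sholl profiles count skeleton crossings of concentric circles in 10 um
steps around the soma centroid, summed over a fixed number of sampled
timepoints (five by default, evenly spaced through the movie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .segmentation import CellMask

__all__ = [
    "Dendrite",
    "DendriteSet",
    "ShollProfile",
    "extract_dendrites",
    "dendrite_metrics",
    "sholl_profile",
    "sholl_condition_summary",
    "select_timepoints",
]

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Dendrite:
    path_um: np.ndarray  # (n, 2) (x, y) from root toward tip
    length_um: float
    mean_emtb: float
    mean_cytosol: float

    @property
    def ratio(self) -> float:
        return self.mean_emtb / self.mean_cytosol if self.mean_cytosol > 0 else np.inf

    @property
    def emtb_positive(self) -> bool:
        return self.ratio > 0.5  # strictly greater

    @property
    def tip_um(self) -> np.ndarray:
        return self.path_um[-1]


@dataclass
class DendriteSet:
    cell_label: int
    frame: int
    soma_centroid_um: tuple[float, float]  # (x, y)
    soma_radius_um: float
    dendrites: list[Dendrite]

    @property
    def count(self) -> int:
        return len(self.dendrites)

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([d.length_um for d in self.dendrites])

    @property
    def emtb_positive_fraction(self) -> float:
        if not self.dendrites:
            return np.nan
        return float(np.mean([d.emtb_positive for d in self.dendrites]))


@dataclass
class ShollProfile:
    cell_label: int
    radii_um: np.ndarray
    crossings: np.ndarray  # summed over timepoints, non-negative ints
    timepoints: tuple[int, ...]

    @property
    def total(self) -> int:
        return int(self.crossings.sum())


# ----------------------------------------------------------------------
# skeleton graph utilities
# ----------------------------------------------------------------------


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    rows, cols = np.nonzero(skel)
    pts = set(zip(rows.tolist(), cols.tolist()))
    G.add_nodes_from(pts)
    for r, c in pts:
        for dr, dc in _NBRS:
            q = (r + dr, c + dc)
            if q in pts and not G.has_edge((r, c), q):
                G.add_edge((r, c), q, weight=float(np.hypot(dr, dc)))
    return G


def _skeleton_polylines(G: nx.Graph) -> list[np.ndarray]:
    """Decompose a skeleton graph into polylines between nodes of
    degree != 2 (plus simple cycles), each as an (n, 2) array of (row, col)."""
    out = []
    seen = set()
    anchors = [n for n in G.nodes if G.degree(n) != 2]
    for a in anchors:
        for b in G.neighbors(a):
            if frozenset((a, b)) in seen:
                continue
            path = [a, b]
            seen.add(frozenset((a, b)))
            while G.degree(path[-1]) == 2:
                nxts = [q for q in G.neighbors(path[-1]) if q != path[-2]]
                if not nxts:
                    break
                path.append(nxts[0])
                seen.add(frozenset((path[-2], path[-1])))
            out.append(np.asarray(path, dtype=float))
    # pure cycles with all-degree-2 nodes
    for comp in nx.connected_components(G):
        comp = list(comp)
        if all(G.degree(n) == 2 for n in comp) and comp:
            edges_in = {frozenset(e) for e in G.edges(comp)}
            if edges_in & seen:
                continue
            cyc = nx.find_cycle(G, comp[0])
            path = [cyc[0][0]] + [e[1] for e in cyc]
            for e in cyc:
                seen.add(frozenset(e))
            out.append(np.asarray(path, dtype=float))
    return out


def _arc_length_px(path_rc: np.ndarray) -> float:
    d = np.diff(path_rc, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _soma(mask: np.ndarray) -> tuple[tuple[float, float], float]:
    """Center (row, col) and radius (px) of the maximal inscribed disk."""
    dist = ndimage.distance_transform_edt(mask)
    idx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return (float(idx[0]), float(idx[1])), float(dist[idx])


# ----------------------------------------------------------------------
# dendrite extraction
# ----------------------------------------------------------------------


def extract_dendrites(
    mask: CellMask,
    emtb_image: np.ndarray,
    cytosol_image: np.ndarray,
    min_branch_um: float = 2.0,
) -> DendriteSet:
    """Skeleton branches from the soma boundary to tips, with per-branch
    EMTB/cytosol intensity ratios."""
    ps = mask.pixel_size_um
    (sr, sc), soma_r_px = _soma(mask.mask)
    skel = skeletonize(mask.mask)
    G = _skeleton_graph(skel)
    # soma interior (dilated by 1 px) is not dendrite territory
    outside = [
        n for n in G.nodes if np.hypot(n[0] - sr, n[1] - sc) > soma_r_px + 1.0
    ]
    sub = G.subgraph(outside)
    dendrites: list[Dendrite] = []
    emtb = np.asarray(emtb_image, dtype=float)
    cyto = np.asarray(cytosol_image, dtype=float)

    for comp_nodes in nx.connected_components(sub):
        comp = sub.subgraph(comp_nodes)
        root = min(comp_nodes, key=lambda n: np.hypot(n[0] - sr, n[1] - sc))
        # only arbors attached to the soma count as dendrites
        if np.hypot(root[0] - sr, root[1] - sc) > soma_r_px + 3.0:
            continue
        dist, paths = nx.single_source_dijkstra(comp, root, weight="weight")
        endpoints = [n for n in comp_nodes if comp.degree(n) <= 1 and n != root]
        if not endpoints:
            endpoints = [max(dist, key=dist.get)]
        endpoints.sort(key=lambda n: -dist[n])
        claimed: dict = {}
        primary_tip = endpoints[0]
        path = paths[primary_tip]
        for n in path:
            claimed[n] = dist[n]
        dendrites.append(_make_dendrite(path, ps, emtb, cyto, skel.shape))
        for tip in endpoints[1:]:
            p = paths[tip]
            # walk from tip toward root until the claimed arbor is reached
            k = len(p) - 1
            while k >= 0 and p[k] not in claimed:
                k -= 1
            junction_idx = max(k, 0)
            branch = p[junction_idx:]
            blen = (dist[tip] - dist[p[junction_idx]]) * ps
            if blen >= min_branch_um and len(branch) >= 2:
                for n in branch:
                    claimed.setdefault(n, dist[n])
                dendrites.append(_make_dendrite(branch, ps, emtb, cyto, skel.shape))

    if not dendrites and mask.area_um2 > 0:
        warnings.warn(
            f"cell {mask.label}: no skeleton outside the soma disk; "
            "reporting zero dendrites",
            stacklevel=2,
        )
    return DendriteSet(
        cell_label=mask.label,
        frame=mask.frame,
        soma_centroid_um=(sc * ps, sr * ps),
        soma_radius_um=soma_r_px * ps,
        dendrites=dendrites,
    )


def _make_dendrite(path_nodes, ps, emtb, cyto, shape) -> Dendrite:
    path_rc = np.asarray(path_nodes, dtype=float)
    length = _arc_length_px(path_rc) * ps
    sel = np.zeros(shape, dtype=bool)
    rr = path_rc[:, 0].astype(int)
    cc = path_rc[:, 1].astype(int)
    sel[rr, cc] = True
    sel = ndimage.binary_dilation(sel, structure=np.ones((3, 3), dtype=bool))
    return Dendrite(
        path_um=path_rc[:, ::-1] * ps,  # (row, col) -> (x, y)
        length_um=length,
        mean_emtb=float(emtb[sel].mean()),
        mean_cytosol=float(cyto[sel].mean()),
    )


# ----------------------------------------------------------------------
# dendrite time-course metrics
# ----------------------------------------------------------------------


def dendrite_metrics(
    series: list[tuple[float, DendriteSet]],
    sample_interval_s: float = 600.0,
) -> tuple[float, float, float]:
    """(avg_count, avg_length_um, max_length_um) over a time course.

    Dendrites are counted and measured at timepoints spaced
    ``sample_interval_s`` apart (every 10 min by default); counts and
    per-timepoint mean lengths are averaged, and the overall maximum
    length across sampled timepoints is reported.
    """
    if not series:
        raise ValueError("empty dendrite time series")
    times = np.array([t for t, _ in series])
    t_end = times.max()
    sample_times = np.arange(0.0, t_end + 1e-9, sample_interval_s)
    idx = sorted({int(np.argmin(np.abs(times - st))) for st in sample_times})
    counts, mean_lengths, max_len = [], [], 0.0
    for k in idx:
        ds = series[k][1]
        counts.append(ds.count)
        if ds.count:
            mean_lengths.append(float(ds.lengths_um.mean()))
            max_len = max(max_len, float(ds.lengths_um.max()))
    avg_len = float(np.mean(mean_lengths)) if mean_lengths else 0.0
    return float(np.mean(counts)), avg_len, max_len


def select_timepoints(n_frames: int, n_select: int = 5) -> tuple[int, ...]:
    """Evenly spaced frame indices used for Sholl sampling."""
    if n_frames < n_select:
        raise ValueError(f"need at least {n_select} frames, got {n_frames}")
    return tuple(int(round(i)) for i in np.linspace(0, n_frames - 1, n_select))


# ----------------------------------------------------------------------
# Sholl analysis
# ----------------------------------------------------------------------


def sholl_profile(
    masks: list[CellMask],
    step_um: float = 10.0,
    n_timepoints_required: int = 5,
) -> ShollProfile:
    """Sholl crossings of the skeleton, summed over sampled timepoints.

    For each timepoint the mask skeleton is decomposed into polylines and
    circle crossings are counted as sign changes of (distance - r) along
    each polyline, with on-circle points inheriting the previous sign.
    """
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    if len(masks) < n_timepoints_required:
        raise ValueError(
            f"Sholl analysis needs {n_timepoints_required} timepoints, "
            f"got {len(masks)}"
        )
    per_tp = []
    max_r = 0.0
    polylines_per_tp = []
    for m in masks:
        ps = m.pixel_size_um
        (sr, sc), _ = _soma(m.mask)
        skel = skeletonize(m.mask)
        polys = _skeleton_polylines(_skeleton_graph(skel))
        dists = [np.hypot(p[:, 0] - sr, p[:, 1] - sc) * ps for p in polys]
        polylines_per_tp.append(dists)
        if dists:
            max_r = max(max_r, max(float(d.max()) for d in dists))
    radii = np.arange(step_um, max_r + step_um, step_um)
    for dists in polylines_per_tp:
        counts = np.zeros(len(radii), dtype=int)
        for d in dists:
            for k, r in enumerate(radii):
                counts[k] += _sign_changes(d - r)
        per_tp.append(counts)
    total = np.sum(per_tp, axis=0) if per_tp else np.zeros(len(radii), dtype=int)
    return ShollProfile(
        cell_label=masks[0].label,
        radii_um=radii,
        crossings=np.asarray(total, dtype=int),
        timepoints=tuple(m.frame for m in masks),
    )


def _sign_changes(values: np.ndarray) -> int:
    s = np.sign(values)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def sholl_condition_summary(profiles: list[ShollProfile]):
    """Per-radius percentage of each cell's total crossings, averaged over
    cells — the per-condition aggregation used for group comparison."""
    import pandas as pd

    if not profiles:
        raise ValueError("no Sholl profiles given")
    radii = max((p.radii_um for p in profiles), key=len)
    rows = []
    for p in profiles:
        tot = p.total
        for r, c in zip(p.radii_um, p.crossings):
            rows.append(
                dict(
                    cell=p.cell_label,
                    radius_um=r,
                    crossings=int(c),
                    pct_of_total=100.0 * c / tot if tot else 0.0,
                )
            )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("radius_um")
        .agg(mean_pct=("pct_of_total", "mean"), total_crossings=("crossings", "sum"))
        .reindex(radii)
        .reset_index()
    )
    return summary
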