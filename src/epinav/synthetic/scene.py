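"""Seeded synthetic epidermis scenes with ground truth.

The generator emulates the three experimental settings used to study
Langerhans-cell behaviour in adult zebrafish skin explants:

* **steady state** — ramified cells whose perinuclear MTOC wanders by a
  persistent random walk at a configured mean speed;
* **single-cell ablation** — a debris target appears near each cell at the
  ablation frame; the cell approaches and engulfs it either with a single
  extending dendrite (soma nearly stationary) or by whole-cell motility;
* **scratch wound** — cells migrate toward a wound polygon, pause at an
  obstacle keratinocyte nucleus placed on their path, and pass it on one
  side with the MTOC either leading or trailing the nucleus.

All quantities a downstream measurement could report are recorded in
:class:`GroundTruth` at simulation time, before any rendering or noise, so
every analysis stage can be validated against exact truth.

Kinematic conventions that matter for validation: per-frame steps of a
moving structure have *exactly* length ``speed * dt`` (turning, biasing and
confinement change direction only), so configured mean speeds are realized
without sampling error; encounter-to-pass durations of successful obstacle
passages are drawn from the configured normal distribution and the dwell at
the obstacle is set so the realized duration matches the draw to within one
frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import nearest_points

from ..timelapse import TimeLapse
from .config import AblationSpec, SceneConfig, WoundSpec

__all__ = ["GroundTruth", "generate_scene", "write_scene", "wound_polygon_at"]

# rendering amplitudes (photon counts above background)
_AMP_CYTO = 100.0
_AMP_DEND = 80.0
_AMP_NUC = 120.0
_AMP_MTOC = 170.0
_AMP_EMTB_DEND = 60.0
_AMP_EMTB_SOMA = 14.0
_AMP_DEBRIS = 180.0
_AMP_LIFEACT = 90.0
_MTOC_SIGMA_UM = 1.0
_DENDRITE_HALF_WIDTH_UM = (1.1, 0.45)  # base -> tip half width
_EDGE_SOFT_UM = 0.3

_PHENOTYPE_EVAL_S = 7200.0  # cells are scored 2 h post-scratch
_ENCOUNTER_DIST_UM = 5.0  # generator-side encounter rule, mirrors the scorer
_MTOC_LEAD_UM = 2.8
_DENDRITE_GROWTH_UM_MIN = 6.0


@dataclass
class GroundTruth:
    """Exact per-frame state and event records of a synthetic scene."""

    config: SceneConfig
    cell_xy: np.ndarray  # (T, N, 2) centroid, um
    nucleus_xy: np.ndarray  # (T, N, 2)
    mtoc_xy: np.ndarray  # (T, N, 2)
    heading_xy: np.ndarray  # (T, N, 2) unit step direction (NaN when still)
    dendrite_angles: list[np.ndarray]  # per cell (k,) rad; angle per frame offset by cell
    dendrite_lengths_t: list[np.ndarray]  # per cell (T, k) um
    dendrite_curve_um: list[np.ndarray]  # per cell (k,) lateral mid offset
    dendrite_emtb_positive: list[np.ndarray]
    obstacles: np.ndarray  # (M, 3): x, y, radius um
    wound_polygon_t: Optional[list[np.ndarray]]
    debris_xy: Optional[np.ndarray]  # (N, 2) per-cell debris target
    passages: pd.DataFrame
    engulfments: pd.DataFrame
    phenotypes: pd.DataFrame
    masks: Optional[list[np.ndarray]] = None  # per frame uint16 label image

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.cell_xy.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cell_xy.shape[1]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.config.frame_interval_s

    def track(self, kind: str, cell: int):
        """Ground-truth positions of one structure as a tracking Track."""
        from ..tracking import Track

        arr = {"cell": self.cell_xy, "nucleus": self.nucleus_xy, "mtoc": self.mtoc_xy}[
            kind
        ]
        return Track(
            kind=kind,
            id=cell,
            frames=np.arange(self.n_frames),
            t_s=self.times_s(),
            xy_um=arr[:, cell].copy(),
        )

    def dendrite_count(self, cell: int, frame: int) -> int:
        return int(np.count_nonzero(self.dendrite_lengths_t[cell][frame] > 0))

    def dendrite_tip_xy(self, cell: int, frame: int) -> np.ndarray:
        """(k, 2) dendrite tip positions at a frame (NaN for retracted)."""
        c = self.cell_xy[frame, cell]
        ang = self.dendrite_angles[cell]
        ln = self.dendrite_lengths_t[cell][frame]
        u = np.c_[np.cos(ang), np.sin(ang)]
        p = np.c_[-np.sin(ang), np.cos(ang)]
        tips = (
            c
            + u * (self.config.soma_radius_um + ln)[:, None]
            + p * (self.dendrite_curve_um[cell] * 0.6)[:, None]
        )
        tips[ln <= 0] = np.nan
        return tips


# ----------------------------------------------------------------------
# small deterministic helpers
# ----------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(*v))
    return v / n if n > 0 else np.array([1.0, 0.0])


def _rot(v: np.ndarray, a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def wound_polygon_at(wound: WoundSpec, t_s: float) -> np.ndarray:
    """Wound polygon at time ``t_s``: isotropic shrink about the centroid
    so area(t)/area(0) = 1 - closure_rate * t_h (floored at 0)."""
    v = wound.vertices()
    frac = max(0.0, 1.0 - wound.closure_rate_per_h * t_s / 3600.0)
    c = v.mean(axis=0)
    return c + (v - c) * np.sqrt(frac)


def _place_cells(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid placement with minimum spacing; in wound scenes cells
    start in the region ahead of the wound."""
    sp = cfg.cell_spacing_um
    margin = cfg.soma_radius_um + 8.0
    x_hi = cfg.width_um - margin
    if cfg.wound is not None:
        x_hi = min(x_hi, cfg.wound.vertices()[:, 0].min() - 40.0)
    xs = np.arange(margin, x_hi + 1e-9, sp)
    ys = np.arange(margin, cfg.height_um - margin + 1e-9, sp)
    if cfg.unique_lanes and cfg.wound is not None:
        if len(ys) < cfg.n_cells:
            raise ValueError(
                f"scene too small for {cfg.n_cells} lanes at spacing {sp} um"
            )
        lanes = rng.permutation(len(ys))[: cfg.n_cells]
        pts = np.array([(xs[rng.integers(len(xs))], ys[k]) for k in lanes])
        jit = np.c_[
            rng.uniform(-0.25 * sp, 0.25 * sp, cfg.n_cells),
            rng.uniform(-0.1 * sp, 0.1 * sp, cfg.n_cells),
        ]
        return pts + jit
    if len(xs) * len(ys) < cfg.n_cells:
        raise ValueError(
            f"scene too small for {cfg.n_cells} cells at spacing {sp} um"
        )
    grid = np.array([(x, y) for y in ys for x in xs])
    idx = rng.permutation(len(grid))[: cfg.n_cells]
    jit = rng.uniform(-0.25 * sp, 0.25 * sp, size=(cfg.n_cells, 2))
    return grid[idx] + jit


def _draw_outcomes(p, n: int, rng: np.random.Generator, name: str) -> np.ndarray:
    if isinstance(p, (int, float)):
        return rng.random(n) < float(p)
    out = np.asarray(list(p), dtype=bool)
    if len(out) != n:
        raise ValueError(
            f"forced outcome list for {name} has length {len(out)}, "
            f"but the scene has {n} cells; set n_cells to match"
        )
    return out


def _reflect(pos: np.ndarray, lo: float, hi_x: float, hi_y: float) -> np.ndarray:
    p = pos.copy()
    for i, hi in enumerate((hi_x, hi_y)):
        if p[i] < lo:
            p[i] = 2 * lo - p[i]
        elif p[i] > hi:
            p[i] = 2 * hi - p[i]
    return p


# ----------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------


def _walk_steady(
    cfg: SceneConfig,
    rng: np.random.Generator,
    start: np.ndarray,
    speed_um_min: float,
    n_frames: int,
) -> np.ndarray:
    """Persistent random walk with fixed step length and reflecting walls."""
    dt_min = cfg.frame_interval_s / 60.0
    step = speed_um_min * dt_min
    lo, hx, hy = 8.0, cfg.width_um - 8.0, cfg.height_um - 8.0
    theta = rng.uniform(0, 2 * np.pi)
    out = np.empty((n_frames, 2))
    out[0] = start
    for t in range(1, n_frames):
        theta += rng.normal(0.0, cfg.heading_turn_sd_rad)
        cand = out[t - 1] + step * np.array([np.cos(theta), np.sin(theta)])
        if not (lo <= cand[0] <= hx and lo <= cand[1] <= hy):
            cand = _reflect(cand, lo, hx, hy)
            theta = float(np.arctan2(*(cand - out[t - 1])[::-1]))
        out[t] = cand
    return out


def _hover_step(
    pos: np.ndarray,
    anchor: np.ndarray,
    step: float,
    hover_r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One fixed-length step confined to a disk around ``anchor``."""
    a = rng.uniform(0, 2 * np.pi)
    cand = pos + step * np.array([np.cos(a), np.sin(a)])
    if np.hypot(*(cand - anchor)) > hover_r:
        d = _unit(anchor - pos)
        cand = pos + step * _rot(d, rng.uniform(-0.5, 0.5))
    return cand


def _ray_hits(poly: Polygon, p0: np.ndarray, width_um: float) -> list[np.ndarray]:
    """Intersections of the rightward horizontal ray from ``p0`` with the
    polygon boundary, sorted by x."""
    ray = LineString(
        [(float(p0[0]), float(p0[1])), (float(width_um) + 50.0, float(p0[1]))]
    )
    hit = ray.intersection(poly.exterior)
    pts: list[np.ndarray] = []
    if not hit.is_empty:
        geoms = hit.geoms if hasattr(hit, "geoms") else [hit]
        for g in geoms:
            pts.extend(np.asarray(g.coords))
    pts.sort(key=lambda q: q[0])
    return [np.asarray(p) for p in pts]


def _lane_boundary_point(
    poly: Polygon, p0: np.ndarray, width_um: float, missing_ok: bool = False
):
    """Wound-boundary target in the cell's own horizontal lane (falls back
    to the nearest boundary point for lanes that miss the wound)."""
    pts = _ray_hits(poly, p0, width_um)
    if pts:
        return pts[0]
    if missing_ok:
        return None
    return np.asarray(nearest_points(poly.exterior, Point(p0))[0].coords[0])


def _lane_interior_point(poly: Polygon, p0: np.ndarray, width_um: float) -> np.ndarray:
    """A point well inside the wound on the cell's horizontal lane."""
    pts = _ray_hits(poly, p0, width_um)
    if len(pts) >= 2:
        return 0.5 * (pts[0] + pts[-1])
    return np.asarray(poly.centroid.coords[0])


def _polyline_walk(points: list[np.ndarray], step: float, start_arc: float = 0.0):
    """Positions spaced ``step`` in arc length along a polyline; yields
    positions after the start point (corner-cutting keeps chords <= step)."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = start_arc
    out = []
    while True:
        s += step
        if s >= total:
            break
        i = int(np.searchsorted(cum, s, side="right") - 1)
        frac = (s - cum[i]) / seg_len[i]
        out.append(pts[i] + frac * seg[i])
    return out, pts[-1]


# ----------------------------------------------------------------------
# scenario simulations
# ----------------------------------------------------------------------


def _simulate_steady_or_ablation(cfg: SceneConfig, rng: np.random.Generator):
    T, N = cfg.n_frames, cfg.n_cells
    dt = cfg.frame_interval_s
    step_m = cfg.mtoc_speed_um_min * dt / 60.0
    starts = _place_cells(cfg, rng)
    mtoc = np.empty((T, N, 2))
    offsets = np.empty((N, 2))

    ab = cfg.ablation
    debris = None
    eng_rows = []
    dend_override: dict[int, tuple[int, np.ndarray]] = {}

    if ab is None:
        for i in range(N):
            mtoc[:, i] = _walk_steady(cfg, rng, starts[i], cfg.mtoc_speed_um_min, T)
            a = rng.uniform(0, 2 * np.pi)
            offsets[i] = (cfg.nucleus_radius_um + 0.8) * np.array(
                [np.cos(a), np.sin(a)]
            )
    else:
        debris = np.empty((N, 2))
        modality = _draw_outcomes(
            cfg.modality_dendritic_p, N, rng, "modality_dendritic_p"
        )
        success = _draw_outcomes(cfg.engulf_success_p, N, rng, "engulf_success_p")
        center = np.array([cfg.width_um / 2.0, cfg.height_um / 2.0])
        for i in range(N):
            a = rng.uniform(0, 2 * np.pi)
            offsets[i] = (cfg.nucleus_radius_um + 0.8) * np.array(
                [np.cos(a), np.sin(a)]
            )
            # pre-ablation: plain steady walk
            pre = _walk_steady(cfg, rng, starts[i], cfg.mtoc_speed_um_min, ab.frame + 1)
            mtoc[: ab.frame + 1, i] = pre
            pos = pre[-1]
            nuc0 = pos - offsets[i]
            if ab.site_um is not None:
                debris[i] = np.asarray(ab.site_um, dtype=float)
            else:
                # debris appears at the ablation frame at the configured
                # distance from the cell body
                d = _unit(_rot(_unit(center - nuc0), rng.uniform(-1.2, 1.2)))
                debris[i] = nuc0 + d * ab.debris_distance_um
            # post-ablation: biased approach toward debris, then hover
            d_init = float(np.hypot(*(debris[i] - nuc0)))
            stop = (
                max(3.0, 0.75 * d_init)
                if modality[i]
                else max(2.5, 0.12 * d_init)
            )
            theta = rng.uniform(0, 2 * np.pi)
            contact = None
            anchor = None
            for t in range(ab.frame + 1, T):
                nuc = pos - offsets[i]
                dist = float(np.hypot(*(debris[i] - nuc)))
                if anchor is None and dist > stop:
                    theta += rng.normal(0.0, cfg.heading_turn_sd_rad)
                    prw = np.array([np.cos(theta), np.sin(theta)])
                    d = _unit(0.12 * prw + 0.88 * _unit(debris[i] - nuc))
                    pos = pos + step_m * d
                else:
                    if anchor is None:
                        anchor = pos
                    pos = _hover_step(pos, anchor, step_m, 2.0, rng)
                mtoc[t, i] = pos
            # contact / engulfment bookkeeping
            nuc_t = mtoc[:, i] - offsets[i]
            dist_t = np.hypot(*(debris[i] - nuc_t).T)
            if modality[i]:
                # dendrite 0 re-aims and extends toward the debris
                dend_override[i] = (0, dist_t)
                need = dist_t - cfg.soma_radius_um - 1.0
                growth = _DENDRITE_GROWTH_UM_MIN * dt / 60.0
                # contact when an initially-average dendrite grown at the
                # fixed rate reaches the debris
                base = (
                    cfg.dendrite_length_um
                    if isinstance(cfg.dendrite_length_um, (int, float))
                    else cfg.dendrite_length_um[0]
                )
                ln = float(base)
                for t in range(ab.frame, T):
                    if ln >= need[t] - 0.2:
                        contact = t
                        break
                    ln += growth
                structure = "dendrite"
            else:
                # body contact scales with the realized start distance so the
                # centroid has always closed well over half of it by contact
                thresh = max(cfg.soma_radius_um + 1.5, 0.35 * d_init)
                hits = np.nonzero(dist_t[ab.frame :] <= thresh)[0]
                contact = ab.frame + int(hits[0]) if len(hits) else None
                structure = "cell_body"
            engulf = None
            if contact is not None and success[i]:
                ef = contact + max(1, int(round(60.0 / dt)))
                engulf = ef if ef < T else None
            eng_rows.append(
                dict(
                    cell=i,
                    ablation_frame=ab.frame,
                    debris_x_um=debris[i, 0],
                    debris_y_um=debris[i, 1],
                    modality="dendritic" if modality[i] else "motility",
                    contact_frame=contact,
                    contact_structure=structure if contact is not None else None,
                    engulf_frame=engulf,
                    success=bool(engulf is not None),
                )
            )

    nucleus = mtoc - offsets[None, :, :]
    cell = nucleus.copy()
    passages = _empty_passages()
    engulfments = pd.DataFrame(
        eng_rows,
        columns=[
            "cell",
            "ablation_frame",
            "debris_x_um",
            "debris_y_um",
            "modality",
            "contact_frame",
            "contact_structure",
            "engulf_frame",
            "success",
        ],
    )
    phenotypes = pd.DataFrame({"cell": np.arange(N), "label": ["neither"] * N})
    return cell, nucleus, mtoc, debris, passages, engulfments, phenotypes, dend_override


def _empty_passages() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "cell",
            "obstacle",
            "encounter_frame",
            "mtoc_pass_frame",
            "nucleus_pass_frame",
            "leading",
            "success",
            "navigation_time_s",
        ]
    )


def _simulate_scratch(cfg: SceneConfig, rng: np.random.Generator):
    """Directed migration toward the wound with one scripted obstacle
    passage per cell (when ``force_obstacle_per_cell``), then a scripted
    end-state phenotype."""
    T, N = cfg.n_frames, cfg.n_cells
    dt = cfg.frame_interval_s
    step_c = cfg.cell_speed_um_min * dt / 60.0
    starts = _place_cells(cfg, rng)
    wound_poly0 = Polygon(cfg.wound.vertices())
    t_eval = min(_PHENOTYPE_EVAL_S, (T - 1) * dt)
    poly_eval = Polygon(wound_polygon_at(cfg.wound, t_eval))
    window_s = 3300.0

    success = _draw_outcomes(cfg.navigation_success_p, N, rng, "navigation_success_p")
    mtoc_first = _draw_outcomes(cfg.mtoc_first_p, N, rng, "mtoc_first_p")
    mu, sd = cfg.navigation_pause_s
    durations = np.clip(rng.normal(mu, sd, size=N), 2 * dt, window_s - 2 * dt)
    u_pheno = rng.random(N)

    nucleus = np.empty((T, N, 2))
    mtoc = np.empty((T, N, 2))
    obstacles = []
    pass_rows = []
    pheno_rows = []
    dend_stretch: dict[int, float] = {}
    retract_from: dict[int, int] = {}

    for i in range(N):
        p0 = starts[i]
        wpt = _lane_boundary_point(wound_poly0, p0, cfg.width_um)
        u = _unit(wpt - p0)
        lead = (_MTOC_LEAD_UM if mtoc_first[i] else -_MTOC_LEAD_UM) * u
        jit = lambda s: rng.normal(0.0, s, size=2)  # noqa: E731

        if cfg.force_obstacle_per_cell:
            r = cfg.obstacle_radius_um
            C = p0 + u * (18.0 + rng.uniform(0.0, 4.0))
            obstacles.append((C[0], C[1], r))
            obs_id = len(obstacles) - 1
        else:
            C = None

        pos_list = [p0]
        pos = p0
        enc_frame = None
        # --- approach to the obstacle (when one is on the path) ---------
        while C is not None and len(pos_list) < T:
            head = _unit(u + jit(0.08))
            pos = pos + step_c * head
            pos_list.append(pos)
            m = pos + lead
            if (
                np.hypot(*(m - C)) <= r + _ENCOUNTER_DIST_UM
                and np.dot(C - m, u) > 0
            ):
                enc_frame = len(pos_list) - 1
                break

        if C is not None and enc_frame is not None and len(pos_list) < T:
            side = 1.0 if rng.random() < 0.5 else -1.0
            n_hat = side * np.array([-u[1], u[0]])
            P_e = pos_list[-1]
            if success[i]:
                detour = [
                    P_e,
                    C + n_hat * (r + 3.0),
                    C + u * (r + 4.0) + n_hat * (r + 1.5),
                    C + u * (r + 12.0),
                ]
                walk, end = _polyline_walk(detour, step_c)
                walk = walk + [end]
                # frames until the MTOC projection clears centroid + radius
                proj = [float(np.dot((q + lead) - C, u)) for q in walk]
                t_travel = next(
                    (k + 1 for k, pr in enumerate(proj) if pr > r), len(walk)
                )
                dwell = max(0, int(round(durations[i] / dt)) - t_travel)
                for _ in range(dwell):
                    if len(pos_list) >= T:
                        break
                    pos_list.append(P_e + jit(0.15))
                for q in walk:
                    if len(pos_list) >= T:
                        break
                    pos_list.append(q)
                pos = pos_list[-1]
            else:
                while len(pos_list) < T:
                    pos_list.append(P_e + jit(0.15))
                pos = pos_list[-1]

        # --- post-pass phenotype behaviour ------------------------------
        if success[i] or C is None:
            if u_pheno[i] < cfg.phenotype_engulfing_p:
                label = "engulfing"
            elif u_pheno[i] < cfg.phenotype_engulfing_p + cfg.phenotype_stretching_p:
                label = "stretching"
            else:
                label = "neither"
            # cells keep to their own horizontal lane at the wound so that
            # neighbours do not pile onto one boundary point and merge
            hits = _ray_hits(poly_eval, pos, cfg.width_um)
            chord = float(hits[-1][0] - hits[0][0]) if len(hits) >= 2 else 0.0
            if label == "engulfing":
                target = _lane_interior_point(poly_eval, pos, cfg.width_um)
            else:
                if label == "stretching" and (not hits or chord < 12.0):
                    label = "neither"  # lane only grazes the wound
                B = hits[0] if hits else wpt
                back = cfg.soma_radius_um + (3.0 if label == "stretching" else 25.0)
                target = B - _unit(B - pos) * back
                if label == "stretching":
                    d_wound = _unit(B - target)
                    depth = min(12.0, 0.5 * chord)
                    dend_stretch[i] = (
                        float(np.hypot(*(B - target)) - cfg.soma_radius_um + depth),
                        float(np.arctan2(d_wound[1], d_wound[0])),
                    )
            # march toward the target as a wound-biased persistent random
            # walk; the bias and turning noise carry the drug condition's
            # directionality (low bias -> meandering, fewer arrivals)
            arrived = None
            theta_i = rng.uniform(0, 2 * np.pi)
            lo, hx, hy = 8.0, cfg.width_um - 8.0, cfg.height_um - 8.0
            while len(pos_list) < T:
                d = target - pos
                if np.hypot(*d) <= step_c:
                    arrived = len(pos_list)
                    break
                theta_i += rng.normal(0.0, cfg.heading_turn_sd_rad)
                prw = np.array([np.cos(theta_i), np.sin(theta_i)])
                head = _unit(
                    cfg.wound_bias * _unit(d)
                    + (1.0 - cfg.wound_bias) * prw
                    + jit(0.05)
                )
                cand = pos + step_c * head
                if not (lo <= cand[0] <= hx and lo <= cand[1] <= hy):
                    cand = _reflect(cand, lo, hx, hy)
                pos = cand
                pos_list.append(pos)
            # resting cells idle with sub-micron jitter (probing, no travel)
            anchor = pos if arrived is None else target
            while len(pos_list) < T:
                pos = anchor + jit(0.15)
                pos_list.append(pos)
            if label == "engulfing" and arrived is not None:
                retract_from[i] = arrived
            if label == "stretching" and arrived is not None:
                dend_stretch.setdefault(i, 10.0)
        else:
            label = "neither"
            while len(pos_list) < T:
                pos_list.append(pos + jit(0.15))
        pheno_rows.append(dict(cell=i, label=label))

        traj = np.asarray(pos_list[:T])
        nucleus[:, i] = traj
        mtoc[:, i] = traj + lead + rng.normal(0.0, 0.12, size=(T, 2))

        # --- ground-truth passage record -------------------------------
        if C is not None and enc_frame is not None:
            proj_m = np.dot(mtoc[:, i] - C, u)
            proj_n = np.dot(nucleus[:, i] - C, u)
            mp = np.nonzero(proj_m[enc_frame:] > r)[0]
            np_ = np.nonzero(proj_n[enc_frame:] > r)[0]
            mpf = enc_frame + int(mp[0]) if len(mp) else None
            npf = enc_frame + int(np_[0]) if len(np_) else None
            if mpf is None and npf is None:
                leading = None
            elif npf is None or (mpf is not None and mpf <= npf):
                leading = "mtoc"
            else:
                leading = "nucleus"
            ok = mpf is not None and (mpf - enc_frame) * dt <= window_s
            pass_rows.append(
                dict(
                    cell=i,
                    obstacle=obs_id,
                    encounter_frame=enc_frame,
                    mtoc_pass_frame=mpf,
                    nucleus_pass_frame=npf,
                    leading=leading,
                    success=bool(ok),
                    navigation_time_s=(mpf - enc_frame) * dt if ok else np.nan,
                )
            )

    # density-sampled distractor nuclei (rendered only)
    n_extra = int(
        round(cfg.obstacle_density_per_100um2 * cfg.width_um * cfg.height_um / 100.0)
    )
    for _ in range(n_extra):
        for _try in range(50):
            q = rng.uniform([8, 8], [cfg.width_um - 8, cfg.height_um - 8])
            if not wound_poly0.contains(Point(q)):
                obstacles.append((q[0], q[1], cfg.obstacle_radius_um))
                break

    passages = (
        pd.DataFrame(pass_rows) if pass_rows else _empty_passages()
    )
    phenotypes = pd.DataFrame(pheno_rows)
    obstacles_arr = (
        np.asarray(obstacles, dtype=float) if obstacles else np.empty((0, 3))
    )
    return (
        nucleus.copy(),
        nucleus,
        mtoc,
        passages,
        phenotypes,
        obstacles_arr,
        dend_stretch,
        retract_from,
    )


# ----------------------------------------------------------------------
# dendrite arbors
# ----------------------------------------------------------------------


def _draw_arbors(cfg: SceneConfig, rng: np.random.Generator):
    angles, lengths, curves, emtb = [], [], [], []
    for _ in range(cfg.n_cells):
        if isinstance(cfg.dendrites_per_cell, int):
            k = cfg.dendrites_per_cell
        else:
            m, s = cfg.dendrites_per_cell
            k = int(np.clip(round(rng.normal(m, s)), 3, 10))
        base = rng.uniform(0, 2 * np.pi)
        ang = (base + np.arange(k) * 2 * np.pi / k + rng.normal(0, 0.18, k)) % (
            2 * np.pi
        )
        if isinstance(cfg.dendrite_length_um, (int, float)):
            ln = np.full(k, float(cfg.dendrite_length_um))
        else:
            m, s = cfg.dendrite_length_um
            ln = np.clip(rng.normal(m, s, k), 3.0, None)
        angles.append(ang)
        lengths.append(ln)
        curves.append(rng.uniform(-1.5, 1.5, k))
        emtb.append(rng.random(k) < cfg.emtb_positive_p)
    return angles, lengths, curves, emtb


def _dendrite_lengths_series(
    cfg: SceneConfig,
    lengths: list[np.ndarray],
    engulfments: pd.DataFrame,
    dend_override: dict,
    dend_stretch: dict[int, float],
    retract_from: dict[int, int],
    cell_xy: np.ndarray,
    debris_xy: Optional[np.ndarray],
) -> list[np.ndarray]:
    T = cfg.n_frames
    dt = cfg.frame_interval_s
    growth = _DENDRITE_GROWTH_UM_MIN * dt / 60.0
    out = []
    for i, ln in enumerate(lengths):
        arr = np.tile(ln, (T, 1))
        out.append(arr)
    # dendritic engulfment: dendrite 0 extends toward the debris
    for _, row in engulfments.iterrows():
        i = int(row["cell"])
        if row["modality"] != "dendritic" or debris_xy is None:
            continue
        arr = out[i]
        t0 = int(row["ablation_frame"])
        need = (
            np.hypot(*(debris_xy[i] - cell_xy[:, i]).T)
            - cfg.soma_radius_um
            - 1.0
        )
        ln = arr[t0, 0]
        for t in range(t0, T):
            if ln < need[t] - 0.2:
                ln = min(ln + growth, need[t])
            arr[t, 0] = ln
        if not pd.isna(row["engulf_frame"]):
            te = int(row["engulf_frame"])
            base = out[i][0, 0]
            for t in range(te, T):
                arr[t, 0] = max(base, arr[t - 1, 0] - growth)
    # stretching phenotype: dendrite 0 elongates to reach into the wound
    for i, (L, _aim) in dend_stretch.items():
        arr = out[i]
        base = arr[0, 0]
        t0 = int(T * 0.55)
        ramp = np.minimum(max(L, base), base + growth * np.maximum(np.arange(T) - t0, 0))
        arr[:, 0] = np.maximum(arr[:, 0], ramp)
    # engulfing phenotype: full retraction after entering the wound
    for i, t0 in retract_from.items():
        arr = out[i]
        for t in range(t0, T):
            arr[t] = np.maximum(arr[t - 1] - 2.5 * growth, 0.0)
    return out


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _render_frame(
    cfg: SceneConfig,
    gt: GroundTruth,
    t: int,
    static_nuclei: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    H, W = cfg.shape_px
    ps = cfg.pixel_size_um
    chans = cfg.channels
    img = np.zeros((len(chans), H, W), dtype=np.float64)
    labels = np.zeros((H, W), dtype=np.uint16)
    ci = {name: k for k, name in enumerate(chans)}
    if "nuclei" in ci:
        img[ci["nuclei"]] += static_nuclei

    lead_ratio = cfg.polarity_ratio
    a_lead = 2.0 / (1.0 + lead_ratio)
    a_trail = 2.0 * lead_ratio / (1.0 + lead_ratio)

    for i in range(gt.n_cells):
        c = gt.cell_xy[t, i]
        ang = gt.dendrite_angles[i]
        ln = gt.dendrite_lengths_t[i][t]
        curve = gt.dendrite_curve_um[i]
        reach = cfg.soma_radius_um + (ln.max() if len(ln) else 0.0) + 4.0
        r0 = max(0, int((c[1] - reach) / ps))
        r1 = min(H, int((c[1] + reach) / ps) + 2)
        c0 = max(0, int((c[0] - reach) / ps))
        c1 = min(W, int((c[0] + reach) / ps) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        ys = (np.arange(r0, r1) * ps)[:, None]
        xs = (np.arange(c0, c1) * ps)[None, :]
        dx, dy = xs - c[0], ys - c[1]
        soma_d = np.hypot(dx, dy)
        soma_prof = _sigmoid((cfg.soma_radius_um - soma_d) / _EDGE_SOFT_UM)
        support = soma_d <= cfg.soma_radius_um
        dend_prof = np.zeros_like(soma_prof)
        emtb_dend_prof = np.zeros_like(soma_prof)
        w0, w1 = _DENDRITE_HALF_WIDTH_UM
        for j in range(len(ang)):
            L = ln[j]
            if L <= 0.5:
                continue
            u = np.array([np.cos(ang[j]), np.sin(ang[j])])
            p = np.array([-u[1], u[0]])
            P0 = c + u * (0.5 * cfg.soma_radius_um)
            Pm = c + u * (cfg.soma_radius_um + 0.5 * L) + p * curve[j]
            P1 = c + u * (cfg.soma_radius_um + L) + p * (0.6 * curve[j])
            pts = [P0, Pm, P1]
            seg_off = [0.0, float(np.hypot(*(Pm - P0)))]
            total = seg_off[1] + float(np.hypot(*(P1 - Pm)))
            prof_j = np.zeros_like(soma_prof)
            for (A, B), off in zip(((P0, Pm), (Pm, P1)), seg_off):
                BA = B - A
                L2 = float(BA @ BA)
                tproj = np.clip(((xs - A[0]) * BA[0] + (ys - A[1]) * BA[1]) / L2, 0, 1)
                d = np.hypot(xs - (A[0] + tproj * BA[0]), ys - (A[1] + tproj * BA[1]))
                sfrac = (off + tproj * np.hypot(*BA)) / max(total, 1e-9)
                wloc = w0 + (w1 - w0) * sfrac
                prof_j = np.maximum(prof_j, _sigmoid((wloc - d) / 0.2))
                support |= d <= wloc
            dend_prof = np.maximum(dend_prof, prof_j)
            if gt.dendrite_emtb_positive[i][j]:
                emtb_dend_prof = np.maximum(emtb_dend_prof, prof_j)

        if "cytosol" in ci:
            img[ci["cytosol"], r0:r1, c0:c1] += _AMP_CYTO * np.clip(
                soma_prof + 0.8 * dend_prof, 0, 1.15
            )
        if "lifeact" in ci:
            h = gt.heading_xy[t, i]
            if not np.all(np.isfinite(h)):
                h = np.array([1.0, 0.0])
            proj = dx * h[0] + dy * h[1]
            w = np.where(proj > 0, a_lead, a_trail)  # on-axis pixels lead
            img[ci["lifeact"], r0:r1, c0:c1] += (
                _AMP_LIFEACT * np.clip(soma_prof + 0.8 * dend_prof, 0, 1.15) * w
            )
        if "emtb" in ci:
            m = gt.mtoc_xy[t, i]
            dm = np.hypot(xs - m[0], ys - m[1])
            img[ci["emtb"], r0:r1, c0:c1] += (
                _AMP_MTOC * np.exp(-0.5 * (dm / _MTOC_SIGMA_UM) ** 2)
                + _AMP_EMTB_SOMA * soma_prof
                + _AMP_EMTB_DEND * emtb_dend_prof
            )
        if "nuclei" in ci:
            nu = gt.nucleus_xy[t, i]
            dn = np.hypot(xs - nu[0], ys - nu[1])
            img[ci["nuclei"], r0:r1, c0:c1] += _AMP_NUC * _sigmoid(
                (cfg.nucleus_radius_um - dn) / _EDGE_SOFT_UM
            )
        patch = labels[r0:r1, c0:c1]
        patch[support & (patch == 0)] = i + 1

    # debris blobs (visible in the nuclei channel until engulfed)
    if "nuclei" in ci and gt.debris_xy is not None and len(gt.engulfments):
        for _, row in gt.engulfments.iterrows():
            if t < int(row["ablation_frame"]):
                continue
            ef = row["engulf_frame"]
            if ef is not None and not (isinstance(ef, float) and np.isnan(ef)):
                if t >= int(ef):
                    continue
            dxy = gt.debris_xy[int(row["cell"])]
            r0 = max(0, int((dxy[1] - 4) / ps))
            r1 = min(H, int((dxy[1] + 4) / ps) + 2)
            c0 = max(0, int((dxy[0] - 4) / ps))
            c1 = min(W, int((dxy[0] + 4) / ps) + 2)
            ys = (np.arange(r0, r1) * ps)[:, None]
            xs = (np.arange(c0, c1) * ps)[None, :]
            dd = np.hypot(xs - dxy[0], ys - dxy[1])
            img[ci["nuclei"], r0:r1, c0:c1] += _AMP_DEBRIS * np.exp(
                -0.5 * (dd / 1.2) ** 2
            )

    # noise: Poisson shot noise on signal+background, additive Gaussian read
    sc = cfg.poisson_scale
    if sc > 0:
        lam = (img + cfg.background) * sc
        img = rng.poisson(lam).astype(np.float64) / sc
    else:
        img = img + cfg.background
    if cfg.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.gaussian_noise_sd, size=img.shape)
    return np.clip(img, 0, None).astype(np.float32), labels


def _render_static_nuclei(cfg: SceneConfig, obstacles: np.ndarray) -> np.ndarray:
    H, W = cfg.shape_px
    ps = cfg.pixel_size_um
    out = np.zeros((H, W), dtype=np.float64)
    for x, y, r in obstacles:
        r0 = max(0, int((y - r - 2) / ps))
        r1 = min(H, int((y + r + 2) / ps) + 2)
        c0 = max(0, int((x - r - 2) / ps))
        c1 = min(W, int((x + r + 2) / ps) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        ys = (np.arange(r0, r1) * ps)[:, None]
        xs = (np.arange(c0, c1) * ps)[None, :]
        d = np.hypot(xs - x, ys - y)
        out[r0:r1, c0:c1] += _AMP_NUC * _sigmoid((r - d) / _EDGE_SOFT_UM)
    return out


# ----------------------------------------------------------------------
# top level
# ----------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> tuple[Optional[TimeLapse], GroundTruth]:
    """Simulate and (optionally) render one scene.

    Returns ``(timelapse, ground_truth)``; the timelapse is ``None`` when
    ``config.channels`` is empty (tracks-only simulation, used for large
    kinematic batches where pixel data are not needed).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    T, N = config.n_frames, config.n_cells

    debris = None
    dend_override: dict = {}
    dend_stretch: dict[int, float] = {}
    retract_from: dict[int, int] = {}
    obstacles = np.empty((0, 3))

    if config.wound is not None:
        (
            cell,
            nucleus,
            mtoc,
            passages,
            phenotypes,
            obstacles,
            dend_stretch,
            retract_from,
        ) = _simulate_scratch(config, rng)
        engulfments = pd.DataFrame(
            columns=[
                "cell",
                "ablation_frame",
                "debris_x_um",
                "debris_y_um",
                "modality",
                "contact_frame",
                "contact_structure",
                "engulf_frame",
                "success",
            ]
        )
    else:
        (
            cell,
            nucleus,
            mtoc,
            debris,
            passages,
            engulfments,
            phenotypes,
            dend_override,
        ) = _simulate_steady_or_ablation(config, rng)
        if config.obstacle_density_per_100um2 > 0:
            M = int(
                round(
                    config.obstacle_density_per_100um2
                    * config.width_um
                    * config.height_um
                    / 100.0
                )
            )
            obstacles = np.c_[
                rng.uniform(8, config.width_um - 8, M),
                rng.uniform(8, config.height_um - 8, M),
                np.full(M, config.obstacle_radius_um),
            ]

    heading = np.full((T, N, 2), np.nan)
    steps = np.diff(cell, axis=0)
    norms = np.hypot(steps[..., 0], steps[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        hdir = steps / np.where(norms > 1e-6, norms, np.nan)[..., None]
    if T > 1:
        heading[1:] = hdir
        heading[0] = heading[1]

    angles, lengths, curves, emtb = _draw_arbors(config, rng)
    wound_poly_t = None
    if config.wound is not None:
        times = np.arange(T) * config.frame_interval_s
        wound_poly_t = [wound_polygon_at(config.wound, t) for t in times]

    gt = GroundTruth(
        config=config,
        cell_xy=cell,
        nucleus_xy=nucleus,
        mtoc_xy=mtoc,
        heading_xy=heading,
        dendrite_angles=angles,
        dendrite_lengths_t=[],
        dendrite_curve_um=curves,
        dendrite_emtb_positive=emtb,
        obstacles=obstacles,
        wound_polygon_t=wound_poly_t,
        debris_xy=debris,
        passages=passages,
        engulfments=engulfments,
        phenotypes=phenotypes,
    )
    # re-aim the extending dendrite toward the debris for dendritic events
    for i, (j, _dist) in dend_override.items():
        d = _unit(debris[i] - cell[-1, i])
        angles[i][j] = float(np.arctan2(d[1], d[0]))
    # aim the stretch dendrite of stretching-phenotype cells at the wound
    for i, (_L, aim) in dend_stretch.items():
        angles[i][0] = aim
    gt.dendrite_lengths_t = _dendrite_lengths_series(
        config,
        lengths,
        engulfments,
        dend_override,
        dend_stretch,
        retract_from,
        cell,
        debris,
    )

    tl = None
    if config.channels:
        static = (
            _render_static_nuclei(config, obstacles)
            if "nuclei" in config.channels
            else np.zeros(config.shape_px)
        )
        H, W = config.shape_px
        stack = np.empty((T, len(config.channels), H, W), dtype=np.float32)
        masks = []
        for t in range(T):
            stack[t], lab = _render_frame(config, gt, t, static, rng)
            masks.append(lab)
        gt.masks = masks
        tl = TimeLapse(
            pixels=stack,
            channel_names=config.channels,
            pixel_size_um=config.pixel_size_um,
            frame_interval_s=config.frame_interval_s,
        )
    return tl, gt


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------


def write_scene(
    out_dir: str | Path, tl: Optional[TimeLapse], gt: GroundTruth
) -> None:
    """Write TIFF stack, ground-truth CSV tables and the config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if tl is not None:
        tl.write_tiff(out / "scene.tif")
    T, N = gt.n_frames, gt.n_cells
    frames = np.repeat(np.arange(T), N)
    cells = np.tile(np.arange(N), T)
    pos = pd.DataFrame(
        {
            "frame": frames,
            "cell": cells,
            "t_s": frames * gt.config.frame_interval_s,
            "cell_x_um": gt.cell_xy.reshape(-1, 2)[:, 0],
            "cell_y_um": gt.cell_xy.reshape(-1, 2)[:, 1],
            "nucleus_x_um": gt.nucleus_xy.reshape(-1, 2)[:, 0],
            "nucleus_y_um": gt.nucleus_xy.reshape(-1, 2)[:, 1],
            "mtoc_x_um": gt.mtoc_xy.reshape(-1, 2)[:, 0],
            "mtoc_y_um": gt.mtoc_xy.reshape(-1, 2)[:, 1],
        }
    )
    pos.to_csv(out / "positions.csv", index=False, float_format="%.5f")
    rows = []
    for i in range(N):
        for j in range(len(gt.dendrite_angles[i])):
            rows.append(
                dict(
                    cell=i,
                    dendrite=j,
                    angle_rad=gt.dendrite_angles[i][j],
                    length_um_t0=gt.dendrite_lengths_t[i][0, j],
                    emtb_positive=bool(gt.dendrite_emtb_positive[i][j]),
                )
            )
    pd.DataFrame(rows).to_csv(out / "dendrites.csv", index=False, float_format="%.5f")
    gt.passages.to_csv(out / "passages.csv", index=False, float_format="%.3f")
    gt.engulfments.to_csv(out / "engulfments.csv", index=False, float_format="%.3f")
    gt.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    if len(gt.obstacles):
        pd.DataFrame(gt.obstacles, columns=["x_um", "y_um", "radius_um"]).to_csv(
            out / "obstacles.csv", index=False, float_format="%.5f"
        )
    cfg_dict = dataclasses.asdict(gt.config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True, default_flow_style=False)
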