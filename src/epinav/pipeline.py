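"""End-to-end experiment runner: simulate -> measure -> compare -> report.

Each named experiment simulates a small batch of synthetic scenes per
condition, runs the measurement chain on them, writes tidy CSV tables and
a run log capturing every parameter and seed, and returns the summary.
All randomness flows from one top-level seed, so a rerun with the same
arguments reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import navigation as nav
from . import engulfment as eng
from .morphology import extract_dendrites
from .segmentation import segment_cells
from .stats import ComparisonSpec, compare
from .synthetic import condition_preset, generate_scene, with_ablation, with_scratch
from .tracking import LinkingConfig, link_frames, track_metrics
from .wound import build_margin_roi, count_cells_in_margin

__all__ = ["run_pipeline", "EXPERIMENTS"]

EXPERIMENTS = ("scratch_migration", "navigation", "ablation_engulfment")


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 - re-tag with the stage name
                raise RuntimeError(f"[{name}] {e}") from e

        return wrapped

    return deco


@_stage("segment")
def _segment_stack(tl, channel: str, min_area_um2: float = 30.0):
    stack = tl.channel(channel)
    masks_per_frame = []
    for t in range(tl.n_frames):
        masks = segment_cells(
            stack[t], tl.pixel_size_um, min_area_um2=min_area_um2, frame=t
        )
        masks_per_frame.append(masks)
    if not any(masks_per_frame):
        raise ValueError("no cells found in any frame")
    return masks_per_frame


@_stage("track")
def _track_masks(masks_per_frame, tl, config: LinkingConfig):
    dets = [
        np.array([m.centroid_um for m in masks]).reshape(-1, 2)
        for masks in masks_per_frame
    ]
    return link_frames(
        dets, config, frame_interval_s=tl.frame_interval_s, kind="cell"
    )


def _tracks_df(tracks) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append(
                dict(
                    entity=tr.kind,
                    id=tr.id,
                    frame=int(tr.frames[k]),
                    t_s=tr.t_s[k],
                    x_um=tr.xy_um[k, 0],
                    y_um=tr.xy_um[k, 1],
                )
            )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.5f")


# ----------------------------------------------------------------------
# experiments
# ----------------------------------------------------------------------


def _scratch_migration(seed: int, out: Path, conditions, log: dict):
    """Cell migration to a scratch: motility metrics and margin counts."""
    # gate above the largest per-frame step of the fast (nocodazole) preset
    link_cfg = LinkingConfig(max_link_um=16.0, max_gap=2)
    metrics_rows, margin_rows = [], []
    mi_groups = {}
    for ci, cond in enumerate(conditions):
        cfg = with_scratch(
            condition_preset(cond).replace(
                rng_seed=seed + 1000 * ci,
                n_cells=6,
                width_um=220.0,
                height_um=280.0,
                frame_interval_s=120.0,
                unique_lanes=True,
            ),
            n_frames=50,
            force_obstacle_per_cell=False,
        )
        tl, gt = generate_scene(cfg)
        masks_pf = _segment_stack(tl, "cytosol")
        tracks = _track_masks(masks_pf, tl, link_cfg)
        _write(_tracks_df(tracks), out / f"tracks_{cond}.csv")
        mis = []
        for tr in tracks:
            if not tr.spans(tl.n_frames) or len(tr) < 2:
                continue
            tm = track_metrics(tr)
            metrics_rows.append(
                dict(
                    condition=cond,
                    track=tr.id,
                    total_distance_um=tm.total_distance_um,
                    displacement_um=tm.displacement_um,
                    meandering_index=tm.meandering_index,
                    included=tm.included,
                )
            )
            if tm.included:
                mis.append(tm.meandering_index)
        mi_groups[cond] = mis
        roi = build_margin_roi(gt.wound_polygon_t[0])
        counts = count_cells_in_margin(masks_pf, roi)
        for t, (c, n) in enumerate(zip(counts["counts"], counts["normalized"])):
            margin_rows.append(
                dict(condition=cond, frame=t, count=int(c), normalized=n)
            )
        log[f"scene_{cond}"] = dataclasses.asdict(cfg)
    _write(pd.DataFrame(metrics_rows), out / "motility_metrics.csv")
    _write(pd.DataFrame(margin_rows), out / "margin_counts.csv")
    summary = {"experiment": "scratch_migration"}
    if len(conditions) == 2 and all(len(v) >= 2 for v in mi_groups.values()):
        res = compare(
            ComparisonSpec(test="mann_whitney"),
            [mi_groups[conditions[0]], mi_groups[conditions[1]]],
        )
        summary.update(
            mi_test="mann_whitney", mi_p_value=res.p_value, mi_stars=res.stars
        )
    for cond in conditions:
        summary[f"n_tracks_{cond}"] = len(mi_groups[cond])
        summary[f"mean_mi_{cond}"] = (
            float(np.mean(mi_groups[cond])) if mi_groups[cond] else np.nan
        )
    return summary


def _navigation(seed: int, out: Path, conditions, log: dict):
    """Obstacle navigation: MTOC-first rate, success rate, times."""
    rows, summaries = [], {"experiment": "navigation"}
    counts = {}
    for ci, cond in enumerate(conditions):
        cfg = with_scratch(
            condition_preset(cond).replace(
                rng_seed=seed + 1000 * ci,
                n_cells=40,
                width_um=420.0,
                height_um=420.0,
                channels=(),
            ),
            n_frames=160,
        )
        _, gt = generate_scene(cfg)
        events = []
        for _, prow in gt.passages.iterrows():
            i, oi = int(prow["cell"]), int(prow["obstacle"])
            mtoc, nuc = gt.track("mtoc", i), gt.track("nucleus", i)
            evs = nav.detect_encounters(
                gt.track("cell", i),
                mtoc,
                nuc,
                gt.obstacles[[oi]],  # each cell scored against its obstacle
                wound_polygon_um=gt.wound_polygon_t[0],
                cell_id=i,
            )
            events.extend(nav.score_event(e, mtoc, nuc) for e in evs)
        s = nav.navigation_summary(events)
        counts[cond] = (s["n_success"], s["n_closed"] - s["n_success"])
        for e in events:
            rows.append(
                dict(
                    condition=cond,
                    cell=e.cell_id,
                    obstacle=e.obstacle_id,
                    encounter_time_s=e.encounter_time_s,
                    decision=e.decision,
                    outcome=e.outcome,
                    navigation_time_s=e.navigation_time_s,
                )
            )
        for k, v in s.items():
            summaries[f"{k}_{cond}"] = v
        log[f"scene_{cond}"] = dataclasses.asdict(cfg)
    _write(pd.DataFrame(rows), out / "navigation_events.csv")
    if len(conditions) == 2:
        table = np.array([counts[c] for c in conditions])
        if table.min() >= 0 and table.sum(axis=1).min() > 0:
            res = compare(ComparisonSpec(test="fisher_exact", raw_counts=True), table)
            summaries.update(success_p_value=res.p_value, success_stars=res.stars)
    return summaries


def _ablation_engulfment(seed: int, out: Path, conditions, log: dict):
    """Debris engulfment after simulated single-cell ablation."""
    rows, summaries = [], {"experiment": "ablation_engulfment"}
    counts = {}
    for ci, cond in enumerate(conditions):
        cfg = with_ablation(
            condition_preset(cond).replace(
                rng_seed=seed + 1000 * ci,
                n_cells=24,
                width_um=320.0,
                height_um=320.0,
                n_frames=40,
                channels=(),
            )
        )
        _, gt = generate_scene(cfg)
        events = []
        for _, row in gt.engulfments.iterrows():
            i = int(row["cell"])
            dt = gt.config.frame_interval_s
            events.append(
                eng.classify_modality(
                    gt.track("cell", i),
                    gt.debris_xy[i],
                    ablation_time_s=row["ablation_frame"] * dt,
                    engulf_time_s=(
                        None
                        if pd.isna(row["engulf_frame"])
                        else float(row["engulf_frame"]) * dt
                    ),
                    cell_id=i,
                )
            )
        s = eng.engulfment_summary(events)
        counts[cond] = (s["counts"]["dendritic"], s["counts"]["motility"])
        for e in events:
            rows.append(
                dict(
                    condition=cond,
                    cell=e.cell_id,
                    modality=e.modality,
                    success=e.success,
                    distance_closure=e.distance_closure,
                )
            )
        summaries[f"pct_dendritic_{cond}"] = s["pct_dendritic"]
        summaries[f"pct_success_{cond}"] = s["pct_success"]
        log[f"scene_{cond}"] = dataclasses.asdict(cfg)
    _write(pd.DataFrame(rows), out / "engulfment_events.csv")
    if len(conditions) == 2:
        table = np.array([counts[c] for c in conditions])
        res = compare(ComparisonSpec(test="fisher_exact", raw_counts=True), table)
        summaries.update(modality_p_value=res.p_value, modality_stars=res.stars)
    return summaries


_DEFAULT_CONDITIONS = {
    "scratch_migration": ("vehicle", "nocodazole"),
    "navigation": ("vehicle", "paclitaxel"),
    "ablation_engulfment": ("vehicle", "nocodazole"),
}


def run_pipeline(
    experiment: str,
    seed: int,
    out_dir: str | Path,
    conditions: Optional[tuple[str, ...]] = None,
) -> dict:
    """Run one named experiment end to end and write its report."""
    if experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = tuple(conditions or _DEFAULT_CONDITIONS[experiment])
    log: dict = {"experiment": experiment, "seed": seed, "conditions": list(conditions)}
    fn = {
        "scratch_migration": _scratch_migration,
        "navigation": _navigation,
        "ablation_engulfment": _ablation_engulfment,
    }[experiment]
    summary = fn(seed, out, conditions, log)
    _write(pd.DataFrame([summary]), out / "summary.csv")
    with open(out / "run.log", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return summary
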