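"""Scene configuration for the synthetic epidermis generator.

A :class:`SceneConfig` fully determines a synthetic time-lapse: the same
``(config, rng_seed)`` pair always produces bit-identical pixel data and
ground truth.  Physical quantities are in micrometres and seconds; speeds
are in micrometres per minute, matching how they are reported for
Langerhans-cell imaging.

Several behavioural parameters (``navigation_success_p``, ``mtoc_first_p``,
``modality_dendritic_p``, ``engulf_success_p``) accept either a probability
or an explicit sequence of boolean outcomes.  Forcing outcomes removes
sampling noise, so worked examples can assert exact event counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "SceneConfig",
    "WoundSpec",
    "AblationSpec",
    "condition_preset",
    "with_scratch",
    "with_ablation",
    "CONDITIONS",
]

#: probability or an explicit list of outcomes (one event per cell)
MaybeForced = Union[float, Sequence[bool]]

#: (mean, sd) of a normal distribution
Dist = tuple[float, float]

CONDITIONS = ("vehicle", "nocodazole", "paclitaxel", "nocodazole_y27632")


@dataclass(frozen=True)
class WoundSpec:
    """A scratch wound: closed polygon plus a linear closure rate.

    ``closure_rate_per_h`` is the fraction of the time-zero area lost per
    hour; the polygon is shrunk isotropically about its centroid so the
    normalized area series is exactly ``1 - rate * t_h``.
    """

    polygon_um: tuple[tuple[float, float], ...]
    closure_rate_per_h: float = 0.15

    def vertices(self) -> np.ndarray:
        return np.asarray(self.polygon_um, dtype=float)


@dataclass(frozen=True)
class AblationSpec:
    """Laser ablation of a single keratinocyte.

    ``site_um`` of ``None`` places one debris target per cell at
    ``debris_distance_um`` from the cell, emulating independent
    single-cell ablation movies in one scene.
    """

    frame: int = 0
    site_um: Optional[tuple[float, float]] = None
    debris_distance_um: float = 15.0


def _is_forced(p: MaybeForced) -> bool:
    return not isinstance(p, (int, float))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a vehicle-treated steady-state field of view:
    ramified cells with ~5 dendrites of ~12 um, MTOC wandering at
    1.4 um/min, calibration 0.5 um/pixel and 30 s/frame.
    """

    rng_seed: int = 0

    # --- geometry / calibration -------------------------------------
    width_um: float = 200.0
    height_um: float = 200.0
    pixel_size_um: float = 0.5
    frame_interval_s: float = 30.0
    n_frames: int = 40
    n_cells: int = 5
    cell_spacing_um: float = 36.0

    # --- morphology --------------------------------------------------
    soma_radius_um: float = 5.0
    nucleus_radius_um: float = 3.0
    dendrites_per_cell: Union[int, Dist] = (5.0, 1.5)
    dendrite_length_um: Union[float, Dist] = (12.0, 4.0)
    emtb_positive_p: float = 0.8

    # --- kinematics --------------------------------------------------
    cell_speed_um_min: float = 1.0
    mtoc_speed_um_min: float = 1.4
    heading_turn_sd_rad: float = 0.45
    wound_bias: float = 0.8

    # --- scenario ----------------------------------------------------
    condition: str = "vehicle"
    wound: Optional[WoundSpec] = None
    ablation: Optional[AblationSpec] = None
    obstacle_density_per_100um2: float = 0.0
    obstacle_radius_um: float = 4.0
    force_obstacle_per_cell: bool = False
    #: one cell per horizontal lane in wound scenes (prevents migrating
    #: neighbours from piling onto the same wound-boundary point)
    unique_lanes: bool = False

    # --- behavioural probabilities (forceable) -----------------------
    navigation_success_p: MaybeForced = 0.76
    navigation_pause_s: Dist = (675.0, 135.0)
    mtoc_first_p: MaybeForced = 0.84
    modality_dendritic_p: MaybeForced = 0.825
    engulf_success_p: MaybeForced = 0.86
    phenotype_engulfing_p: float = 0.20
    phenotype_stretching_p: float = 0.047

    # --- intensity model ---------------------------------------------
    polarity_ratio: float = 1.0
    channels: tuple[str, ...] = ("cytosol", "emtb", "nuclei")
    background: float = 20.0
    poisson_scale: float = 1.0
    gaussian_noise_sd: float = 3.0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "width_um",
            "height_um",
            "pixel_size_um",
            "frame_interval_s",
            "soma_radius_um",
            "nucleus_radius_um",
            "obstacle_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.n_frames < 1:
            raise ValueError("a scene needs at least one frame")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in (
            "emtb_positive_p",
            "phenotype_engulfing_p",
            "phenotype_stretching_p",
            "wound_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in (
            "navigation_success_p",
            "mtoc_first_p",
            "modality_dendritic_p",
            "engulf_success_p",
        ):
            p = getattr(self, name)
            if _is_forced(p):
                if len(p) == 0:
                    raise ValueError(f"forced outcome list for {name} is empty")
            elif not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
        if self.phenotype_engulfing_p + self.phenotype_stretching_p > 1.0:
            raise ValueError("phenotype probabilities exceed 1")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        for name in ("cell_speed_um_min", "mtoc_speed_um_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background < 0 or self.gaussian_noise_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.wound is not None:
            v = self.wound.vertices()
            if v.ndim != 2 or v.shape[0] < 3:
                raise ValueError("wound polygon needs at least 3 vertices")
            if (
                v[:, 0].min() < 0
                or v[:, 1].min() < 0
                or v[:, 0].max() > self.width_um
                or v[:, 1].max() > self.height_um
            ):
                raise ValueError("wound polygon lies outside the scene")
        if self.ablation is not None:
            if not 0 <= self.ablation.frame < self.n_frames:
                raise ValueError("ablation frame outside the movie")
            if self.ablation.site_um is not None:
                x, y = self.ablation.site_um
                if not (0 <= x <= self.width_um and 0 <= y <= self.height_um):
                    raise ValueError("ablation site outside the scene")

    # ------------------------------------------------------------------
    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) of the rendered frames."""
        return (
            int(round(self.height_um / self.pixel_size_um)),
            int(round(self.width_um / self.pixel_size_um)),
        )

    @property
    def dt_s(self) -> float:
        return self.frame_interval_s

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)

    def forced_count(self, name: str) -> Optional[int]:
        """Length of a forced outcome list, or None when probabilistic."""
        p = getattr(self, name)
        return len(p) if _is_forced(p) else None


# ----------------------------------------------------------------------
# Condition presets
# ----------------------------------------------------------------------

#: per-condition parameter overrides, in the effect directions reported for
#: microtubule depolymerization (nocodazole) and stabilization (paclitaxel).
_PRESETS: dict[str, dict] = {
    "vehicle": {},
    "nocodazole": {
        # fewer but longer dendrites, faster yet less directional migration,
        # rear-enriched actin, fewer dendrite-mediated engulfments
        "dendrites_per_cell": (3.0, 1.0),
        "dendrite_length_um": (18.0, 5.0),
        "cell_speed_um_min": 1.6,
        "heading_turn_sd_rad": 0.9,
        "wound_bias": 0.35,
        "polarity_ratio": 1.5,
        "modality_dendritic_p": 0.5,
        "engulf_success_p": 0.6,
    },
    "paclitaxel": {
        # morphology unchanged; obstacle navigation impaired
        "navigation_success_p": 0.23,
        "navigation_pause_s": (2175.0, 435.0),
        "phenotype_engulfing_p": 0.06,
        "phenotype_stretching_p": 0.10,
    },
    "nocodazole_y27632": {
        # ROCK inhibition on top of nocodazole restores front-rear actin
        "dendrites_per_cell": (3.0, 1.0),
        "dendrite_length_um": (18.0, 5.0),
        "cell_speed_um_min": 1.6,
        "heading_turn_sd_rad": 0.9,
        "wound_bias": 0.35,
        "polarity_ratio": 1.05,
    },
}


def condition_preset(name: str) -> SceneConfig:
    """Baseline :class:`SceneConfig` for a treatment condition.

    ``vehicle`` returns the documented defaults; ``nocodazole`` and
    ``paclitaxel`` shift the affected parameters in the directions reported
    for those drugs; ``nocodazole_y27632`` models ROCK inhibition restoring
    the actin polarity ratio to near-vehicle levels.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
    return SceneConfig(condition=name, **_PRESETS[name])


def default_scratch_polygon(
    width_um: float, height_um: float
) -> tuple[tuple[float, float], ...]:
    """Oval scratch occupying the right-hand part of the scene."""
    cx, cy = 0.82 * width_um, 0.5 * height_um
    rx, ry = 0.10 * width_um, 0.38 * height_um
    th = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    pts = np.c_[cx + rx * np.cos(th), cy + ry * np.sin(th)]
    return tuple((float(x), float(y)) for x, y in pts)


def with_scratch(
    config: SceneConfig,
    closure_rate_per_h: float = 0.15,
    force_obstacle_per_cell: bool = True,
    n_frames: int = 150,
) -> SceneConfig:
    """Attach a scratch wound and obstacle course to a baseline config.

    Cells placed ahead of the wound migrate toward it at ``cell_speed``,
    each encountering one obstacle keratinocyte nucleus on its path.
    """
    poly = default_scratch_polygon(config.width_um, config.height_um)
    # directed migration is faster than steady-state patrolling
    return config.replace(
        wound=WoundSpec(polygon_um=poly, closure_rate_per_h=closure_rate_per_h),
        force_obstacle_per_cell=force_obstacle_per_cell,
        cell_speed_um_min=max(2.0 * config.cell_speed_um_min, 2.0),
        n_frames=n_frames,
    )


def with_ablation(
    config: SceneConfig, frame: int = 2, debris_distance_um: float = 15.0
) -> SceneConfig:
    """Attach per-cell laser-ablation debris to a baseline config."""
    return config.replace(
        ablation=AblationSpec(frame=frame, debris_distance_um=debris_distance_um)
    )
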