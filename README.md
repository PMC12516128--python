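# epinav

Quantification of tissue-resident macrophage behaviour in epidermal
time-lapse microscopy.

Langerhans cells — the resident macrophages of the epidermis — surveil
skin with long dynamic dendrites, engulf debris from damaged
keratinocytes, and squeeze through a densely packed epithelium toward
wounds, steering around obstacle keratinocyte nuclei with their
microtubule organizing centre (MTOC) leading the way. `epinav`
implements the measurements used to quantify these behaviours from
multi-channel 2D movies (cytosolic reporter, microtubule/EMTB reporter,
nuclei), together with a seeded synthetic-scene generator that provides
exact ground truth for every analysis stage, so the whole pipeline is
testable without raw imaging data.

## What it measures

- **Dendrite morphology** — skeleton-based dendrite counts and lengths;
  a dendrite is microtubule-positive when its EMTB/cytosol intensity
  ratio exceeds 0.5; Sholl profiles count skeleton crossings of
  concentric circles in 10 µm steps, summed over five sampled timepoints.
- **Tracking & motility** — per-frame detections linked by optimal
  linear-assignment (LAP) with gap closing; total distance *d*,
  displacement *D*, and the meandering index MI = *D*/*d* (cells with
  *D* < 10 µm are flagged for exclusion); per-step speeds in µm/min and
  least-squares Gaussian fits to speed histograms.
- **Front–rear polarity** — each migrating cell's mask is bisected
  through its centroid perpendicular to its motion; the summary is the
  trailing/leading mean-intensity ratio over the migration.
- **Wound analysis** — margin ROI of 150 µm × (1.2 × wound length)
  aligned with the wound's major axis; cells counted when strictly more
  than 50 % of their area is inside; wound areas normalized to time 0;
  margin cells scored *engulfing* (body in the wound, circularity
  4πA/P² > 0.6), *stretching* (dendrite tip in the wound, body outside)
  or *neither*.
- **Obstacle navigation** — an encounter opens when the MTOC comes
  within 5 µm of an obstacle nucleus lying ahead on the approach axis; a
  structure passes once its axial projection clears the obstacle; the
  decision is MTOC-first or nucleus-first, and navigation succeeds when
  the MTOC passes within the 55-min window (3300 s).
- **Engulfment modality** — dendrite-mediated vs motility-based
  engulfment, separated by whether the cell body closed more than 50 %
  of its initial distance to the debris.
- **Statistics** — Mann–Whitney, Fisher's exact, chi-squared,
  Kolmogorov–Smirnov and ANOVA + Bonferroni comparisons via
  scipy/statsmodels, with the usual significance stars.

## Worked example

Score obstacle navigation in vehicle- vs paclitaxel-treated synthetic
scratch assays (`examples/05_navigation.py`):

```python
from epinav import (condition_preset, detect_encounters, generate_scene,
                    navigation_summary, score_event, with_scratch)

for cond in ("vehicle", "paclitaxel"):
    cfg = with_scratch(condition_preset(cond).replace(
        rng_seed=17, n_cells=40, width_um=420, height_um=420, channels=()),
        n_frames=160)
    _, gt = generate_scene(cfg)
    events = []
    for _, r in gt.passages.iterrows():
        i, oi = int(r["cell"]), int(r["obstacle"])
        mtoc, nuc = gt.track("mtoc", i), gt.track("nucleus", i)
        evs = detect_encounters(gt.track("cell", i), mtoc, nuc,
                                gt.obstacles[[oi]],
                                wound_polygon_um=gt.wound_polygon_t[0], cell_id=i)
        events += [score_event(e, mtoc, nuc) for e in evs]
    s = navigation_summary(events)
    print(cond, s["pct_mtoc_first"], s["success_rate_pct"],
          s["mean_navigation_time_s"])
```

prints

```
vehicle    : 77% MTOC-first, 78% success, mean time 662 s over 31 successes
paclitaxel : 70% MTOC-first, 25% success, mean time 2181 s over 10 successes
```

i.e. in the vehicle condition most cells put their MTOC past the
obstacle before the nucleus and clear it in about 11 minutes, while
microtubule stabilization makes most navigation attempts fail and slows
the successful ones several-fold. The other scripts in `examples/`
demonstrate scene generation, morphology/Sholl, tracking, polarity and
engulfment/wound analysis the same way; a thin `epinav` command-line
interface (`simulate`, `segment`, `track`, `morphology`, `navigate`,
`engulfment`, `wound`, `report`) wraps the same calls for shell use.

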