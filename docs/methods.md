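# Methods

This note documents the models and conventions behind `epinav`: what the
synthetic scenes contain, how each measurement is defined, which
parameters matter, and where the design was genuinely open.

## Coordinate and calibration conventions

Images are indexed `(frame, channel, row, col)` with row 0 at the top
and pixel centers at integer (row, col); physical positions use
`x = col · pixel_size`, `y = row · pixel_size`. Default calibration is
0.5 µm/pixel and 30 s/frame. Both are configuration fields carried by
the `TimeLapse` container and never hard-coded in the metrics, so any
calibrated movie can be analysed. Speeds are reported in µm/min, times
in seconds.

## The synthetic scene generator

The generator emulates three assay settings on a 2D plane (all in-scope
metrics are planar, matching analysis of single optical slices):

**Cells.** Each cell is a soma disk (radius 5 µm) with 3–10 tapering,
gently curved dendrites of configurable length distribution (vehicle
default 5 ± 1.5 dendrites of 12 ± 4 µm), a nucleus disk, and a single
perinuclear MTOC rendered as the brightest Gaussian focus in the EMTB
channel — per-cell maximum EMTB intensity is therefore the MTOC by
construction, matching the identification rule used by the measurement
side. A configurable fraction of dendrites (default 0.8) carries EMTB
signal.

**Kinematics.** Moving structures take steps of *exactly*
`speed · Δt`; turning, wound bias and confinement only change direction.
The configured mean speed is therefore realized without sampling error,
which is what makes speed-recovery tests meaningful: any deviation in
the measured mean is attributable to detection and linking, not to the
simulation. In steady-state scenes the MTOC is the primary walker
(default 1.4 µm/min) and nucleus/cell follow at a fixed perinuclear
offset — cell body and MTOC move in concert. In wound scenes the cell
is primary and the MTOC leads (or trails) the nucleus by 2.8 µm along
the approach axis according to the drawn MTOC-first outcome.

**Ablation scenes.** At the ablation frame a debris target appears at a
configured distance (default 15 µm) from each cell body. Cells assigned
the *dendritic* modality hold their soma near its position (approach
stops at 75 % of the initial distance) while one dendrite re-aims and
extends at 6 µm/min until tip contact; *motility* cells walk to the
debris and contact it with the cell body after closing ≥ 65 % of the
initial distance. These margins place the two modalities safely on
either side of the classifier's 50 % distance-closure rule, so
forced-count scenes reproduce configured proportions exactly.

**Scratch scenes.** A wound polygon (default an oval band on one side
of the scene) shrinks isotropically so its normalized area is
`1 − rate·t` exactly. Cells march toward the wound boundary point in
their own horizontal lane as a wound-biased persistent random walk; the
bias (default 0.8) and turning noise carry the drug condition's
directionality. When an obstacle nucleus is scripted onto the path, the
encounter-to-pass duration of a successful passage is drawn from the
configured normal distribution (vehicle 675 ± 135 s) and the dwell at
the obstacle is set so the realized duration matches the draw to within
one frame; failed passages dwell at the obstacle beyond the scoring
window. Note the drawn quantity is the full encounter-to-pass time, not
only the stationary pause — that is the quantity the navigation scorer
measures. After passing, each cell realizes a drawn end-state phenotype:
*engulfing* cells enter the wound and retract their dendrites (high
circularity), *stretching* cells stop short and extend one dendrite past
the boundary, *neither* cells stop ~30 µm outside.

**Forced outcomes.** Any behavioural probability
(`navigation_success_p`, `mtoc_first_p`, `modality_dendritic_p`,
`engulf_success_p`) may instead be a list of booleans, one per cell;
realized event counts then equal the list exactly. This removes
sampling noise from worked-example tests.

**Noise.** Poisson shot noise on signal + background, plus additive
Gaussian read noise (defaults: background 20, Gaussian σ 3). Rendering
is simplified fluorescence: soft-edged disks and ridges, no PSF
convolution, no photobleaching, no z-structure, no keratinocyte
segmentation. Passing tests therefore demonstrate correctness of the
measurement definitions and their noise robustness at these SNRs — not
performance on real microscope data, where segmentation and MTOC
detection would face debris, uneven illumination and out-of-focus light
that the generator does not emulate.

**Determinism.** One `numpy` Generator seeded from `rng_seed` drives
everything; identical (config, seed) pairs give bit-identical stacks,
ground truth and on-disk files.

## Condition presets

`condition_preset(name)` encodes effect directions of acute microtubule
drugs: `nocodazole` (depolymerization) — fewer but longer dendrites
(3 ± 1 × 18 ± 5 µm), faster but less directional migration (bias 0.35),
rear-enriched actin (trailing/leading 1.5), more motility-based
engulfment and lower engulfment success; `paclitaxel` (stabilization) —
morphology unchanged, navigation success 0.23 with encounter-to-pass
times 2175 ± 435 s; `nocodazole_y27632` — nocodazole kinematics with
the actin ratio restored to 1.05, modelling ROCK inhibition downstream
of RhoA. Magnitudes without a stated source value were chosen once as
plausible for this cell type and are not tuned.

## Measurement definitions and numerical choices

**Segmentation.** Per-frame global threshold (Otsu default; li/yen/mean
available), 8-connected components, minimum area 30 µm²; labels ordered
by bounding-box (top, left) for determinism.

**Dendrites.** Soma = maximal inscribed disk of the mask (distance
transform), dilated 1 px. The mask skeleton outside the soma is a
weighted 8-neighbour graph; per arbor root (nearest node to the soma)
the longest root-to-tip Dijkstra path is the primary dendrite and side
branches count separately when ≥ 2 µm (suppresses skeleton spurs).
Lengths are polyline arc length × pixel size; skeletonization erodes
tips by ~1–2 px, so lengths are accurate to ~10 % and slightly biased
short. Intensity ratios are means over the 1-px-dilated path;
`emtb_positive` uses a strict `> 0.5`. Manual counting in the original
protocol is replaced by this deterministic rule.

**Sholl.** Circles in 10 µm steps centred on the soma centroid;
crossings are sign changes of (distance − r) along skeleton polylines,
with on-circle samples inheriting the previous sign (so tangent
touches are not double-counted); five evenly spaced timepoints are
summed (the original selection of timepoints was manual and unstated;
even spacing is recorded in the output).

**Linking.** Jaqaman-style LAP per frame pair: squared-distance costs,
alternative cost `max_link²` (defaults: 10 µm gate, gap ≤ 2 frames),
solved with `scipy.optimize.linear_sum_assignment`; verified against
exhaustive enumeration on small instances. Gap closing links segment
ends to later starts under the same gate.

**Motility.** MI = displacement / total distance with the 0/0 → 0
convention (flagged; such tracks are excluded anyway by the 10 µm
displacement rule). Speeds are per-step, unsmoothed; centroid positions
are used throughout.

**Polarity.** The bisector passes through the mask centroid
perpendicular to the displacement over a centred 3-frame window (the
original bisection was manual; this is the declared convention).
On-line pixels go to the leading half — deterministic and affecting
< 1 % of pixels at realistic sizes. The frame median is subtracted as a
background estimate before averaging so the ratio reflects reporter
signal, not camera offset.

**Wound.** Margin axis = principal axis of the polygon vertices; for a
degenerate (circular) vertex cloud the principal vector nearest the
x-axis is chosen and flagged. The > 50 % in-margin rule and the > 0.5
ratio rule are strict inequalities. "Rounded, phagocytic" is
operationalized as circularity > 0.6 (configurable); the original
scoring was by eye.

**Navigation.** Encounter distance 5 µm from the obstacle boundary;
"past the obstacle" = axial projection beyond centroid + radius; ties
at the same frame score MTOC-first; window 3300 s. Events observed for
less than the window without a pass are *censored* and excluded from
success-rate denominators. The approach axis is supplied explicitly or
computed per frame toward the nearest wound-boundary point. Summaries
are per event; when several obstacles lie near a path, scoring can be
restricted to a cell's assigned obstacle.

**Engulfment.** Events are annotation-driven (on real data a phagosome
marker would be required; detection from imagery is out of scope). The
modality rule (50 % centroid-distance closure) is a quantitative
surrogate for an observational distinction and its threshold is a
parameter.

## Problem sizes

Speed recovery uses 50 tracks × 500 frames (steady state) and
50 tracks × 11 frames (post-ablation window), rendered and re-detected
from images. Navigation-time recovery uses 150 (vehicle) and 500
(paclitaxel) simulated passages, keeping ≥ 100 successes; success-rate
recovery uses 5000 events. Rendered test scenes use a handful of cells
per condition; these sizes give sub-percent standard errors on the
recovered means while keeping the default test run fast.

## Known limitations

2D only; no merging/splitting or Kalman prediction in the tracker; no
Strahler branch ordering or sub-pixel skeletons; rendering is not
photorealistic and the obstacle course is scripted rather than emergent
from tissue mechanics; engulfment detection from pixels is out of
scope. Statistical tests are delegated to scipy/statsmodels and
significance stars are cosmetic output only.
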