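"""Generate a small synthetic epidermis scene and inspect its ground truth.

Builds a steady-state field of ramified macrophages (cytosol, microtubule
reporter and nuclei channels), prints what the generator put in it, and
writes the TIFF + ground-truth CSVs to ./scene_out.
"""

import numpy as np

from epinav import SceneConfig, generate_scene, write_scene

cfg = SceneConfig(rng_seed=42, n_cells=4, n_frames=10, width_um=160, height_um=160)
tl, gt = generate_scene(cfg)
write_scene("scene_out", tl, gt)

print(f"stack: {tl.pixels.shape} (frame, channel, row, col), "
      f"{tl.pixel_size_um} um/px, {tl.frame_interval_s} s/frame")
for i in range(gt.n_cells):
    ln = gt.dendrite_lengths_t[i][0]
    print(f"cell {i}: {len(ln)} dendrites, mean length "
          f"{ln.mean():.1f} um, {gt.dendrite_emtb_positive[i].sum()} EMTB+")
steps = np.diff(gt.mtoc_xy, axis=0)
speed = np.hypot(steps[..., 0], steps[..., 1]).mean() / (cfg.frame_interval_s / 60)
print(f"realized mean MTOC speed: {speed:.2f} um/min "
      f"(configured {cfg.mtoc_speed_um_min})")
# The ground truth is exact: downstream modules are validated against it.
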