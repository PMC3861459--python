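"""Detect a forming thermal lesion in an ultrasound speckle phantom.

Simulates an 11 frames/s envelope sequence in which an elliptical lesion's
amplitude statistics ramp during a 4 s ablation exposure, computes the
windowed log-normal σ parametric maps and their cumulative-extrema temporal
map, and scores lesion detection against the generative mask.
"""

import numpy as np

import hifumap as hm
from hifumap.roc import detection_timecourse

cfg = hm.SpecklePhantomConfig(shape=(60, 40), lesion_center=(30.0, 20.0),
                              lesion_semiaxes=(15.0, 8.0))
env, mask = hm.simulate_speckle_sequence(cfg, seed=1)
print(f"envelope sequence: {env.n_frames} frames of {env.frames.shape[1:]}, "
      f"t = {env.times_s[0]:.2f}–{env.times_s[-1]:.2f} s, "
      f"ablation {cfg.ablation_window_s[0]}–{cfg.ablation_window_s[1]} s")

window = hm.WindowSpec(7, 5)
sigma = hm.lognormal_sigma_map(env, window)
tm = hm.temporal_maps(sigma)
print(f"baseline σ̂ ≈ {np.nanmean(sigma.frames[0]):.3f}, "
      f"final σ̂ inside lesion ≈ {np.nanmean(sigma.frames[-1][mask.mask]):.3f} "
      "(the lesion broadens the amplitude distribution)")

a = hm.SpeckleAnalysis(subject="demo", param="sigma", maps=tm, mask=mask,
                       window=window)
r = hm.roc_curve(a.scores("extrema"))
print(f"|Δσ|_max lesion detection: AUC = {r.auc:.3f}, "
      f"Youden threshold = {r.threshold:.3f} "
      f"(sens {r.sensitivity:.2f} / spec {r.specificity:.2f})")

df = detection_timecourse(tm.extrema, mask)
during = (env.times_s >= 4.5) & (env.times_s <= 8.5)
print(f"per-frame AUC rises {df['auc'][during].iloc[0]:.2f} → "
      f"{df['auc'][during].iloc[-1]:.2f} across the ablation window — "
      "detectability grows as the lesion forms.")
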