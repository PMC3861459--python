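"""Lesion segmentation from a gross/histology photograph + registration.

Generates a two-color stained-section phantom (pale necrotic lesion on
dark-red myocardium) with color noise and speckled outliers, segments it
with L*a*b* k-means + MRF smoothing, and registers a mask through a known
similarity transform via fiducial landmarks.
"""

import numpy as np

import hifumap as hm

img, truth = hm.simulate_histology_image(noise_sd=10.0, outlier_frac=0.05, seed=2)
mask = hm.segment_lesion(img, smoothing_weight=1.0, seed=0)
cmp = hm.compare_masks(mask, truth, pixel_spacing_um=(50.0, 50.0))
print(f"segmentation vs truth: {100 * cmp['match']:.2f}% pixel match, "
      f"Dice = {cmp['dice']:.3f}, lesion area {cmp['area1_mm2']:.2f} mm² "
      "(k-means labels cleaned by the Ising/ICM smoothing)")

raw = hm.segment_lesion(img, smoothing_weight=0.0, closing_radius=0, seed=0)
print(f"without MRF smoothing the match drops to "
      f"{100 * hm.compare_masks(raw, truth)['match']:.2f}% — "
      "the pairwise prior removes the speckled outliers.")

rng = np.random.default_rng(0)
tf_true = hm.RigidTransform(rotation_rad=0.2, scale=1.05, translation=(6.0, -4.0))
src = rng.uniform(0, 100, (4, 2))
fit = hm.fit_landmark_transform(hm.LandmarkSet(src, tf_true.apply_points(src)))
print(f"landmark registration: rotation {fit.rotation_rad:.3f} rad, "
      f"scale {fit.scale:.3f}, translation ({fit.translation[0]:.1f}, "
      f"{fit.translation[1]:.1f}) px, residual {fit.residual_rms:.1e} — "
      "exact recovery of the fiducial similarity transform.")
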