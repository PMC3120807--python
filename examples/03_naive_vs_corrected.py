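"""Fit the naive and measurement-error-corrected models on one study.

Generates a synthetic study with known weak effects (ORs 0.9, 0.8, 1.3 per
unit log exposure), then fits the conditional-logistic model twice: naively
(observed exposures taken as exact) and with the Bayesian correction (latent
true exposures sampled jointly with the log ORs).  Chains are kept short for
a quick demonstration; the full protocol uses 2 x 55,000 sweeps.
"""

import numpy as np

import matchedme as mm

synth = mm.generate(seed=7)
spec = mm.MeasurementErrorSpec(sigma2=synth.config.sigma2)
cfg = mm.SamplerConfig(n_iter=6_000, n_burn=1_000, n_chains=2, base_seed=0)

_, naive = mm.fit_naive(synth.study, use_confounders=True, config=cfg)
_, corrected = mm.fit_me(synth.study, spec, use_confounders=True, config=cfg)

print(f"true ORs: {np.round(np.exp(synth.config.beta), 3)}\n")
print("naive analysis (N-A):")
print(naive.to_frame().head(3).to_string(index=False))
print("\nmeasurement-error analysis (ME-A):")
print(corrected.to_frame().head(3).to_string(index=False))
# Each row: posterior mean OR with its equal-tailed 95% credible interval,
# plus convergence diagnostics (R-hat near 1, small MCSE).  The corrected
# estimates sit further from OR=1 than the naive ones on average — the
# correction undoes attenuation — and their intervals are wider, reflecting
# the acknowledged uncertainty in the true exposures.
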