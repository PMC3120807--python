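# Methods

## Model

`matchedme` targets the joint posterior

p(β, δ, X, M, V_W, V_B | W, Z, y) ∝
p(W | X, Σ) · p(y | X, Z, β, δ) · p(X | M, V_W) p(M | μ, V_B) · p(β, δ, V_W⁻¹, V_B⁻¹)

with the four factors described in the README: classical additive normal
measurement error on the log scale with known diagonal covariance Σ, the
conditional logistic likelihood for one case per matched set, a two-level
multivariate-normal exposure model, and proper diffuse priors.  The two-level
exposure model is not a convenience: conditioning on one case per set
discards a likelihood factor that is ignorable when exposures are observed
but not, in general, when they are latent.  Modelling both the between-set
and within-set exposure variation restores the argument, so the generator
and the fitter deliberately share this structure.

Assumptions worth stating explicitly: non-differential, unbiased error
(surrogates depend on outcome only through the true exposures); error
variances known (no uncertainty in Σ is propagated); multivariate-normal
true exposures; confounders precisely measured and excluded from the
exposure model (defensible when exposure-confounder correlations are small,
as the generator enforces by construction).

## Priors and their defaults

| parameter | prior | default | notes |
|---|---|---|---|
| β_p, δ_k (log ORs per unit) | N(0, v) | v = 10⁴ | effectively flat over plausible effects |
| V_W⁻¹, V_B⁻¹ | Wishart(b, R⁻¹) | R = I_P, b = P | R is an inverse scale; b = P is the minimal proper choice |
| μ (grand mean) | plug-in | across-set mean of W | unweighted mean of the set-level means; an explicit value can be supplied |

A single Wishart specification is shared by both precision matrices.  All
hyperparameters are overridable through `PriorSpec`.

With very diffuse coefficient priors the posterior is only as good as the
likelihood's identification: the integrated conditional likelihood flattens
to a positive constant as |β| → ∞, so when the data carry little information
(very small studies, or assumed error variance approaching the exposure
variance) a non-trivial share of posterior mass follows the prior into the
tails.  The small-instance oracle checks therefore use a moderately
informative prior (variance 1–4) in both the sampler and the oracle, and the
sensitivity sweep is run in the regime where the ten-fold-scaled error
variance stays well below the exposure variance.  This mirrors the
motivating application, whose estimated error variances (~0.01–0.03 on the
log scale) are an order of magnitude below the exposure spread.

## Error variances from percent recovery

The QC experiment measures a spiked/unspiked serum pair and a gold standard;
the percent recovery is Q = (spiked − unspiked) / gold.  Under the same
log-scale error model as the main analysis each measurement carries an
independent multiplicative log-normal error, and a first-order delta
expansion around zero error gives Var(Q) ≈ σ²·g(c, a) with
g(c, a) = (c/a)² + ((c+a)/a)² + 1.  `estimate_sigma2` inverts this;
`simulate_recovery` simulates the experiment exactly and serves as the
built-in oracle.

The delta relation is first order: the exact moments of Q (a difference of
correlated log-normals) give Var(Q) = (A²+B²)e^{4σ²} − 2ABe^{3σ²} − e^{2σ²}
with A = (c+a)/a, B = c/a, whose leading term is σ²·g.  The relative error
of the first-order formula is ≈1.7% at σ = 0.1, ≈3.8% at σ = 0.15 and
≈6.7% at σ = 0.2.  At the error levels the published recovery SDs imply
(σ ≈ 0.09–0.15) the approximation is comfortably adequate; users with much
noisier assays should treat the estimate as a mild underestimate of σ².
The mean concentration c_p is rarely published; when unknown, c = 0 gives
the conservative (largest) σ² for a given recovery SD.

## Sampler

One sweep of the Metropolis-within-Gibbs sampler updates:

1. **M_i** — exact conjugate draw, N_P((V_B⁻¹ + n_i V_W⁻¹)⁻¹(V_B⁻¹μ + V_W⁻¹Σ_j X_ij), (V_B⁻¹ + n_i V_W⁻¹)⁻¹),
   vectorized over sets grouped by size (one Cholesky per distinct n_i per sweep);
2. **V_W⁻¹, V_B⁻¹** — conjugate Wishart draws (Bartlett decomposition);
3. **X_ij** — random-walk Metropolis on each subject's P-vector.  Positions
   within sets are updated simultaneously *across* sets (sets are mutually
   independent given the rest), so a sweep does max(n_i) vectorized
   Metropolis steps instead of 271 sequential ones;
4. **（β, δ)** — joint random-walk Metropolis, two refreshes per sweep.  The
   proposal covariance is learned from the first half of burn-in (empirical
   covariance of the draws, ridge-regularized); the global step scales for
   the X and θ blocks follow Robbins–Monro adaptation toward 0.35
   acceptance, frozen at the end of burn-in so the post-burn-in kernel is a
   fixed Markov kernel.

Initialization: X = W, M = set means of W, V_W/V_B from within/between
empirical covariances (ridge-regularized to positive definite), β = δ = 0.
Chain c shifts X and M by +0.5·c·SD(W) and the coefficients by +0.15·c so
multiple chains start overdispersed.  A non-finite initial posterior raises
immediately with the offending state.

The sampler maintains the disease log-likelihood and per-set log-sum-exp
incrementally; the tracked log-posterior is tested to match the reference
`model_core.log_joint` to machine precision at stored states, which ties the
fast path to the plainly written densities.

Defaults mirror the full protocol: 2 chains × 55,000 sweeps, 5,000 burn-in,
no thinning of the coefficient draws (covariance matrices are kept every
10th sweep).  On one CPU a full-protocol adjusted fit of the default
271-subject study takes about 1.5 minutes; the scaled-down settings used in
the heavier validation runs (2 × 11,000, burn 1,000, twenty replicates)
keep each replicate near twenty seconds.  Diagnostics: split-chain
Gelman-Rubin PSRF and batch-means MCSE (~√n batches per chain, combined
across chains); both are cross-checked in the tests against independent
implementations.

`mode="naive"` fixes X ≡ W and samples (β, δ) only — the comparator analysis.
`exposure_only=True` mutes the disease term; it exists to validate the
conjugate updates against an independent Gibbs sampler.  `fix_covariances`
holds V_W, V_B at supplied values, used when comparing against the
small-instance quadrature oracle with known covariances.

## Synthetic-data generator

The generator draws from exactly the model above: set means from N_P(μ, V_B),
subjects from N_P(M_i, V_W), the case chosen within each set with probability
softmax(X'β + Z'δ) (the conditional-logistic law, so no rejection step), and
W = X + U with independent N(0, σ²_p) noise drawn after case assignment
(non-differential by construction).  Confounders load on a weak shared
set-level factor, keeping |corr(exposure, confounder)| well under 0.18 at
the defaults; one confounder is binary.

Defaults emulate the motivating study's shape: N = 96 sets (34 of size 2,
45 of size 3, 17 of size 4; 271 subjects — the published composition gives
only the totals, so the split is a choice), P = 3 exposures with
equicorrelated V_W = 0.6·R(0.3) and V_B = 0.4·R(0.3), grand mean 0,
true ORs (0.9, 0.8, 1.3) echoing the published weak-effect magnitudes,
δ = 0, and σ² = 0.09 per exposure — error SD 30% of the total exposure SD,
a deliberately *moderate* level chosen so that attenuation is material; the
study's own estimated error was smaller.  An LOD-censoring step
back-transforms to concentrations and flags non-detects for the LOD/2
pipeline.

What passing tests on generated data do **not** show: robustness to skewed
or mixture exposure distributions, differential or systematically biased
error, misspecified Σ, confounders that belong in the exposure model, or
frequency-matched designs.  The generator is the model; real assay data can
violate any of these.

## Numerical choices

* Natural log throughout (log-molar units are ln(c/m_p)).
* Non-detects are replaced by LOD/2 before the log transform; the operation
  is idempotent and reports substitution counts.
* Equal-tailed 95% intervals are empirical 2.5/97.5 percentiles (linear
  interpolation) of the OR draws pooled over chains; OR means are means of
  exp(draw), so OR mean ≥ exp(posterior mean log OR) by Jensen.
* Log-sum-exp stabilization everywhere in the conditional likelihood.
* Wishart draws by Bartlett decomposition; covariance initialization adds a
  1e-3 ridge; the learned proposal covariance adds 1e-8.
* Degenerate sets (a case with no control) are rejected at load time.

## Known limitations

* Σ is treated as known; uncertainty from the QC experiment is not
  propagated into the posterior.
* The delta-method σ² estimate is first order (see above).
* Only diagonal Σ and non-differential error are supported.
* The exposure model is multivariate normal; heavy skew should be handled
  by transforming before analysis.
* With assumed error variance comparable to the exposure variance the log
  ORs are weakly identified and results become prior-driven; the sensitivity
  sweep caps its factors at 10 and should be read in that light.
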