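# Methods

## The observer model

A participant observes a dictator's returns `r ∈ {1..9}` (1 = nothing
returned, 5 = half, 9 = everything) and maintains a joint belief over the
dictator's harmful intent (HI) and self-interest (SI), each discretised to
nine levels indexed 0 (totally altruistic) to 8 (totally antisocial). All
distributions come from the sharpened binomial family
`NB(k; p, u, n) ∝ Bin(k; p, n)^u`, computed in log space and renormalised;
the exponent preserves the binomial's mode while scaling its concentration,
and `u = 0` degenerates to the uniform distribution.

**Priors.** The initial belief is the outer product of
`NB(·; pHI0, 1/uHI0, 8)` and `NB(·; pSI0, 1/uSI0, 8)`. The uncertainties
enter as the *inverse* exponent so that larger `uHI0`/`uSI0` means a flatter
marginal, matching their interpretation as reduced confidence. Independence
holds only in the prior; Bayesian updating through the joint policy map
induces posterior dependence.

**Policy map.** The shared attribute-to-behaviour template factorises as
`π_gen(r; HI, SI) ∝ π_gen(r; HI)·π_gen(r; SI)` with
`π_gen(r; a) = NB(r−1; 1 − p_init − δp·a, u_init − 2δp(a+1), 8)`,
`p_init = 0.05`, `u_init = 2.5`, `δp = (1 − 2 p_init)/8 = 0.1125`. The
success probability spans 0.95 (level 0 → mode at full return) down to 0.05
(level 8 → mode at zero return); the exponent spans 2.275 down to 0.475, so
extreme-attribute cells are *less* deterministic than the raw probability
suggests. Individual policy uncertainty flattens the template,
`π ∝ π_gen^{1/uπ} + ξ`, with lapse `ξ = 0.02/9² ≈ 2.47×10⁻⁴` added after
exponentiation and before row renormalisation; the lapse bounds every entry
away from zero so the Bayes normaliser can never vanish.

**Updating and carry-over.** After each observed return the belief is
updated by the exact grid Bayes rule. Between dictators the next block's
prior is the convex mixture `(1−η)·prior_d + η·posterior_d` of the previous
block's *starting* prior and *final* posterior, chained across blocks
(dictator 3's prior mixes dictator 2's prior with dictator 2's posterior).
At `η = 0` every dictator is approached fresh; at `η = 1` the posterior
carries over wholesale.

**Response model.** The two ratings of a trial are treated as one joint
draw from the 81-cell belief, mapped to the 1–100 scale through bin centres
(`rating = round((bin + 0.5)·100/9)`; inverse `bin = min(8, ⌊rating·9/100⌋)`).
The joint treatment fixes the chance floor at `ln(1/81) = −4.394` per
trial. Ratings are scored against the belief *after* incorporating that
trial's observed return, since participants rate after seeing the split;
pre-update scoring is available as a configuration switch. Probabilities
are floored at 1e−30 before logs.

## MAP fitting

The log-posterior is the 18-trial log-likelihood plus a weak regularising
prior: uniform over the feasible box for `pHI0, pSI0 ∈ [0.01, 0.99]` and
`η ∈ [0, 1]`, and log-normal(0, 1.5) for `uHI0, uSI0, uπ ∈ [0.05, 20]` — a
gentle pull towards order-1 scales that keeps the flat directions of an
18-trial likelihood from drifting to the bounds.

Optimisation is a coarse Cartesian grid search (default 5 values per
parameter, linear for bounded parameters and geometric for scales) followed
by L-BFGS-B ascent with numerical gradients from the best `K` seeds
(default 3). Ties in the grid are broken by lexicographic parameter order,
making the whole fit deterministic. The ascent runs on an unconstrained
scale — scaled logit for bounded parameters, scaled logit of the logarithm
for the scales — and the result is reported on the natural scale; the seed
itself is kept whenever no restart improves on it, so the fitted
log-posterior is never below the best grid point. A `FitConfig.fast()`
preset (4 grid values, 2 restarts) is used for batch stages; it agrees with
the default preset to well within the sampling noise of any population
statistic reported here.

The likelihood kernel is implemented twice: a reference implementation in
`core_model` built from the documented primitives, and a compiled (numba)
flat-array version used inside the optimiser. The test suite asserts
agreement to 1e−12, and both are checked against a brute-force
re-derivation that shares no code with the package.

## Synthetic populations

The generator defines the study conditions under which the pipeline is
validated. GPTS totals are `32 + round(128·Beta(1.2, 4))` — right-skewed
over 32–160, like general-population paranoia. Each parameter is linear in
the z-scored GPTS on its link scale (logit for `pHI0, pSI0, η`; log for the
scales) plus Gaussian noise, then clipped to the fitting bounds. Defaults:
intercepts at `pHI0 = 0.30`, `pSI0 = 0.60`, `uHI0 = uSI0 = 1.0`,
`uπ = 1.5`, `η = 0.30`; couplings per 1 SD of GPTS of +0.11 on logit
`pHI0`, +0.04 on log `uHI0`, +0.03 on log `uSI0`, +0.09 on log `uπ`, zero
on `pSI0` and `η`; noise SDs of 0.4 (logit scales), 0.3 (log scales) and
0.6 (η). The coupling magnitudes are emulation settings chosen to match the
direction and order of magnitude of the associations the model is meant to
exhibit, not estimates of anything.

Sessions are simulated by running the same belief recursion as the
likelihood and sampling one joint cell per trial from the post-update
belief. Dictator orders are counterbalanced round-robin over the three
cyclic rotations; partially fair dictators realise an independent
Bernoulli(0.5) sequence per participant. All randomness flows from one
master seed through per-participant `SeedSequence` substreams.

What the generator deliberately does *not* emulate: item-level GPTS
responses, age/sex structure, response-time or anchoring effects on the
1–100 sliders, and any departure of real raters from the model's own
response distribution. Passing recovery and direction-of-effect checks on
these populations therefore shows the pipeline is self-consistent and
well-powered under the model's assumptions — not that real data satisfy
those assumptions.

## Validation pipeline

*Diagnostics* aggregate per-trial log-likelihoods by trial index, dictator
type and GPTS quantile (default 4 quantiles; the grouping is a reporting
choice) and flag any stratum mean below the −4.394 chance floor.

*Recovery* simulates from known parameters, refits, and reports per-parameter
Spearman ρ, bias and RMSE. With 18 trials per participant the session is
information-poor: the prior modes and `uπ` recover well in rank order
(ρ ≈ 0.55–0.75 at n = 200), the prior uncertainties moderately
(ρ ≈ 0.2–0.45), and `η` weakly except under strongly contrasting dictator
sequences, where extreme learning rates are assigned to the correct half of
[0, 1] essentially always.

*Network.* The network stage intentionally uses unregularised partial
correlations (inverse covariance of z-scored variables, with a small ridge
added only if the covariance is near-singular) plus nodewise OLS with
moderator interactions, rather than regularised mixed graphical models with
information-criterion model selection — a deliberate simplification that
keeps the stage dependency-light and exactly testable against a
residual-correlation oracle. Edge intervals are percentile bootstrap
(default 1000 resamples; fewer in tests); an edge's sign is reported as 0
when its interval covers zero. Moderation is the symmetrised coefficient of
the moderator-by-parameter interaction from the two nodewise regressions of
an edge's endpoints.

*Cluster control.* To ask whether parameter correlations could be artefacts
of fitting itself, populations are generated with `pHI0`/`pSI0` confined to
low- (0.01–0.2 × 0.01–0.2), medium- (0.25–0.5 × 0.5–0.75) and high-density
(0.01–0.98 × 0.8–0.98) boxes and all other parameters drawn independently
from one shared dense range. Since the generating parameters are
independent (up to the box constraint), any significant edge in a network
refitted from such data that matches the sign of the corresponding edge in
the reference network is a candidate fitting artefact; the pipeline emits
the per-cluster sign tables and the edge-by-edge comparison.

## Problem sizes and numerical choices

Population stages use n = 200 participants, the sign-recovery check 20
replicated populations of 200, and the cluster control 200 per cluster —
sizes at which every direction-of-effect and recovery criterion is stable
across seeds while a full validation run stays within a few minutes on one
core. Normalisation is enforced to 1e−9 on every belief and policy row;
update/oracle agreement is asserted at 1e−12; probabilities are floored at
1e−30 before logs. Degenerate inputs (constant ratings, identical GPTS)
yield missing rank correlations rather than errors.

## Known limitations

- Real-data constants (mean fitted log-likelihood, regression coefficients,
  real-vs-simulated rating correlations) require the original behavioural
  dataset and are outside what synthetic validation can reproduce.
- `uHI0`/`uSI0` and especially `η` are weakly identified from 18 trials;
  population-level couplings routed through them would need larger designs.
- The moderated-network stand-in estimates linear moderation only and does
  not perform model selection over edge sets.
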