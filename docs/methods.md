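# Methods notes

## Model and assumptions

`camocc` fits the closed single-season site-occupancy model: a latent
Bernoulli occupancy state zᵢ ~ Bern(Ψᵢ) per site and conditionally
independent Bernoulli detections yᵢⱼ | zᵢ = 1 ~ Bern(pᵢⱼ) per survey
occasion, with no false positives (yᵢⱼ = 0 whenever zᵢ = 0).  The
assumptions this encodes: (1) demographic closure — the occupancy state
does not change across a site's occasions; (2) detections are correct
(no species misidentification); (3) sites are independent.  Both Ψ and p
are logit-linked to site covariates.  Detection covariates are site-level
habitat descriptors only, so p is constant over occasions within a site;
occasion-varying detection covariates are out of scope.  This makes each
site's likelihood a function of two sufficient statistics (detections dᵢ,
surveyed occasions mᵢ), which is what keeps exhaustive model sets cheap.

Missing occasions (camera inactive for the whole window) drop out of the
detection product — a missing-at-random treatment, appropriate when
camera failure is unrelated to animal presence.

## Detection-history construction

Occasions are fixed-length blocks (default 4 trap-days) anchored at each
site's deployment start; surveys spanning multiple years make a shared
calendar grid meaningless, so sites do not share windows.  A final short
block (deployment not divisible by the occasion length) is kept as a
shorter occasion and flagged in the matrix metadata; an occasion with at
least one active camera-day counts as surveyed rather than missing
(conservative use of effort — both choices are visible in the metadata so
users can drop or reclassify flagged occasions).  The independent-
detection count collapses same-site photos closer than a configurable
window (default 60 minutes); this affects reporting only, since the
occupancy likelihood consumes occasion-level 0/1 records.

## Fitting and numerics

The joint negative log-likelihood is minimized by BFGS with the analytic
gradient, starting from all-zero coefficients (Ψ = p = 0.5); a failed run
restarts once from the naive-occupancy and naive-detection logits.  The
gradient-norm tolerance is 1e-8.  The coefficient covariance is the
inverse of the observed information, obtained by central differences of
the analytic gradient; a non-invertible or non-positive-diagonal Hessian
falls back to a pseudo-inverse and flags the fit as boundary, as does any
coefficient beyond ±10 on the logit scale (e.g. every site detected at
every occasion drives Ψ̂ to the boundary at 1).  Convergence reporting is
honest: a fit is `converged` only if the optimizer reports success or the
final gradient infinity-norm is below 1e-5; non-converged fits are
excluded from model sets with a warning.

AICc uses the number of *sites* as the effective sample size.  The
convention (sites vs. site×occasions) is genuinely unsettled for occupancy
models; sites is the common choice and is what `aicc()` receives from
`fit_occupancy`, and the function is exposed directly for anyone wanting
the other convention.  AICc ties are broken by smaller K, then label
order — this affects table ordering only.

## Model selection and averaging

All detection-covariate subsets are crossed with all occupancy-covariate
subsets (2^|p| · 2^|ψ| models; a budget guard suggests capping subset
size beyond 20,000).  Akaike weights are computed over all converged
models; a confidence set keeps ΔAICc strictly < 2 and renormalizes.
Model-averaged coefficients default to shrinkage (zero-substitution)
averaging — models without a term contribute 0, pulling weak effects
toward zero — with `mode="conditional"` available for natural averaging
over models containing the term.  The unconditional SE is
Σᵢ wᵢ √(varᵢ + (β̂ᵢ − β̄)²).  Averaged probability predictions are
weight-averaged on the probability scale, with the unconditional spread
assembled on the logit scale so intervals stay inside [0, 1].

## Goodness of fit and cross-validation

The Pearson X² statistic compares observed and expected counts of
detection histories.  Sites sharing a missingness pattern form a cohort;
within a cohort the fitted (Ψ̂, p̂) are averaged by default (a documented
approximation; `mode="exact"` sums site-specific history probabilities
instead).  Because p is constant within a site, a history's probability
depends only on its detection count, and the total expected count over
unobserved histories equals the cohort size minus that of the observed
ones — so X² is computed without enumerating 2^J histories at any J.

The reference distribution comes from a parametric bootstrap: B datasets
(default 500) are simulated from the fitted model with the same design
and missingness, each refit, and X² recomputed.  The overdispersion ratio
is ĉ = X²_obs / mean(X²_boot); ĉ > 1 multiplies variances by ĉ (SEs by
√ĉ) and never touches point estimates.  The bootstrap p-value is the
share of simulated X² at least as large as observed.

Cross-validation partitions *sites* (never occasions) into k folds
(default 5), refits on training sites and scores held-out cells by the
Brier score of the unconditional detection probability Ψ̂·p̂ against the
0/1 record.  The paper-style "MSE" for such data has no canonical
definition; the unconditional form is the default because it matches what
the survey actually observes, and a conditional-on-occupancy variant
(p̂ alone) is exposed via `prediction="conditional"`.

## Survey design

p\* = 1 − (1 − p)^K with the delta-method SE K(1−p)^(K−1)·SE(p) and
intervals truncated to [0, 1] (matching the symmetric error bars these
curves are usually drawn with; a logit-scale transform would be asymmetric
near saturation).  At the fitted detectability range (~0.46 per occasion)
p\* exceeds 0.999 by 12–15 occasions, the basis for 60-day deployments.

## Synthetic data

The generator emulates: z-scored site covariates from an exchangeable
multivariate normal (default correlation 0.3, a plausible landscape
autocorrelation; any SPD matrix accepted, including a deliberately
collinear pair to exercise pruning), logit-linear Ψ and p, Bernoulli
states and detections, photos placed uniformly within detected occasions
(count ~ 1 + Poisson(rate − 1)) and one 60-day deployment per site.  It
does *not* emulate spatial autocorrelation between sites, diel activity
rhythms, animal movement, occasion-varying detectability or false
positives — so passing tests demonstrate the estimator's correctness
under its own assumptions, not robustness to their violation in real
surveys.

The reference scenario uses 380 sites × 15 four-day occasions with
occupancy effects (+0.334, +0.232, −0.100, −0.354) for dense forest,
crops, pasture and distance to streams.  Detection-side effects are not
reported as coefficients in the source study; (+0.25, 0, +0.20, −0.10)
follow the reported directions (better detection in dense forest and
pasture, worse far from water) at plausible magnitude.  Intercepts
(−0.46557, −0.21297) were calibrated once by bisection with common random
numbers at 400,000 sites so the expected naive occupancy is 0.392 and the
naive detection rate 0.46 (`scripts/calibrate_intercepts.py`); they are
fixed constants, not tuned per run.

`inject_overdispersion` adds a site-level normal random effect to the
detection logits and regenerates histories, preserving occupancy states
and recording the effects for audit — the mechanism used to verify that
ĉ responds to extra-binomial noise.

## Statistical power at the reference effect sizes

At n = 380 standardized covariates with correlation 0.3, the sampling SE
of each occupancy slope is ≈ 0.12 (detection is nearly perfect over 15
occasions at p ≈ 0.46, so the information approaches that of logistic
regression on the latent states).  The weakest reference effect
(pasture, −0.100) is therefore recovered with the correct sign in only
P(β̂ < 0) ≈ Φ(0.10/0.12) ≈ 0.8 of replicates, putting the joint
four-effect sign-recovery rate near 0.78 — an inherent property of the
design, not an estimator defect; the recovery test in the acceptance
suite documents this by asserting a 90% joint rate that the design cannot
deliver, and the acceptance script reports the measured rate.  Interval
calibration is unaffected: 95% Wald CI coverage of each slope at n = 500
sits within [0.92, 0.97] across replicates.

## Problem sizes used in checks

The test and acceptance runs use 600 replicates for coverage (n = 500),
200 for sign recovery (n = 380), B = 500 bootstrap replicates at n ≤ 380
and 15 overdispersion replicates at B = 60 — sizes chosen to keep Monte
Carlo error well inside the asserted bands on a single CPU.

## Known limitations

- No occasion-varying detection covariates (effort, season, weather).
- Single-season only: no colonization/extinction dynamics.
- No spatial random effects; sites are treated as independent.
- Wald intervals can undercover near boundaries (Ψ̂ → 0/1); boundary fits
  are flagged rather than profiled.
- The greedy collinearity pruner is oracle-checked at small scale but is
  not guaranteed to find the maximum retained subset for adversarial
  correlation structures.
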