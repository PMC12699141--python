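# camocc — camera-trap single-season occupancy analysis

`camocc` implements the standard analysis chain for estimating where an
elusive species occurs from camera-trap surveys, built for studies like
large-mammal monitoring programs (its reference scenario mirrors a
lowland-tapir survey across the Colombian Orinoquia: ~380 stations, 60
trap-days each, 4-day survey occasions).  It is aimed at wildlife
ecologists who have a photo-record table, a deployment table and a
site-covariate table, and want occupancy and detectability estimates that
correct for imperfect detection.

## The model

Each site *i* is occupied with probability Ψᵢ; given occupancy, each
survey occasion *j* yields a detection with probability pᵢⱼ, and an
unoccupied site never yields a detection.  Under closure (the occupancy
state is fixed across occasions) the likelihood of site *i*'s detection
history *yᵢ* is

    L(ψᵢ, pᵢ ; yᵢ) = ψᵢ ∏ⱼ pᵢⱼ^yᵢⱼ (1 − pᵢⱼ)^(1−yᵢⱼ)  +  (1 − ψᵢ) 𝟙[yᵢ ≡ 0],

with missing occasions dropped from the product.  Both probabilities carry
logit-linear site covariates: logit(Ψᵢ) = xᵢᵀβ_ψ, logit(pᵢ) = wᵢᵀβ_p.
Around this core the package provides:

- **Detection histories** — timestamped photos + deployment windows →
  sites × occasions 0/1/missing matrix (per-site anchored, fixed-length
  occasions, default 4 days), plus naive occupancy, naive detection rate
  and independent-detection counts.
- **Covariate preparation** — z-scoring (sample SD) and |r| > 0.7
  collinearity pruning, as scikit-learn transformers.
- **Model selection** — exhaustive detection-subset × occupancy-subset
  enumeration, AICc ranking, Akaike weights, ΔAICc < 2 confidence sets,
  shrinkage model averaging with unconditional standard errors.
- **Assessment** — parametric-bootstrap Pearson X² goodness of fit, the
  overdispersion ratio ĉ with √ĉ standard-error inflation, and site-level
  k-fold cross-validation of unconditional cell predictions Ψ̂·p̂.
- **Survey design** — cumulative detection probability
  p\* = 1 − (1 − p)^K with delta-method intervals, and the survey count
  needed to reach a target p\*.
- **Synthetic data** — a generator that draws covariates, latent occupancy
  and detections from the same hierarchical model, emitting the photo /
  deployment / covariate CSVs the pipeline consumes, so everything is
  testable end to end without field data.

## Worked example

```python
import camocc as co

ds = co.simulate(co.tapir_scenario(seed=42))        # 380 sites, 15 occasions
print(f"naive occupancy   {co.naive_occupancy(ds.matrix):.3f}")
print(f"naive detection   {co.naive_detection_rate(ds.matrix):.3f}")

specs = co.enumerate_models(ds.design.covariates, ds.design.covariates)
fits = co.fit_models(specs, ds.matrix, ds.covariates)
ranked = co.rank_and_weight(fits)
conf = co.confidence_set(ranked, threshold=2.0)
print(f"models fitted     {len(specs)}, confidence set {len(conf)}")
print(f"best model        {ranked.best.spec.label}")

est = co.model_average(conf, "psi:forest_d")
print(f"psi:forest_d      {est.estimate:+.3f} ± {est.unconditional_se:.3f}")
psi = co.average_predictions(conf, {}, "psi")
print(f"psi at means      {psi.point:.2f} (CI {psi.lower:.2f}-{psi.upper:.2f})")

gof = co.bootstrap_gof(ranked.best, ds.matrix, ds.covariates, B=500, seed=1)
print(f"c_hat             {gof.c_hat:.3f} (p = {gof.p_value:.2f})")
cv = co.cross_validate(ranked.best.spec, ds.matrix, ds.covariates, k=5, seed=2)
print(f"cv mean MSE       {cv.mean_mse:.3f}")
print(f"surveys for p*>=0.95 at p=0.46: {co.required_surveys(0.46, 0.95)}")
```

prints

```
naive occupancy   0.397
naive detection   0.469
models fitted     256, confidence set 3
best model        p(forest_d+past+d_streams)Ψ(forest_d+crops+d_streams)
psi:forest_d      +0.311 ± 0.121
psi at means      0.39 (CI 0.34-0.44)
c_hat             0.978 (p = 0.68)
cv mean MSE       0.146
surveys for p*>=0.95 at p=0.46: 5
```

Reading this: about 40% of sites produced at least one detection, with a
0.47 per-occasion detection rate at those sites.  All 256 covariate
combinations were fitted; three models are within 2 AICc units of the
best.  The model-averaged dense-forest effect on occupancy is positive
(+0.31 on the logit scale per SD of forest cover, unconditional SE 0.12),
and averaged occupancy at mean covariates is 0.39.  ĉ ≈ 1 indicates no
overdispersion, the cross-validated Brier score 0.146 indicates low
prediction error, and 5 occasions already push the chance of detecting a
resident animal past 95%.

The same pipeline runs from the shell:

```sh
camocc simulate --seed 2 --out data/
camocc run-all --config config.yaml --out results/
```

with a YAML config naming either CSV inputs (`photos`, `deployments`,
`covariates`) or a simulation design, plus candidate covariate lists,
thresholds and stage seeds (see `camocc.pipeline.RunConfig`).

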