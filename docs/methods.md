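# Methods

## The measurement model

Each larva contributes one standardized skin patch (250 × 420 px =
105,000 pixels, cropped from a cheek photograph). Two responses are
derived per patch:

* **Darkness** — the patch is converted to grayscale with Rec. 601 luma
  weights (0.299 R + 0.587 G + 0.114 B; configurable) and darkness is
  the mean of `1 − luminance/255`, so 0 is pure white and 1 pure black.
  Using the mean makes the response a proportion-like quantity suited to
  a beta likelihood; with 105,000 pixels per patch exact 0/1 values do
  not occur in practice, but quantified boundary values are pulled
  inward with the standard `(y·(n−1)+0.5)/n` shrinkage before fitting.
* **Composition** — every pixel is assigned to exactly one of
  {black, yellow, clear} by a deterministic HSV rule: *black* if value
  ≤ `v_max` (default 0.35); otherwise *yellow* if hue ∈ [30°, 75°] and
  saturation ≥ `s_min` (default 0.35); otherwise *clear*. The black
  rule fires first, so dark yellows count as black — melanin overlying
  a xanthophore reads as dark. All thresholds are config-exposed. This
  replaces a manual magic-wand workflow; it is a reproducible
  re-design, not a reconstruction of the manual operator's tolerance
  settings, which have no exact color-space equivalent.

## Compositional geometry

Counts are closed to proportions `(p_black, p_yellow, p_clear)`; rows
containing a zero count get a 0.5-pixel pseudo-count on every part
first (configurable). The models operate on two orthonormal isometric
log-ratio balances from the sequential binary partition
{yellow, black | clear}, {black | yellow}:

    z1 = sqrt(2/3) * ln( sqrt(p_yellow * p_black) / p_clear )
    z2 = sqrt(1/2) * ln( p_black / p_yellow )

The normalising constants `sqrt(rs/(r+s))` make the map an isometry
(Aitchison distance = Euclidean distance in (z1, z2)); any other fixed
constants would only rescale coefficients. z1 is invariant to swapping
black and yellow inside the geometric mean, so the order there is
immaterial. The inverse transform reconstructs clr coordinates from
the two basis vectors, exponentiates and closes; round-trip error is at
machine precision. Ternary plots use black at the apex, yellow lower
left, clear lower right.

## The two regression models

**Darkness.** `y ~ Beta(μφ, (1−μ)φ)` with treatment-coded linear
predictors on `logit(μ)` and `log(φ)`. Exposure time is a 4-level
categorical factor (0/1/4/12 h) — the experiment reports per-level
estimates with an apparent asymptote after 4 h, which a linear-in-hours
term could not express. Reference cell: 0 h, *texanum* mother,
*texanum* father. Both predictors include clutch random intercepts;
the μ and φ intercept sets are independent (nothing in the design ties
dispersion heterogeneity to mean heterogeneity, and independence is the
conservative default), each `Normal(0, τ)` with its own τ.

**Composition.** `(z1, z2) ~ MVNormal(μ, Σ)` with the mean structure
time + mother + father + mother×father + mother×time + father×time plus
clutch intercepts `U ~ MVNormal(0, T)`. `U` is modelled as a correlated
2-vector (full `T`): the two balances are biologically coupled, since a
clutch with more chromatophore cover typically also shifts its
black:yellow ratio. `Σ` is homoscedastic across cells; only the mean is
modelled with predictors. Posterior cell means are mapped through the
inverse ILR per draw, so each draw is a valid composition; per-part
posterior means of this nonlinear map need not sum exactly to one and
are reported with per-part HDCIs.

**Priors** (weakly informative, overridable): `Normal(0, 2.5)` on all
fixed effects on the link/balance scales, `Exponential(1)` on every
random-effect and residual scale, LKJ(2) on the 2×2 correlations. On
the logit scale ±2.5 spans essentially the whole (0,1) mean range, so
these regularise without constraining; prior-predictive darkness spans
(0,1) without boundary pile-up.

## Sampling and diagnostics

Posteriors are sampled with a differential-evolution ensemble sampler
(emcee; 80 % DE moves, 20 % DE-snooker) on a fully unconstrained
vector: scales as logs (Jacobian included), correlations via atanh,
clutch effects non-centred (`u = τ·u_raw`). Walker count defaults to
~2× the parameter dimension; walkers are initialised in a tight cloud
around a moment-based centre (logit of the mean darkness, log of the
method-of-moments precision). After warm-up the kept ensemble is split
into four disjoint walker groups treated as pseudo-chains for
rank-normalised split R-hat and bulk/tail ESS (arviz). The convergence
contract — R-hat < 1.01 and bulk ESS > 400 for fixed effects and scales
— is recorded on every fit as a `converged` flag; non-convergence is
flagged, never silent. Ensemble walkers are not independent chains, so
these diagnostics are interpreted as necessary-but-approximate checks.

Default run lengths are 2000 warm-up + 500 kept steps (thinned by 5).
The test suite and the acceptance script use shorter, stated run
lengths per fit (darkness 1100 + 300, composition 1800 + 400; nested
comparison variants shorter still) — chosen as the smallest runs whose
HDCIs are calibrated in the recovery study, trading a little tail
accuracy for a tractable 20-replicate study.

`beta_loglik` is evaluated from the shape-parameter form with `betaln`;
linear predictors are clipped at ±30 before the inverse links (both
links are saturated far before that, so the clip only prevents overflow
during early exploration).

## Inference utilities

* **HDCI** — the shortest contiguous interval containing
  `ceil(prob·n)` sorted draws; the sample estimator of the
  highest-density interval for unimodal posteriors. It is slightly
  narrow-biased at small draw counts, which is why run lengths above
  were chosen by calibration.
* **WAIC** — `elpd_i = log mean_d exp(ll_di) − var_d(ll_di)` with the
  unbiased (S−1) variance, log-sum-exp stabilised, SE over
  observations.
* **PSIS-LOO** — delegated to arviz; per-observation Pareto k̂ is
  reported and k̂ > 0.7 flagged. For hierarchical fits the pointwise
  likelihood is conditional on the drawn clutch effects.
* **Model comparison** — models ranked by elpd; difference SEs from
  pointwise elpd differences against the best model. The shipped
  comparison ladders are the printed model formulas plus nested
  simplifications (dropping genotype×time, interactions, or time).

## The synthetic study

The generator emulates the real experimental conditions: 4 reciprocal
pairings × 3 clutches × 4 exposure levels × 6 larvae (288 rows), beta
darkness and ILR-normal compositions with multinomial pixel allocation
over 105,000 pixels. Default ground-truth parameters were set once so
the simulated study resembles the published effect regime — *texanum*
baseline darkness ≈ 0.30, exposure effects rising steeply to 4 h then
plateauing, a maternal *barbouri* effect about twice the paternal one,
melanophore cover rising from ~20–30 % at baseline toward ~70 % in
exposed *barbouri* — with clutch SDs of 0.10–0.15 and residual balance
SDs of ~0.3. Dosage bookkeeping carries the measured 1-h per-band
dosages (305/320/380 nm and PAR) and scales them linearly with time.

Rendered patches paint yellow then black disks (radius 4–14 px,
merging allowed) on a pale background and then correct individual
pixels so the label mask matches the requested counts exactly; the mask
is therefore an exact oracle for the classifier. Rendered patches use
pure class prototype colours with optional additive noise — they do not
emulate illumination gradients, chromatophore texture, translucency or
focus blur, so classifier tests certify the decision rule and its noise
robustness, not performance on real micrographs. Likewise the
generator draws observations from the same model families the fits
assume; recovery results certify the inference machinery, not
robustness to model misspecification (no ontogeny, mortality,
behaviour, or temperature-control arm is simulated).

## Degenerate inputs and edge rules

All-zero compositions are rejected; zero counts are pseudo-counted
before log-ratios. Crop rectangles are half-open, 0-based, and must lie
fully inside the image. Infeasible render requests (counts not summing
to the patch area) are rejected. Beta responses at 0 or 1 are rejected
by the likelihood and must be nudged explicitly. Non-positive-definite
covariances are rejected at simulation time; sampled covariances are
positive definite by construction.

## Known limitations

* Ensemble MCMC mixes more slowly than gradient-based samplers on these
  ~40–60-dimensional posteriors; weakly identified dispersion-side
  parameters (γ, τ_φ) carry visible prior influence at n = 288.
* The HDCI estimator assumes unimodality; multimodal posteriors would
  need a different summary.
* The classifier is a fixed per-pixel rule; it does not adapt to
  lighting differences between imaging sessions.
* Clutch is the only grouping factor; maternal identity across clutches
  is confounded with clutch in this design and not separately modelled.
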