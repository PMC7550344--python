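# Methods

## The inference chain and its assumptions

The package estimates the metabolic grade of a fossil taxon from three
independent proxies, none of which requires soft-tissue preservation:

1. **Maximum lifespan from cementum.** Cementum grows appositionally for
   life, one thick + one thin increment pair per year, so the largest
   increment count observed in a taxon's sample is a *minimum* estimate of
   its *maximum* lifespan. The estimate is biased low by outer-increment
   damage and by sections that miss increments, never high (accessory
   increments from splitting/coalescence are the one inflation channel,
   which is why counting uses the max over multiple virtual sections read
   blind by several observers, not a single section).
2. **Body mass from cranial allometry.** Two published scaling laws
   bracket mass; the dentary law (natural-log form) gives the maximum, the
   skull law (base-10 form) the minimum, and the arithmetic mean is the
   point value. The skull law's printed notation says "ln" but only a
   base-10 reading reproduces its own published worked outputs; it is
   implemented base-10 with a note in the docstring. Skull length
   (1.0458 × dentary) is carried unrounded: rounding it to 0.1 mm moves
   the final mass by ~0.2 g.
3. **Trait projection.** Extant lifespan–msSMR and lifespan–K relations
   (log10–log10) are assumed to extend to the fossil: the fossil's lifespan
   is evaluated on the fitted line and back-transformed. The projection CI
   is the regression's confidence band (uncertainty of the mean), not the
   prediction band; the fossil's lifespan enters as an exact integer with
   no sampling-error model. Fossils are never placed on the phylogeny.

The blood-flow index Qi = r⁴/L assumes Poiseuille-like laminar flow
through the nutrient foramen, so flow capacity scales with the fourth
power of radius; multiple foramina are combined by summing radii first
(total entry/exit potential), with per-foramen r⁴ summation available as
an alternative rule. All lengths are normalized to mm at ingest; Qi is in
mm³ and the index is invariant up to s³ under a global unit change.

## PGLS formulation

For species trait vectors x, y on a rooted tree with branch lengths in
Myr, the phylogenetic VCV has V[i,j] = shared root-to-MRCA path length and
V[i,i] = root-to-tip distance. Pagel's λ multiplies the off-diagonal
only. The regression uses V in correlation form C = D^{-1/2} V D^{-1/2}
(for an ultrametric tree, V/height); coefficient estimates are invariant
to this scaling and σ² becomes the marginal residual variance, which is
what prediction intervals need and matches how the correlation structure
enters R's `gls()`. Estimation whitens by the Cholesky factor of C and
solves ordinary least squares; the closed form is
β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y.

λ is estimated by maximizing the restricted (REML) log-likelihood

  ℓ_R(λ) = −½[(n−p)(log 2π + log σ̂² + 1) + log|C(λ)| + log|XᵀC(λ)⁻¹X|],
  σ̂² = RSS(λ)/(n−p)

over λ ∈ [0, 1] by golden-section search (40 iterations, interval width
≈4e-9 < 1e-6), with the endpoints evaluated explicitly so boundary maxima
are returned exactly. λ outside [0, 1] loses the PSD guarantee and is
rejected (an explicit override exists on the VCV builder). When the
estimate falls below 1e-3 (configurable) the pipeline drops to plain GLS
with identity covariance — numerically the same fit, honestly labelled.

The overall F statistic compares the fit against the intercept-only GLS
model on the same C; r² = 1 − RSS/TSS is computed in the whitened space
(the underlying study does not define its r², so printed r² values are
not directly comparable — this definition is the package's own and is
stated here deliberately).

**Tree distributions.** Given several candidate trees, each is fitted and
the tree with the maximal F is selected, ties broken by lowest index; all
per-tree F values are retained for audit. Clades are combined by grafting
two ultrametric trees under a new root at a fixed age (stem branch = root
age − clade height), e.g. 275.9 Ma for squamates+crocodilians and
325.5 Ma for reptiles+mammals.

**ANCOVA ladder.** Four nested mean models — common slope+intercept,
varying slope, varying intercept, varying both — are fitted under a
single C whose λ is REML-estimated once on the richest model (nested F
tests need a common covariance; the source is silent on this, so it is a
design choice here). Each richer model is compared with the baseline by
F = [(RSS₀ − RSS₁)/Δp] / [RSS₁/(n − p₁)] on whitened RSS; likelihood
ratios (ML) are reported alongside but not used for selection. The
selected model is the significant comparison with the lowest p, or the
baseline if none reaches 0.05. Partial η² is reported as
1 − RSS_model/RSS_base; it is not validated against any external value.

**Intervals.** At x₀, the CI uses the coefficient covariance
(XᵀC⁻¹X)⁻¹σ̂² with a t quantile on n−p df; the PI adds σ̂², treating the
new observation as phylogenetically independent of the sample (appropriate
for projecting a fossil that is not on the tree). PI ⊇ CI always; the CI
is narrowest at the design mean.

## Statistics conventions

- CV uses the sample (n−1) standard deviation; for two values this equals
  |Δ|/√2, which is the form consistent with the downstream effect size.
- Cohen's d uses the unweighted pooled sd √((s₁² + s₂²)/2); with the
  group summaries it is applied to here, this is the only pooling that
  reproduces the published effect size to rounding.
- One-way ANOVA accepts raw groups and (n, mean, sd) summaries
  interchangeably; the summary path reconstructs SS_between and SS_within
  algebraically and equals the raw path exactly when summaries derive
  from the raw data.
- Shapiro–Wilk is computed for n ≥ 3 only; for smaller groups it returns
  "not computable" rather than a degenerate W = 1.
- Consensus across observers is the median of observer final counts
  (max-over-sections), with .5 ties rounded half up; max and min rules
  are selectable because the choice is not dictated by the data model.
- Display rounding of masses is half-up to 0.1 g; all intermediate values
  are carried at full precision.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the simulated study conditions: pure-birth
(Yule) clades of 100 tips at height 100 Myr (exponential waiting times,
rescaled to the stated height so grafting ages are controllable), grafted
at 325.5 Ma for two-clade designs; log10 mass uniform on [0.5, 5] (≈3 g
to 100 kg, the span of a terrestrial comparative sample); lifespan slope
0.26 with clade intercepts 0.16 and 0.60; msSMR and K linear in log10
lifespan with slopes −0.83/−0.692; residual sd 0.15 (log10 units, giving
r² near the published ≈0.7 at this mass spread) with residuals drawn from
N(0, σ²C(λ)) via Cholesky (1e-10 jitter retry) using the same VCV code
path the estimators consume. Increment tables give each specimen 3–5
sections × 3 observers, each reading = truth − Bernoulli(p_miss = 0.1) +
Poisson(p_accessory = 0.02), floored at 1 because cementum starts at
eruption. Foramen radii are log-normal with median ≈0.05 mm, the order of
small-mammal nutrient foramina. Identical seeds give byte-identical
outputs.

Not emulated: birth–death extinction dynamics, diagenetic damage or
images of cementum, measurement error in masses, non-lambda correlation
models (OU), and multi-predictor regressions. Passing recovery tests on
these simulations therefore shows the estimators are correct under the
stated model, not that real comparative data satisfy it.

## Problem sizes used in validation

Simulation-based checks use 200 replicates of 200-tip trees for slope-CI
coverage and λ recovery (mean |λ̂ − λ| ≤ 0.15 at λ ∈ {0, 0.5, 1}); 500
null and 200 shifted two-clade simulations of 25 tips per clade for
ANCOVA type-I error (5% ± 2%) and power (≥95% at a 5σ intercept shift) —
the F test's null calibration is size-exact under the model, so the
per-clade tip count trades runtime against nothing; and 10 fits × 100 new
points for marginal 95% PI coverage. Small-n (≤6) fits are checked
against a naive explicit-inversion GLS oracle to 1e-10, and a fixed-λ fit
against R's `nlme::gls` with `ape::corPagel` to 1e-6.

## Known limitations

- λ is profiled on [0, 1]; correlation structures permitting λ > 1 or < 0
  are intentionally out of range (PSD safety) and only the raw VCV builder
  can be overridden.
- The ANCOVA supports exactly two groups and one covariate.
- Published regression lines ingested as coefficients-only carry no
  coefficient covariance, so projections onto them are point estimates.
- Polytomies pass through unresolved; no tree inference or dating beyond
  fixed-age grafting is attempted.
- The taxon lifespan estimator inherits cementochronology's downward bias
  from damaged outer increments; it is a minimum estimate by construction.
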