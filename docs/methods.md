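# Methods

This note documents the models implemented in `allomix`, the defaults and
their units, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Isotope preprocessing

Trophic level is estimated per sample from nitrogen isotopes with a single
end member: `TL = TL_base + (δ¹⁵N_consumer − δ¹⁵N_baseline) / TDF_N`, with
herbivorous cladocerans (TL 2.1 ± 0.1) as the baseline for pelagic,
profundal and fish compartments and littoral *Asellus* (TL 2.1 ± 0.1) for
littoral zoobenthos; TDF_N = 3.4 ± 1.0 ‰. Baselines are resolved per lake
from the consumer table itself; a lake missing its baseline taxon gets an
imputed value from an ordinary least-squares regression of baseline lake
means on a surrogate bulk group across the remaining lakes (adjusted R² is
reported with the small-sample correction `1 − (1−R²)(n−1)/(n−2)`).
Resolution order is: measured baseline → regression imputation → error;
there is no cross-compartment fallback. Trophic levels below 1 are clamped
to 1 with a warning, because the water-exchange exponent `TL − 1` must be
non-negative. Zoobenthos samples with δ¹³C at or below a configurable
threshold (default −40 ‰) are treated as methane-influenced — methanogenic
carbon carries anomalously depleted values and distorts the nitrogen
baseline logic — and their TL is fixed to the baseline level.

Hydrogen in consumer tissue partly derives from ambient water rather than
diet. With a per-trophic-level exchange proportion ω (default 0.23 ± 0.09)
the compound proportion after `TL − 1` transfers is
`ω_c = 1 − (1 − ω)^(TL−1)`; non-integer trophic levels propagate through
this formula without rounding since it is continuous. Measured values are
corrected to the source scale by
`δ²H_corr = (δ²H − ω_c·δ²H_water)/(1 − ω_c)`, which is exact for the forward
mixing model (the package asserts this round trip to 1e−9 ‰). The
correction amplifies measurement noise by `1/(1 − ω_c)`; a fixed additional
observation SD (default 13 ‰) is attached to every corrected value to
represent the propagated baseline/TDF/ω uncertainty. It enters the model as
an additive variance term outside the multiplicative error factor, because
it is preprocessing uncertainty rather than source-mixing process error;
`MixingModelConfig.sigma_extra` can override it.

## Sources

The terrestrial end member is measured inlet dissolved organic matter; the
aquatic end member is lake-water δ²H plus a photosynthetic discrimination of
−110 ‰ (the mean offset between benthic algae and water). Spatiotemporal
SDs of 11.2 ‰ (terrestrial) and 23.6 ‰ (aquatic) apply to every lake. Lakes
without a measurable inlet may borrow the nearest lake's inlet value
(flagged). Two sensitivity scenarios replace end members without touching
consumer records: a bacterial step
`δ²H_bact = δ²H_inlet·(1−ω_b) + δ²H_water·ω_b` with ω_b = 0.17 as the
terrestrial source, and measured benthic algae as the aquatic source.
Consumers are screened against the per-lake source envelope
`[min − k·SD_min-source, max + k·SD_max-source]`; each endpoint uses its own
source's SD (a pooled-SD variant would be narrower at the terrestrial end;
the per-source reading is the conservative choice and k is configurable).
Screening is diagnostic only — no sample is ever excluded.

## The mixing model

With two sources the composition has one ILR coordinate,
`φ = √½·ln(p_aq/p_terr)` with the aquatic source first (alphabetical, as in
common mixing-model software); allochthony is `1 − p_aq`, so a positive
covariate slope in ILR space means declining allochthony along the gradient.
The hierarchical regression is

```
φᵢ = (β₀ + b₀,s(i) + u_l(i)) + (β₁ + b₁,s(i)) · x_l(i)
yᵢ ~ Normal(mᵢ, Vᵢ),  mᵢ = (1−pᵢ)T_l + pᵢA_l,
Vᵢ = ξ·[(1−pᵢ)²σ_T² + pᵢ²σ_A²] + σ_extra²
```

with taxon random intercepts and slopes and lake random intercepts, and a
trophic discrimination factor of zero for hydrogen (no TDF variance term).
Priors: the two-source proportion itself is flat; fixed effects get
Normal(0, 10²) in ILR units, variance-component SDs Uniform(0, 5), and the
multiplicative error ξ Uniform(0, 20) — all weakly informative at survey
size and configurable. A fitted mean ξ below 1 indicates the nominal source
variances overstate the observed process scatter.

### Sampling

The posterior is sampled with the emcee affine-invariant ensemble using
differential-evolution moves, run as several independent ensembles
("chains", default 3) from distinct seeds. One ensemble step advances every
walker (≥ 2·ndim + 2, at least 64), so far fewer steps are needed than with
single-walker MCMC; the defaults are 3 000 steps with 2 100 burn-in and
thinning 10, which on the default synthetic design yields ≈ 10⁴ retained
draws per chain and passes all convergence checks. `paper_scale()` provides
survey-scale settings. Walkers start from a cheap empirical estimate
(per-observation inversion of the mixing equation, clipped to [0.02, 0.98],
then least squares in ILR space) plus a small jitter.

Lake intercepts and taxon slopes are weakly identified, so their posteriors
form the classic funnel against their hierarchical SDs; they are sampled in
a non-centered parameterization (standardized deviates, with the Jacobian
folded into the sampling density) and converted back to natural units for
all reported draws. The taxon intercepts are data-dominated and stay
centered. This is purely an internal reparameterization; the posterior is
unchanged, and the public `log_posterior` is in natural coordinates.

### Diagnostics

Per parameter: rank-normalized split R̂ (arviz) across chains on the
thinned draws, and a Geweke z comparing the ensemble mean of the first 10 %
of post-burn-in steps with the last 50 %, with segment standard errors from
an autocorrelation-corrected effective sample size estimated by treating
walkers as parallel chains (plain spectral estimates on a single walker are
unstable at these lengths). A fit is flagged converged when all R̂ ≤ 1.05
and ≥ 95 % of parameters have |z| ≤ 2; non-convergence raises a warning,
is recorded in the manifest, and gives a nonzero CLI exit — never silently
downgraded. Identical constant chains report R̂ = 1; a single chain reports
R̂ as unavailable.

### Summaries and comparison

Taxon intercept allochthony (covariate = 0, the environmentally average
lake), per-taxon credible curves along the covariate grid, per-lake×taxon
point estimates (including the lake effect at the lake's covariate), and a
global-average-consumer curve are all equal-tailed median/95 % summaries of
`1 − ilr⁻¹(φ)` draws. The global curve integrates random effects by drawing
fresh effects from their posterior hierarchical SDs per draw (the
alternative — zeroing the effects — is available via `global_mode="zero"`;
sampling was chosen because it propagates between-taxon variance into the
interval, which is what "an average consumer" should show). A taxon's slope
is called non-zero when its 95 % interval excludes 0 — in one-dimensional
ILR space this directly tests the covariate effect.

Model comparison uses DIC = D̄ + p_D with p_D = D̄ − D(θ̄) (deviance at the
posterior mean), Akaike weights `w ∝ exp(−ΔDIC/2)`, and an approximate R²
(squared Pearson correlation of observations with posterior-mean fitted
means). Pointwise log-likelihood matrices are retained on each fit so an
external PSIS-LOO implementation can consume them; PSIS smoothing itself is
out of scope.

## Environmental gradient and DOM indices

The PCA standardises all variables (zero mean, unit variance, ddof = 1) so
the decomposition is of the correlation matrix; loadings are reported as
Pearson correlations between original variables and scores (numerically
equal to eigenvectors scaled by √eigenvalue), and PC1's sign is fixed by
requiring the forest-cover loading to be negative, making PC1 run from
forested to agricultural catchments deterministically and idempotently. The
number of environmental variables is not hard-coded: any table with ≥ 15
complete numeric columns is accepted and the count is recorded.

SUVA is `(A₂₅₄ / pathlength in m) / DOC` in L mg⁻¹ m⁻¹ with decadic
absorbance (A₂₅₄ linearly interpolated if 254 nm is not sampled); the slope
ratio SR fits ordinary least squares of ln(absorption) on wavelength over
275–295 nm and 350–400 nm separately and returns the ratio of negated
slopes, so S is positive for decaying spectra; a flat long-wavelength window
raises an explicit division error rather than returning infinity. N:C of
particulate organic matter is a plain mass ratio.

## Synthetic data

The generator emulates the study design: 35 lakes evenly spaced along a
single environmental gradient (even spacing guarantees an identifiable slope
at small n; uniform-random spacing is available), water δ²H of −60 ± 5 ‰,
inlet DOM 10 ‰ below water, aquatic source at water − 110 ‰ — a terrestrial–
aquatic separation of ≈ 100 ‰ — and eight consumer groups whose ILR
intercept offsets span near-zero allochthony (copepods, *Chaoborus*) to very
high allochthony (profundal chironomids), with baseline taxa present in
every compartment. True global ILR intercept 1.4089 (≈ 12 % allochthony at
the gradient midpoint) and slope 0.84 per covariate unit; the covariate
spans [−2, 2], on the scale of a standardized principal-component score.
Per-taxon slope offsets sum to zero so the global slope is the mean taxon
slope. Residual measurement noise is 8 ‰ (instrument precision ~3 ‰ plus
tissue heterogeneity), δ¹⁵N noise 0.3 ‰, lake-effect SD 0.2 ILR units.

Spatiotemporal source variation is realised **per observation**: each
consumer sample's mixture draws its terrestrial and aquatic source values
around the lake's nominal end members with the stated SDs (11.2/23.6 ‰).
This mirrors the mixing model's process-error treatment, in which source
variance enters each observation's likelihood independently. The
alternative — drawing one realised source mean per lake and sharing it
across all of that lake's samples — was implemented and rejected: a single
±24 ‰ aquatic draw shared by a whole lake cannot be absorbed by the model's
scalar lake effect, clips asymmetrically near the simplex boundary, and
attenuates the recovered gradient slope by ~40 % even with noise-free
measurements, i.e. it simulates a different (and unestimable) error process
than the one the model states. Consumers integrate sources over time and
space, so independent per-sample realisations are also the more defensible
ecological reading of a "spatiotemporal SD".

The environmental table is a one-latent-factor construction: each of the 18
variables is `loading · gradient + noise` with a fixed sign pattern (forest,
DOC, SUVA negative; agriculture, nutrients, pH positive). It makes no claim
of realism beyond letting the PCA recover the gradient with the right
orientation; the joint distribution of real lake variables is richer.

**What the synthetic tests show** — that the implementation inverts its own
forward process: exact round-trip of the ω-correction, slope/intercept
recovery under the stated design, DIC preference for the true covariate
model, and the ω-sensitivity structure (higher assumed ω → lower absolute
allochthony, especially at high TL, with taxon ranking preserved). **What
they do not show** — robustness to real-data features absent from the
generator: seasonal source and baseline drift, tissue-turnover lag,
lake-level source misspecification, non-Normal residuals, and guild
assignment error.

## Problem sizes and test scale

The shipped tests run the full design (35 lakes × 8 taxa × 3 samples = 840
observations) at 2 000–3 000 ensemble steps with 2 chains for the recovery
and sensitivity studies, and a reduced 12-lake, 4-taxon design for the
repeated model-comparison study; these sizes give stable results while
keeping the whole suite in the tens of minutes on a single core. Survey-
scale runs simply swap in `MixingModelConfig.paper_scale()`.

## Known limitations

* Reproducing the original survey's numerical estimates requires the real
  deposited isotope and environmental tables and survey-scale MCMC; the
  pipeline accepts those CSVs but ships no field data.
* The ensemble sampler's walkers are coupled, so effective-sample-size
  estimates treating walkers as chains are approximate; they are used for
  diagnostics, not for inference.
* The ±13 ‰ preprocessing uncertainty is a single constant; a per-sample
  propagation (by TL and ω uncertainty) would be heteroscedastic.
* No concentration dependence, no informative source priors, no more than
  two sources.
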