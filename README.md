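# allomix

Hierarchical Bayesian estimation of **terrestrial support (allochthony) of
lake consumers** from hydrogen and nitrogen stable isotopes.

Lake food webs are fuelled by two basal carbon pools: organic matter produced
inside the lake by algae (autochthonous) and organic matter imported from the
catchment (allochthonous, t-OM). Because terrestrial plants transpire, their
tissues are strongly enriched in ²H relative to aquatic primary producers, so
consumer δ²H traces the terrestrial share of assimilated organic matter. This
package implements a complete multi-lake analysis of that tracer for users
studying land-use effects on aquatic food webs:

* **Trophic levels** from δ¹⁵N with a single-end-member model,
  `TL = 2.1 + (δ¹⁵N_consumer − δ¹⁵N_baseline) / 3.4`, with cross-lake
  regression imputation of missing baselines and a δ¹³C rule that fixes
  methane-influenced zoobenthos to the baseline level.
* **Water-exchange (ω) correction** of consumer δ²H. A proportion ω (0.23 ±
  0.09 per trophic level) of tissue hydrogen comes from ambient water rather
  than diet and compounds up the food chain,
  `ω_compound = 1 − (1 − ω)^(TL−1)`; measured values are corrected back onto
  the source scale by
  `δ²H_corrected = (δ²H_consumer − ω_compound · δ²H_water) / (1 − ω_compound)`.
* **Per-lake sources**: inlet dissolved organic matter (terrestrial end
  member, SD 11.2 ‰) and photosynthesis-adjusted lake water (aquatic end
  member, water − 110 ‰, SD 23.6 ‰), plus bacterial-step and benthic-algae
  sensitivity scenarios and a diagnostic ±k·SD source-envelope screen.
* **The mixing model**: with two sources the composition has a single
  isometric log-ratio (ILR) coordinate
  `φ = √½ · ln(p_aq / p_terr)`, and the model is the hierarchical regression

  ```
  φᵢ = (β₀ + b₀,species + u_lake) + (β₁ + b₁,species) · x_lake
  yᵢ ~ Normal( (1−pᵢ)·T + pᵢ·A ,  ξ·[(1−pᵢ)²σ_T² + pᵢ²σ_A²] + σ_extra² )
  ```

  i.e. `allochthony ~ 1 + PC1 + (1 + PC1 | species) + (1 | lake)` with a
  multiplicative process×residual error ξ and a flat prior on the source
  proportion. Sampling is by seeded ensemble MCMC with Gelman–Rubin and
  Geweke convergence checks; models are compared by DIC, Akaike weights and
  approximate R², with pointwise log-likelihoods exported for LOO tools.
* **Environmental gradient**: correlation-matrix PCA of the lake
  morphometry / chemistry / land-use / OM-quality table (PC1 oriented so
  forest cover loads negatively), plus SUVA₂₅₄, the spectral slope ratio
  S₂₇₅₋₂₉₅/S₃₅₀₋₄₀₀ and the N:C ratio of particulate organic matter.
* **A synthetic-data generator** with known ground truth (35 lakes, 8
  consumer groups spanning trophic levels 2.1–3.8, global ILR slope 0.84,
  global allochthony ≈ 12 % at the gradient midpoint) so the whole pipeline
  is testable without any data download.

## Worked example

Simulate a survey with the default design, fit the mixing model against the
(known) environmental gradient, and summarise allochthony:

```python
import numpy as np
from allomix import GeneratorConfig, MixingModelConfig
from allomix.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    simulate=GeneratorConfig(seed=1),
    covariate="latent",     # the simulated gradient; use "pc1" for PCA scores
    mixing=MixingModelConfig(chains=2, iterations=3000, burn_in=2100, thinning=10),
    seed=1,
)
result = run_pipeline(cfg)
man = result["manifest"]
print(f"converged: {man['converged']}  max R-hat: {man['rhat_max']:.3f}")
slope = result["model"].posterior_["beta1"]
print(f"global ILR slope: {np.median(slope):.2f} "
      f"[{np.percentile(slope, 2.5):.2f}, {np.percentile(slope, 97.5):.2f}]  (true 0.84)")
print(result["summary"]["taxon_intercepts"]
      [["taxon", "allochthony_median", "allochthony_lo95", "allochthony_hi95"]]
      .round(2).to_string(index=False))
```

Output:

```
converged: True  max R-hat: 1.007
global ILR slope: 0.86 [0.65, 1.11]  (true 0.84)
               taxon  allochthony_median  allochthony_lo95  allochthony_hi95
             asellus                0.62              0.57              0.66
           chaoborus                0.01              0.00              0.02
 chironomid_littoral                0.30              0.24              0.36
chironomid_profundal                0.83              0.79              0.88
           cladocera                0.21              0.14              0.27
            copepoda                0.01              0.00              0.03
         perch_large                0.12              0.06              0.17
         roach_large                0.06              0.03              0.10
```

The slope credible interval covers the generating value 0.84 (a positive ILR
slope means allochthony *declines* along the gradient under the
aquatic-first convention), and the taxon intercepts — allochthony of each
group in an environmentally average lake — recover the generated contrast
from near-zero (copepods, *Chaoborus*) to very high (profundal chironomids).

## Command line

```bash
allomix simulate --seed 3 --out data/          # write consumers/sources/environment/truth CSVs
allomix prep     --config run.yaml --out out/  # preprocessing + source pairs only
allomix fit      --config run.yaml --seed 1 --out out/
allomix scenarios --config run.yaml --seed 1 --out out/   # omega / source sensitivity grid
allomix report   --out out/
```

`run.yaml` mirrors `allomix.pipeline.RunConfig`: top-level keys
`consumers`, `sources`, `environment` (CSV paths) or a `simulate` block, the
`covariate` choice (`pc1`, `forest_pct`, `nc_pom`, `latent`, `none`),
`omega_scenarios`, `source_scenarios`, and nested `trophic`, `source` and
`mixing` blocks whose keys match the corresponding config dataclasses. Input
CSV schemas are documented in `allomix/pipeline.py`. Exit status is nonzero
on any stage error or convergence failure.

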