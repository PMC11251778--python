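# qcpattern

Quantitative colour-pattern analysis through the eyes of a predator, with
Bayesian distributional comparison of pattern means **and** variances across
chemical-defence classes.

The package is built for the study design in which the visual appearance of a
community of aposematic animals (the motivating system is dorid nudibranchs
viewed by a triggerfish, *Rhinecanthus aculeatus*) is quantified from
cone-catch images, reduced to latent pattern factors, and compared across
three levels of chemical defence — undefended, toxic/moderately unpalatable,
toxic/highly unpalatable — at two viewing distances (2 cm and 10 cm). It is
aimed at visual-ecology researchers who want a fully scripted, reproducible
version of that workflow, exercised end to end on synthetic data.

## What it computes

1. **Observer model (receptor-noise-limited).** Per-channel Weber fractions
   ω_i = ν·√(η_max/η_i) from cone abundances η (defaults 1:2:2:2 for
   sw:mw:lw:dbl with ν = 0.05, giving 0.07:0.05:0.05:0.05). Chromatic
   distance between stimuli A and B with quantum catches q:

   ΔS² = [ω₁²(Δf₃−Δf₂)² + ω₂²(Δf₃−Δf₁)² + ω₃²(Δf₂−Δf₁)²] /
   [(ω₁ω₂)² + (ω₁ω₃)² + (ω₂ω₃)²],  Δf_i = ln(q_A,i/q_B,i)

   and luminance distance ΔL = |ln(q_A/q_B)|/ω_dbl on the double-cone
   channel. Images are blurred to the observer's acuity (3 cycles/degree) at
   the viewing distance, cleaned with an RNL ranked filter (falloff 3,
   radius 5, 5 repetitions), and segmented by agglomerative RNL clustering
   (merge while ΔS < 2 **and** ΔL < 4).
2. **157 pattern statistics** per individual per distance: colour adjacency
   (CAA, geometry), visual contrast (VCA, boldness), boundary strength (BSA)
   and local edge intensity (LEIA), with horizontal/vertical variants.
3. **Latent factors.** Rows with missing statistics are dropped; metrics are
   decorrelated (greedy Pearson |r| < 0.6); the factor count comes from
   parallel analysis against the median eigenvalues of 10 000 random
   datasets; a minres (OLS) EFA with varimax rotation yields loadings with
   1000-replicate bootstrap CIs and regression factor scores.
4. **Distributional phylogenetic models.** Per factor,
   y ~ Student(ν, μ, σ) with μ = Xβ + a_species + b_species·distance and
   log σ = Xγ, where X is the full defence × distance interaction,
   a ~ MVN(0, σ²_phy·A) carries the Brownian tree correlation A and b are
   random slopes over distance. Priors: Normal(0,5) on β, γ; Exponential(1)
   on scales; 1+Gamma(2, 0.1) on ν. Four MCMC chains give 8000 post-warm-up
   draws; convergence requires R-hat < 1.01, bulk ESS > 10% and MCSE < 5% of
   the posterior SD. All pairwise cell contrasts are reported for the
   population-average mean and the back-transformed residual SD.

A synthetic-data module generates every input — body-shaped cone-catch
images with planted chromatic/achromatic contrasts, pure-birth trees, assay
tables and factor scores from known model parameters — so all claims are
testable without any external download.

## Worked example

```python
from qcpattern import RunConfig, run_pipeline
from qcpattern.pipeline import report
from qcpattern.synth import GroupDesign, gen_cohort

cfg = RunConfig(seed=1, n_bootstrap=200)
cohort = gen_cohort(GroupDesign(n_individuals=6), seed=1)
species = {r.id: s for r, s in zip(cohort.recipes, cohort.species)}
run_pipeline(cfg, cohort.images(), species, cohort.assays, cohort.tree,
             "out/run1")
print(report("out/run1"))
```

prints (abridged):

```
qcpattern run (version 0.1.0, seed 1)
  stage metrics: n_rows=156
  stage filter: n_dropped=9, n_metrics_kept=9
  stage efa: n_factors=2, explained_variance=[0.309, 0.232]
  stage classify: classes={'toxic_moderate': 5, 'toxic_high': 5, 'undefended': 3}
  stage fit: all_pass=True, max_rhat=1.0070
major loadings (|loading| >= 0.4):
  factor 1: CAA.Asp = +0.66 [+0.53, +0.75]
  factor 1: VCA.BsL = +0.82 [+0.58, +0.90]
  factor 1: VCA.uMS = -0.71 [-0.79, -0.63]
  ...
convergence: max R-hat 1.0070, all pass: True
```

Nine of 156 image×distance rows were rejected because a pattern with fewer
than two perceptual elements yields undefined boundary statistics. Factor 1
loads positively on luminance boundary contrast (VCA.BsL) and pattern
anisotropy (CAA.Asp) and negatively on chromatic contrast (VCA.uMS): the
"bold achromatic, chromatically dull" axis planted in the toxic/highly
unpalatable preset. Its contrasts recover the planted structure:

```
factor  kind         cell_a           cell_b               median  ci_lo  ci_hi
1       mean         toxic_high@20mm  toxic_moderate@20mm  0.95    0.81   1.08
1       residual_sd  undefended@20mm  toxic_high@20mm      0.39    0.23   0.63
```

i.e. highly defended species sit higher on the bold-achromatic axis than
moderately defended ones, and undefended species are more variable at close
range — both with 95% credible intervals excluding zero.

The same stages are available as a CLI:
`qcpattern simulate | qcpa | classify | factors | fit | report`.

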