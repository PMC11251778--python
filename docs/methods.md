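# Methods

This note documents the models, numerical choices and open design decisions
behind qcpattern, and what the synthetic-data tests do and do not establish.

## Observer model

The receptor-noise-limited (RNL) framework treats discriminability as limited
by photoreceptor channel noise. Weber fractions derive from relative cone
abundances and single-receptor noise, ω_i = ν·√(η_max/η_i); with the default
triggerfish parameterisation (η = 1:2:2:2 sw:mw:lw:dbl, ν = 0.05) this gives
0.07:0.05:0.05:0.05. Chromatic distance uses the trichromatic RNL closed form
on log catch ratios of the sw/mw/lw channels; luminance distance is the
log-ratio of double-cone catches divided by its Weber fraction. Both are
symmetric, zero iff the channel ratios agree, and invariant to a common
rescaling of both stimuli — zero catches are rejected rather than clamped, so
the synthetic generator emits strictly positive catches.

**Acuity blur.** The minimum resolvable angle is 1/acuity degrees; the
resolvable extent at distance d is s = 2·d·tan(MRA/2). Each channel is
low-pass filtered with an isotropic Gaussian of σ_px = s·px_per_mm/2 using
mask-normalised convolution so background values never bleed into the region
of interest. The Gaussian was chosen for separability and testability; when
σ_px < 0.25 px the image is already beyond the acuity limit and is passed
through with a warning. At the default synthetic scale (2 px/mm) this makes
the 2 cm view effectively unblurred and the 10 cm view visibly smoothed,
matching the intent of a near/far comparison.

**Ranked filter.** Per repetition, each in-mask pixel is replaced by the
weighted mean of in-mask neighbours within a circular radius, ranked by their
combined RNL distance √(ΔS²+ΔL²) to the centre (rank 1 = nearest) and
weighted rank^(−falloff). This is an explicit, monotone scheme that is
faithful to the published parameters (falloff 3, radius 5, 5 repetitions);
the original toolbox's internal kernel mathematics are not reprinted
anywhere, so fidelity is to parameters and behaviour (noise suppression that
preserves edges), not to a specific reference implementation.

**Clustering.** Agglomerative merging on the 4-connected region adjacency
graph: start from single-pixel regions, repeatedly merge the adjacent pair
with the smallest normalised combined distance max(ΔS/2, ΔL/4) provided both
ΔS < 2 and ΔL < 4 between region means, recompute means, stop when no
adjacent pair qualifies; ties break on the lower label pair. Consequences to
be aware of: (i) the output invariant is that *no adjacent* clusters are
below both thresholds — spatially disconnected elements of identical colour
remain distinct clusters, so cluster count K counts pattern elements, not
colour classes; (ii) the merge order is a design decision (the thresholds,
not the schedule, are the published quantities). The merge/split flip of a
two-patch image sits exactly at the thresholds, which is the property the
acceptance sweep measures.

## The 157-statistic registry

The statistic vector is fixed at 157 names split CAA 33 / VCA 58 / BSA 42 /
LEIA 24. The total and the four families are the published contract; the
exact composition is this package's own, built so that every statistic named
in the motivating analyses exists (CAA.Sc, CAA.C, CAA.Qc, CAA.Qt, CAA.Asp,
CAA.Pt, VCA.ML/sL/CVL/MS/CVS/MSL/CVSL, VCA.MDmax, VCA.BML, BSA.BMSL with
directional variants, LEIA Col/Lum moments). Formula choices: transition
diversity C = exp(Shannon entropy) of off-diagonal transition frequencies;
evenness statistics use inverse-Simpson divided by the number of categories;
Asp = vertical/horizontal off-diagonal transition counts; Pt = mean
same-label run length along transects in mm; contrast kernels are Weber
luminance |L_i−L_j|/(L_i+L_j), RNL ΔL and chromatic ΔS between cluster
means, weighted by element abundance (VCA) or boundary-length share
(VCA.B*/BSA). LEIA takes mean/SD/skew/excess kurtosis of 1-px-offset edge
contrast distributions; degenerate (zero-variance) distributions report 0
moments. Patterns with fewer than two elements produce NaNs by design; NaNs
are emitted, never dropped — the pipeline's row filter handles them.

Horizontal transects run perpendicular to, and vertical transects along, the
body axis (animals are oriented head-up). A perfectly straight horizontal
stripe pattern has no horizontal class transitions and therefore an
undefined aspect ratio; the synthetic stripe generator jitters stripe edges
per column so both orientations are populated, which also mirrors real
animals.

## Defence classes

Assay values are oriented as 1−ED50 (unpalatability) and 1−LD50 (toxicity),
"not rejected" outcomes count as 0, and multiple whole-body extracts per
species are averaged; a species without assays may be imputed as the mean of
two named sister species. Classes: undefended (both 0), toxic/moderately
unpalatable (toxicity > 0, 0.25 < 1−ED50 ≤ 0.74), toxic/highly unpalatable
(toxicity > 0, 1−ED50 > 0.74). The printed source inequalities are
typographically ambiguous; both cuts are closed on the moderate side here.
Combinations outside the three regions raise instead of guessing. The 0.74
cut (the median unpalatability of defended species in the source data) is a
fixed constant by default and can be recomputed behind a flag.

## Factor analysis

Metrics are standardised; the Pearson filter scans columns in a fixed,
documented order (family CAA, VCA, BSA, LEIA, then name) keeping a column
iff |r| < 0.6 against everything already kept — deterministic and
idempotent. Parallel analysis compares observed correlation eigenvalues
rank-wise against the *median* eigenvalues of 10 000 i.i.d. standard-normal
datasets of the same shape ("randomly generated" is unspecified upstream;
i.i.d. normal is the neutral choice), stopping at the first non-exceeding
rank. Note the median criterion retains ≥1 factor on pure noise in roughly
half of seeds — that is a property of the rule, asserted as such in tests.

Extraction is minres/OLS: uniquenesses are optimised (L-BFGS-B, bounded to
(0.001, 0.999), started at 1−SMC) so the off-diagonal residuals of
R − ΛΛᵀ are minimal, with Λ from the top-k eigenpairs of R − diag(ψ).
Varimax uses the classic SVD iteration with Kaiser normalisation. Factors
are ordered by explained variance and sign-fixed so each factor's largest
loading is positive. Scores use the regression method (their variance is the
factor's squared multiple correlation, slightly below 1 by construction).
Bootstrap CIs resample rows, refit, align each replicate to the reference by
permutation/sign via Tucker congruence, and take 2.5/97.5 percentiles;
replicates that fail to converge are skipped and counted (error above 10%).
Near-zero-noise data put loadings near 1 and make the rotation nearly
indeterminate; recovery tests therefore use moderate noise.

## Distributional phylogenetic model

One model per factor. The Brownian correlation matrix A has entries
(shared root-to-MRCA path length)/(root-to-tip depth), unit diagonal; a star
phylogeny gives the identity. The likelihood is Student-t with unknown ν;
the mean combines the full defence × distance interaction (treatment coding,
reference undefended at 2 cm), a phylogenetically structured species
intercept a ~ MVN(0, σ²_phy A) and an independent species slope over
distance; the log residual SD gets the same fixed-effect design. A single
phylo-structured intercept (rather than phylo + i.i.d.) keeps the model
identifiable at 13 species. Priors: Normal(0,5) for β and γ, Exponential(1)
for σ_phy and σ_b, and ν = 1 + Gamma(2, rate 0.1) to keep the likelihood
integrable while allowing near-Gaussian tails.

Sampling is ensemble MCMC (emcee; 80% differential-evolution moves, 20%
snooker moves), vectorised over 100 walkers, with the random effects
non-centred and scales/ν sampled on the log scale. Four independent
ensembles play the role of four chains: each is initialised in a tight ball
around the posterior mode (found by L-BFGS-B), warmed up for 3000 steps,
then thinned (every 120th step) to exactly 2000 draws per chain — 8000
post-warm-up draws total. The centred parameterisation was tried and mixes
far worse here; so do snooker-heavy or KDE move mixtures. The slowest
direction is log σ_phy, whose posterior is weakly identified with 13
species: on most datasets the default budget gives max R-hat ≈ 1.005–1.010,
but adversarial draws of tree and data can leave it near 1.015, and clearly
smaller datasets (e.g. below ~100 rows) may need a longer run. Diagnostics
(rank-normalised split R-hat and bulk ESS via arviz, MCSE = SD/√ESS) are
computed for every parameter, with the pass rule R-hat < 1.01, ESS > 10% of
draws, MCSE < 5% of the posterior SD.

Population-average fitted values set the random effects to zero; contrasts
are posterior medians and central 95% intervals of all pairwise cell
differences, for the mean and for the residual SD back-transformed to the
natural scale. The contrast table is antisymmetric by construction.

## Synthetic data: what it emulates and what it does not

Images are generated directly as cone catches (no RGB intermediate) so the
planted perceptual contrasts are exact: element colours are solved in
log-catch space, where both ΔS and ΔL are linear in the displacement, to hit
the chromatic and achromatic targets exactly. Bodies are ellipses with
stripe, spot, rim or uniform patterns, per-column edge jitter, and
multiplicative log-normal pixel noise for the ranked filter to remove.

Class presets are the study conditions: the toxic/highly unpalatable preset
plants bold achromatic stripes (ΔL 12, ΔS 1); the moderate preset chromatic
spots (ΔL 5, ΔS 3.5); the undefended preset intermediate contrasts with the
largest variance dial (log-SD 0.4 vs ≈0.1), applied at the individual level
(the dial is the among-individual SD of the contrast targets) with a
half-dial species-level displacement for species distinctiveness. Cohorts
use 13 species (3 undefended, 5 moderate, 5 high) at 20 and 100 mm, on a
pure-birth tree. Assay values are drawn inside each class's region so the
classifier reproduces the intended class by construction.

What passing tests show: the pipeline recovers structure it planted —
thresholds, factor counts, loadings, signs and coverage of group contrasts —
at the problem sizes used (cohorts of 13 species × 3–6 individuals at
44–52 px body size; factor tables of ~289 rows × 15 metrics; score datasets
of ~300–520 rows; 20 scaled-down model replicates with 2 chains × 400
draws). What they do not show: behaviour on real photographs (illumination,
segmentation error, within-animal texture, non-elliptical bodies), real
phylogenies with taxonomy-grafted tips, or assay noise — real cone-catch
images enter through the documented TIFF/PNG interface, not through the
generator.

## Known limitations

- Cluster count is connected-component-based (see clustering above), so
  statistics normalised by the number of elements are not comparable with
  colour-class-based implementations on patterns with repeated elements.
- The ensemble sampler's convergence on the phylogenetic scale is the
  binding constraint of the default budget; for small datasets increase
  `warmup_steps`/`thin` rather than walker count.
- The registry's exact name composition beyond the documented anchor names
  is package-specific; map names, not positions, when comparing with other
  toolboxes.
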