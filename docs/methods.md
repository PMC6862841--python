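# Methods

## Canopy coverage from plot imagery

Each plot image is reduced to a canopy fraction in three steps. RGB
channels are first chromaticity-normalized, `r = R/(R+G+B)` etc. (a black
pixel is assigned r = g = b = 1/3), and the Excess Green Index
`ExG = 2g − r − b` is computed per pixel. Normalized rather than raw
channels are used because they are invariant to illumination scaling and
give ExG a fixed range of [−1, 2], which makes the histogram stage stable
across images. The ExG raster is then thresholded by Otsu's criterion: the
values are binned into `n_bins` (default 256, the 8-bit heritage choice)
equal-width bins between the raster minimum and maximum, and the interior
bin edge maximizing the between-class variance ω₀ω₁(μ₀−μ₁)² is returned.
Class means use exact per-bin value sums, not bin centers, so the result
agrees exactly with an exhaustive scan over all candidate cuts; ties take
the smallest edge, and pixels equal to the threshold count as background
(conservative canopy call). Coverage is the fraction of pixels strictly
above the threshold.

Otsu's split is meaningless on near-unimodal rasters (bare soil before
emergence, or full canopy). When the maximal between-class variance falls
below 10⁻⁴, classification falls back to a fixed cutoff `ExG > 0.1`; an
exactly constant raster is reported as coverage 0 (no separable canopy).
The 10⁻⁴ guard is calibrated against the two scales involved: a genuinely
bimodal soil/canopy raster has a between-class variance of order 10⁻²–10⁻³
(class separation ≈ 0.35 in ExG units), while the within-class chromatic
spread of either class alone is below ~0.012 ExG units, i.e. a
between-class variance under ~10⁻⁴ even at the worst split.

Replicate images of the same plot and date (the plot-extraction upstream
produces several views per date) are summarized by the median of their
coverages; the average canopy coverage (ACC) of a plot is the unweighted
mean of its per-date medians over the sampling dates present (missing
dates simply drop out). Coverage is stored as a fraction and formatted as
a percentage with one decimal at I/O.

## Numerator relationship matrix

The A-matrix is built by the tabular method in topological order: founders
get Aᵢᵢ = 1 and 0 off-diagonal, an offspring row is the average of its
parents' rows, and Aᵢᵢ = 1 + A(sire,dam)/2. Selfing is encoded as
`sire = dam = progenitor`, which makes a t-generation selfing chain from a
non-inbred F1 reach the expected diagonal 2 − (1/2)ᵗ without special
cases. A record with one known parent treats the unknown side as an
unrelated founder — the standard convention, keeping A well-defined
without imputation. Ids are opaque strings; ordering is resolved by
topological sort with input order breaking ties, and cycles or references
to absent ids raise structural errors.

## Pedigree animal model by Gibbs sampling

The progeny-row stage fits, one trait at a time,

    y = μ + Xβ + Zg + e,   g ~ N(0, A σ²ₐ),   e ~ N(0, R σ²ₑ)

where Z maps plots to lines (replicated checks share one genetic effect),
X holds optional centered-and-scaled covariates (Yield|ACC adds the
plot-level ACC; β is a single slope — per-genotype slopes are
unidentifiable on unreplicated plots), and R is an optional field
correlation matrix. R is built from rook-adjacent field neighbors: the
neighbor correlation ρ is the Pearson correlation between each plot's
phenotype and the mean of its neighbors, R = I + ρ·(adjacency), with ρ
scaled down minimally if needed so the smallest eigenvalue stays ≥ 10⁻⁶.
An alternative reading of the field-correction idea — the neighbor average
as a fixed covariate — can be obtained by passing the neighbor-mean column
as a covariate; the correlation-matrix form is the default.

The sampler uses the standard full conditionals: normal for (μ, β), normal
for the genetic block, and scaled inverse chi-square for both variances.
For speed, the genetic block is drawn in the basis of the one-time
generalized eigendecomposition A⁻¹U = (Z'R⁻¹Z)U·diag(κ): in that basis the
conditional precision is the diagonal 1/σ²ₑ + κ/σ²ₐ, so an iteration costs
O(n) vector work after an O(n³) setup that can be shared across traits and
replicate datasets. The draws are algebraically identical to a joint block
update of the mixed-model equations; with the variances held fixed the
posterior mean of g equals the Henderson MME solution, which the test
suite checks against a direct solve.

Priors are scaled-inv-χ² with scale S = half the phenotypic variance for
both components and ν = 0.5. The small ν matters: with equal scales,
larger ν (e.g. 4) concentrates the implied prior on
h² = σ²ₐ/(σ²ₐ+σ²ₑ) around 0.5 and visibly biases the posterior-mean
heritability on unreplicated designs, where the likelihood for the
variance split is weak; ν = 0.5 keeps both priors proper while letting the
pedigree likelihood dominate (recovery simulations at n = 2000 show
|bias| ≤ 0.015 across h² ∈ {0.1, 0.3, 0.6}). Heritability is reported as
the posterior mean of the per-draw ratio. Default chain: 6000 iterations,
1000 burn-in, thinning 5, seed mandatory. Convergence is monitored with a
split-chain R-hat on both variance draws.

Reported BLUPs are mean-centered with the mean folded into the intercept:
μ and the genotype-mean are separately identified only through the prior,
and centering makes BLUP tables comparable across traits and runs.

## Truncation selection and response

Lines are ranked by BLUP within each category (Yield, ACC, Yield|ACC) and
the top floor(p·n) (minimum 1) are kept; ties at the cut go to the
lexicographically smaller id. The real experiment deviated from its
nominal intensities for logistical reasons, so a deterministic rule is
fixed rather than emulating those deviations. Overlaps between categories
are tracked per combination; the early/late split assigns a line to
"early" when its R8 (BLUP-scale by default) is ≤ the check's, ties early.
Predicted response uses the breeder's equation ΔG = h²·i·σₚ/L with
i = φ(z)/p for upper-tail normal truncation.

## Multi-location trial evaluation by REML

Preliminary and advanced trials are fitted with

    y = μ + g + loc + rep(loc) + block(rep(loc)) + g×loc + e

with all terms random for PYT and genotype fixed for AYT. The restricted
log-likelihood is profiled over σ²ₑ and maximized over the log variance
ratios γ = σ²ᵢ/σ²ₑ by bounded L-BFGS-B followed by a short Nelder–Mead
polish (the polish removes residual gradient noise; on balanced one-way
data the fit matches the closed-form ANOVA estimators to 10⁻⁶).
Components pinned at the lower bound are truncated to zero and the model
is refit without them; terms that are structurally unidentifiable on the
given design (a single location, blocks coinciding with reps, g×loc
duplicating g when only one location exists) are dropped up front with a
warning. Adjusted line values are μ + gᵢ — empirical BLUPs for random
genotypes, GLS means for fixed — and maturity-adjusted yield refits the
model with centered R8 as a fixed covariate.

Selection categories are compared by Welch (unequal-variance) two-sample
t-tests on per-line adjusted means, two-sided, with the conventional star
thresholds (0.05, 0.01, 0.001, 0.0001) and no multiplicity correction —
each pair is reported on its own, and the tests are on per-line adjusted
means (one value per line), not plot-level data. A line selected by
several categories contributes to each of them. Early and late trials are
meant to be analyzed separately, never pooled. Top-k attribution sorts
evaluated lines by adjusted mean and labels each with every PR category
that selected it, summarizing k into canopy-informed (ACC and/or
Yield|ACC, possibly alongside Yield), Yield-alone, and other.

## Synthetic-data generator

The generator emulates the experiment end to end with known truth:

- **Pedigree**: founders, biparental crosses among them (parent pairs can
  recur, creating families), then single-seed-descent selfing chains;
  terminal individuals are the phenotyped lines. The heritability-recovery
  experiments use 40 founders × 2000 crosses × 3 selfing generations — an
  F4:5-type population of 2000 lines.
- **Breeding values**: multitrait draws from N(0, kron(G, A)) via the
  symmetric square roots of A and of G = D·corr·D, D = diag(h·σₚ). A trait
  with h² = 0 gets exactly zero values. The default architecture uses an
  ACC–yield genetic correlation of 0.87 as its scenario parameter, with
  h² = 0.25 (yield, σₚ = 400 kg/ha), 0.35 (ACC, σₚ = 0.08) and 0.50 (R8,
  σₚ = 5 d).
- **Field**: a modified-augmented-design grid with a check every k-th plot
  (k is a parameter — the real check density is a design unknown),
  experimental lines unreplicated, 1.83 m plots at 0.76 m spacing.
- **Phenotypes**: mean + BV + spatial trend + iid residual. The spatial
  trend is one smooth surface per field (a sum of 3 random-phase 2-D
  cosines rescaled to the requested SD) shared across traits and scaled
  per trait; a shared surface is what a fertility or moisture gradient
  does physically, and it is what induces the positive non-genetic
  canopy–yield correlation seen in real trials — with independent
  per-trait surfaces the characteristic negative correlation between ACC
  BLUPs and Yield|ACC BLUPs does not emerge. Residual variance is
  (1−h²)σₚ² minus the spatial share, floored at 10⁻⁶σₚ² (requesting more
  spatial variance than the non-genetic total is an error).
- **Canopy trajectories**: logistic growth over the sampling dates
  (default schedule 15–54 days after planting), with per-plot rate and
  midpoint jitter and the maximum chosen so the date-average matches the
  plot's simulated ACC.
- **Images**: canopy is a union of elliptical blobs centered on the
  planted row; the blob scale is set by thresholding the distance field at
  the quantile matching the target cover, so the ground-truth mask hits
  the requested fraction to within one pixel. Canopy pixels are
  green-dominant with a per-blob margin (G − R ≈ 52 ± jitter), soil is
  brownish with R ≥ G; pixel-level brightness noise is multiplicative and
  shared across channels so each class's chromaticity — and hence its ExG
  — stays tight while the image remains textured. Default ground sampling
  distance is 1.5 cm/pixel.

What the generator does *not* emulate: mixed soil/canopy boundary pixels,
shadows, weeds, sensor vignetting or photogrammetric artifacts, weather or
lodging. Passing the imaging tests therefore shows the segmentation chain
is correct on clean two-class imagery, not that it is robust to every
field artifact; the guard and threshold logic are the components that
would absorb such effects on real data.

## Problem sizes and numerical choices

Validation experiments are sized so the full suite runs on one CPU:
heritability recovery uses 20 replicate datasets of 2000 unreplicated
plots per h² level (12000-iteration chains, sharing one design
factorization); the Gibbs-vs-MME check uses 200 lines with 40000 kept
draws; REML recovery uses 50 balanced trials of 100 genotypes × 2
locations × 2 replications; the correlated-response law uses 50 replicates
of 2000 lines with selection on phenotype ranking, which for unrelated
lines is the same ranking BLUP would give. The acceptance script repeats
the same computations (10 replicates per h² level and 30 REML trials).

Degenerate inputs are handled explicitly: constant ExG rasters map to
coverage 0; an all-isolated field yields R = I with a warning; non-PSD
trait correlation matrices, negative requested residual variances,
pedigree cycles and unknown parent ids raise errors naming the problem.

## Known limitations

- The spatial model is a stationary neighbor-correlation structure; real
  field trends are anisotropic and the upstream reference for the field
  correction is only loosely specified, so both implemented readings
  (correlation matrix, neighbor-mean covariate) are approximations.
- Traits are fitted separately (matching the original analysis); a
  multi-trait sampler would use the genetic correlations the generator
  already knows.
- Welch tests on category means ignore the genetic overlap between
  categories (a line can sit in several samples), as in the original
  analysis.
- The logistic canopy trajectory cannot represent mid-season setbacks
  (e.g. storm damage years) except through altered rate/midpoint
  parameters.
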