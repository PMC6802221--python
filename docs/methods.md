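# Methods

This note documents the models and procedures implemented in `forestdiv`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Synthetic landscape generator

Each 1-ha plot carries three latent variables: *maturity* M ∈ [0, 1]
(stand development from regeneration to old growth), *heterogeneity*
Het ∈ [0, 1] (vertical and horizontal structural variability) and a
conifer fraction. Latents are independent Uniform(0, 1) per plot;
optional per-region mean shifts can induce region effects (off by
default). All simulators are deterministic given a seed; the pipeline
derives per-stage child seeds from one root seed via `SeedSequence`.

**Point clouds.** Plots are divided into 1 m cells. A fraction
0.4·(1 − M) of cells is canopy gap (ground-only returns). Mean canopy
top height is 5 + 30·M m; a vegetated cell's height is depressed by up
to 60 % · Het (uniform), giving cell-to-cell variance that grows with
heterogeneity. Within a cell, vegetation return heights follow
h·Beta(a, 1) with a interpolating from 20 (Het = 0; returns packed near
the canopy top, height CV ≈ 0.05) to 2 (Het = 1; deep vertical spread).
Returns are Poisson with expectation density × 10⁴; a pulse in a
vegetated cell still reaches the ground with probability 0.1. The
default benchmark density is 4 pulses/m², chosen as a representative
survey density that keeps per-cell return counts realistic while the
1-ha rasters stay cheap to simulate in quantity (operational ALS
campaigns for such analyses span roughly 8–40 pulses/m²; all
coefficients are config-exposed).

**Backscatter.** γ⁰ is simulated directly in dB on a 16×16 raster of
10 m pixels centred on the plot. Mean levels are base − slope·M per
polarisation (VV: −6 − 2.5·M dB, VH: −11 − 4·M dB), with an annual
cosine cycle whose amplitude is 2·(1 − conifer) dB (deciduous stands
have the stronger seasonal cycle) and an additional winter dip of 3·M dB
— so winter VH separates maturity most strongly, mirroring the
empirical pattern that motivates the analysis. Spatial structure is a
per-plot fixed random field (3×3-smoothed, unit SD) scaled by 1.5·Het
dB; speckle is additive Gaussian noise in dB (multiplicative in linear
power), 0.3 dB by default. The acquisition calendar is every 12 days
over one year; season windows default to summer = Jun–Aug, winter =
Dec–Feb and are configurable.

**Phylogeny and communities.** The species pool evolves on a pure-birth
(Yule) tree; because the simulator stops exactly at the n-th speciation,
all tip edges are extended by the exponential waiting time to the next
event so pairwise distances are positive and the tree stays ultrametric.
Each species' maturity optimum is a Brownian-motion trait on the tree,
rank-transformed to (0, 1) — closely related species get similar optima,
so community assembly along maturity produces phylogenetic clustering
that SES-MPD can detect. Occurrence probability is a Gaussian niche
(width 0.15) around the optimum times a richness multiplier
0.45 + 0.55·Het, capped at 0.97; abundances are zero-truncated Poisson
(mean 5 extra individuals) given occurrence, so occurrence =
(abundance > 0) holds exactly. Regional pools are the species observed
anywhere in a region.

The generator reproduces the *monotone couplings* the analysis assumes —
nothing more. It has no radiative transfer, no speckle correlation, no
topography, no geolocation error, no observational error in species
detection. Passing tests therefore demonstrate that the analysis chain
recovers the gradients when they exist and are monotone; they say
nothing about the attainable skill on real acquisitions.

## ALS metrics

Vegetation = non-ground returns, no lower height cut. Layer boundaries
are half-open (lower, upper]: canopy h > 5 m, understorey 2 < h ≤ 5 m,
regeneration 0 < h ≤ 2 m. Penetration ratios divide the returns captured
by a layer by the returns that reached it (returns above a layer drop
out of its denominator; ground returns sit in the regeneration
denominator). Canopy cover is the fraction of all returns above 2 m.
FHD is the Shannon entropy (nats) of vegetation-return proportions over
the three layers, hence bounded by ln 3. Height SD is the sample (n−1)
standard deviation; CV = SD/mean.

**Gaps.** The gap mask marks 1 m cells whose above-2 m return fraction
is below 0.2; cells without returns are no-data and never enter the
mask. Features are 8-connected components; perimeter counts exposed
rook edges. Features below 50 m² are dropped. The perimeter-area-ratio
(PAR = perimeter/area, 1/m) filter is implemented literally — exclude
when PAR < 1.5 — with a config flag (`exclude_low_par=False`) that
inverts it to "exclude thin features (PAR > 1.5)". The literal rule
removes all large compact gaps (PAR falls with size), which is almost
certainly not the intent of the filter's usual phrasing, but the units
and normalisation are not standardised across tools; both readings are
available and neither is silently chosen for the user. Outputs are the
square roots of total surviving area and total surviving edge length.

**Canopy surface.** The CHM takes the highest return per 1 m cell and
fills empty cells by nearest neighbour — a deliberate simplification of
pit-free CHM construction, adequate for the SD and rugosity summaries
used here. The surface ratio triangulates the cell-centre lattice (two
triangles per quad) and divides the 3-D area by the flat lattice area;
for a planar canopy of slope s this equals √(1 + s²) exactly.

## Radar metrics

All temporal statistics are computed in dB. Six median composites
(year/summer/winter × VV/VH), winter − summer differences per
polarisation, the yearly VV − VH difference in dB and the yearly VV/VH
ratio in linear power (10^(ΔdB/10)) — difference and ratio are kept as
distinct quantities because a dB ratio would duplicate the dB
difference. Focal mean and population SD use a 9×9 pixel window
truncated at raster edges (no padding). GLCM texture (dissimilarity
Σp|i−j|, entropy −Σp ln p) is computed per moving 9×9 window with
*per-window* min–max quantisation to 32 grey levels and symmetric
accumulation over four offsets ((0,1), (1,0), (1,1), (1,−1)) pooled
before normalisation; a constant window contributes zero for both
indices. Whether the reference tooling quantises globally or per window
is ambiguous; per-window is the default and both the offsets and levels
are configurable. Plot rows average each metric layer over the 100
pixels whose centres fall in the 1-ha footprint, skipping NaNs. The
default row has 34 named metrics; additional layers (e.g. textures of
the difference composites) can be appended through the layer dictionary.

## Biodiversity responses

Bray–Curtis on presence–absence (equal to Dice dissimilarity) feeds the
ordination. When at least one plot pair shares no species the index
saturates at 1, and a saturated matrix admits a *degenerate* near-zero
stress solution — the configuration collapses into a few tight clusters
whose step-function disparities fit perfectly, which is the global
stress optimum but carries no gradient information. Following standard
ordination practice for long gradients, `composition_dissimilarity`
therefore applies a "stepacross" extension automatically whenever
no-share pairs exist: saturated entries are replaced by shortest-path
distances through sub-saturation links (pairs disconnected even through
paths are capped at the largest finite extended value, with a warning).
Sub-saturation dissimilarities are never modified.

The extended matrix feeds a non-metric MDS minimising Kruskal stress-1
by SMACOF majorisation
alternating with isotonic regression of configuration distances on the
dissimilarity ranks. Stress is evaluated from the raw isotonic fit,
while the disparities entering the Guttman update are rescaled to the
*fixed* norm of the input dissimilarities (Σd̂² = Σδ²): anchoring the
disparity norm to the data keeps the configuration scale stable across
iterations — tying it to the current configuration instead lets the
update contract the points into a numerically coincident cluster
solution whose apparent stress is spuriously near zero. Convergence is a
stress improvement < 1e−6 or 300 iterations; the best of 30 random
starts is kept, centred and rotated to principal axes. Dimensionality is
the smallest k ≤ 5 with stress < 0.2; each k seeds one start from the
(k−1) solution padded with a zero column, which guarantees the reported
stress sequence is non-increasing in k. If no k qualifies, k_max is
returned with a warning.

Richness uses the natural log. SES-MPD compares each plot's mean
pairwise patristic distance with 999 assemblages of the same richness
drawn without replacement from the plot's regional pool;
SES = (obs − mean)/SD of the null. Plots with fewer than two species,
or a null with zero SD (e.g. a star phylogeny), are flagged NaN rather
than imputed. Sample coverage is the Chao–Jost estimator
1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)]; the degenerate n = 1 singleton
case takes the limit value 0.

## Canonical correlation

Columns are standardised; the whitened cross-covariance
Sxx^{-1/2} Sxy Syy^{-1/2} is decomposed by SVD. A ridge of 1e−8 is added
to the within-set covariances before inversion and recorded on the
result. Axis scores are rescaled to exactly unit sample variance, and
each axis is oriented so its largest-|loading| X-side structure
correlation is positive (the underlying signs are arbitrary). Structure
correlations are plain Pearson correlations of the standardised
variables with the axis scores; the redundancy index per axis is the
mean squared structure correlation times the squared canonical
correlation (an RDA-style summary, replaceable by configuration).
Sequential Wilks tests use Λ_k = Π_{i≥k}(1 − rᵢ²) with Rao's F
approximation and its standard degrees of freedom; non-positive df leave
the p-value NaN with a flag.

## Boosted additive models

L2 component-wise boosting: offset = mean(y); per iteration every base
learner is fitted to the residuals by penalised least squares and only
the best (smallest residual sum of squares; ties broken by declaration
order) is added with step ν = 0.1. P-spline learners use cubic B-splines
on 20 equidistant interior knots with a second-order difference penalty,
the penalty strength solved by bisection so each update contributes 4
effective df (trace of the smoother matrix); these defaults mirror the
conventions of the boosting ecosystem this component models itself on.
The categorical ridge learner penalises an indicator basis to
(levels − 1) effective df and serves as the random-intercept surrogate
in the mixed variant; unseen levels predict zero contribution.
Prediction clamps continuous predictors to the training range (constant
extrapolation). Early stopping is selected on a grid (default 10..500,
step 10 — the grid step is a package choice) by out-of-bag squared error
averaged over 25 bootstrap resamples; knots and penalties are built once
on the full training table and the bootstrap enters through observation
weights. mstop is re-tuned inside every cross-validation fold.

## Evaluation

Cross-validation stratifies folds by region: plots are shuffled within
each region and dealt round-robin into k = 5 folds, so every fold spans
all regions. Held-out skill is R² = 1 − SSE/SST about the *test-set*
mean (primary; the squared Pearson correlation is reported alongside)
and RMSE, averaged over folds. The mixed variant adds the region
learner during fitting but scores fixed-effects-only predictions, so
variance explained purely by region membership is excluded. External
validation ordinates training and external communities jointly, fits on
the training plots only and scores the external plots; a
weighted-average projection onto the training ordination would be a
reasonable alternative but joint ordination is the default because it
needs no out-of-sample embedding rule.

## Benchmark scale and numerical choices

The default benchmark is 250 plots in 5 regions with 60 species —
roughly half the plot count of the field network the generator emulates,
a size at which every acceptance-level property is stable across seeds
while a full run (simulation, both metric tables, ordination, canonical
correlation, several cross-validated models) completes in minutes on one
core. Tolerances: GLCM and gap modules are compared to brute-force
oracles at 1e−12/exactly; NMDS against an independent Nelder–Mead stress
minimiser within 0.02 stress; boosting against closed-form least squares
at 1e−6 after 10⁴ iterations. Degenerate inputs (constant windows,
empty cells, single-species plots, zero-variance nulls, unseen factor
levels) return explicit zeros, NaNs-with-flags or named errors as
documented above, never silent imputations.

## Known limitations

* The latent-to-signal couplings are plausibility devices; none is
  calibrated physics, and the generator's noise levels are optimistic.
  Skill numbers on the benchmark are upper bounds by construction.
* The simplified CHM understates canopy surface roughness relative to
  pit-free algorithms at low pulse density.
* The literal PAR gap filter and its inverted reading can produce very
  different gap metrics on landscapes dominated by large openings; users
  must choose consciously.
* NMDS dissimilarity ties (frequent for presence–absence Bray–Curtis at
  high turnover) are handled by the isotonic fit's tie-averaging; no
  primary/secondary tie option is exposed.
* The mixed-model variant is a boosting surrogate for a random
  intercept, not a likelihood-based mixed model; its shrinkage is
  governed by the learner df and mstop, not by an estimated variance
  component.
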