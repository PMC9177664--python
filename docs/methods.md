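# Methods

This note documents the models, conventions and numerical choices behind
`treetraits`, in the order the pipeline runs them.

## Phylogenetic machinery

**Trees.** Input is Newick with branch lengths; tips must be uniquely
labelled. Polytomies are resolved deterministically (input order) into
zero-length binary splits at parse time, so contrasts and pruning
recursions always see a binary tree. Unrooted trees and tree inference are
out of scope; the practical target is up to roughly 5,000 tips with dense
linear algebra.

**Eigenvectors.** The cophenetic matrix D (tip-to-tip path lengths) is
transformed by the principal-coordinates (Gower) convention
G = −½ C (D∘D) C, C = I − 11ᵀ/n. Eigenvectors are sorted by descending
eigenvalue; the share of variation per vector uses only the positive
eigenvalue mass in the denominator (negative eigenvalues can occur for
non-Euclidean distances and are never selectable). Because "double
centring" is also sometimes applied to D itself rather than D∘D, a
`square_distances=False` switch provides that variant; both behave the
same qualitatively downstream. Signs are fixed by making each vector's
largest-magnitude entry positive, so results are platform-stable.

**Independent contrasts.** The pruning recursion: at each internal node the
contrast is the difference of daughter values over the square root of
summed adjusted branch lengths, the ancestral value is the
branch-length-weighted average, and the parent branch is extended by
v_l·v_r/(v_l+v_r). A zero summed branch length in a denominator (a
zero-length cherry that polytomy resolution could not avoid) raises an
error rather than producing infinities. Contrasts define a linear map A
with A·V·Aᵀ = I, where V is the Brownian covariance (depth of the most
recent common ancestor per species pair); the test suite uses this GLS
whitening identity as the oracle, plus values frozen from an independent
reference implementation.

**Pagel's λ.** V(λ) multiplies the off-diagonal of V by λ. The root mean
and rate σ² are profiled analytically by GLS at each λ, leaving a 1-D
bounded likelihood maximised on [0, 1] (tolerance 1e-6); ties against the
bound values report the bound. At least 10 species are required; constant
traits are rejected (degenerate likelihood). On species-level *means* of
noisy data, λ̂ is attenuated below the generating value — the recovery
tests therefore use the pure phylogenetic signal (no environment, no
noise), which is the regime in which λ is identified.

## Trait tables

Observation-level rows: `obs_id`, `species`/`genus`/`family`, WGS84
`lat`/`lon`, trait columns (NaN = missing), covariate columns. Adult-tree
thresholds (height > 5 m, stem diameter > 10 cm, root depth > 25 cm, crown
height/width > 1 m) and plausibility bounds (stem diameter ≤ 15 m) **mask
the offending value rather than drop the row**, preserving the other
traits measured on the same record; filtering is idempotent and reported
per trait per rule. Standardisation is natural log then z-score with the
sample (n−1) standard deviation; zero or negative raw values are masked
and counted, never clamped. The transform is stored and exactly invertible
(round-trip to 1e−10). Rows without coordinates are eligible only for the
phylogeny-only model path.

## The synthetic world

The generator's defaults are the study conditions used by every recovery
test: 200 species, 18 traits in 8 correlation blocks (ρ_in = 0.7,
ρ_out = 0), 10 covariates, 2,000 observations, λ = 0.6 for every trait,
and a variance budget of sd 1.0 phylogeny, 0.7 environment, 0.5 residual
noise per standardized trait (≈ 57/28/14%). An observation decomposes as

    y[obs, t] = u[species(obs), t] + β_t · env(site) + ε

with u drawn matrix-normal — trait columns correlated by the block matrix,
species rows by V(λ_t) — so true trait correlations and true λ are
simultaneously well-defined, which is exactly what the clustering and λ
modules must recover. The β rows share the same block correlation, so the
*total* trait correlation (not just its phylogenetic part) follows the
declared structure. Environmental fields are low-rank Gaussian-kernel
random fields over the unit square (length scale 0.15), mapped onto a
10° × 10° geographic window so that haversine distances and the 250 km CV
buffer are meaningful; each species occupies a disc of radius 0.1
(~110 km), which spatially clusters species identity and is what makes the
buffer bite. Missingness is MCAR at a single rate or per-trait
("trait-skewed") to emulate real coverage imbalance. Everything derives
from one seed through `SeedSequence` spawns; regeneration is
bit-identical.

What the generator does **not** emulate: realistic biogeography or range
shapes, non-linear environmental responses (the hook exists; default
linear), measurement-protocol heterogeneity, and non-random missingness
mechanisms correlated with trait values. Passing recovery tests therefore
demonstrate correctness of the machinery under the declared model, not
performance guarantees on any particular real database.

## Imputation

Forests use the common regression defaults: 500 trees (tests and the
bundled analysis use 100 for desk-scale runtime; accuracy differences are
marginal), bootstrap with replacement, √p candidate variables per split,
minimum node size 5, variance split rule. Covariate selection takes the
first k eigenvectors (default 10) and one representative per
correlation-cluster of environmental variables (default 10): average
linkage on 1 − |ρ|, medoid = member with highest mean |ρ| to its own
cluster, ties by column order.

The two-step algorithm fits every trait (focal + ancillary) on the base
covariates, predicts all traits everywhere, then refits each focal trait
adding the other traits' first-round predictions as covariates. The
stage-2 covariates are the *predictions* even where observations exist
(a `stage2_use_observed` switch substitutes observed values; default off).
Ancillary traits participate only as covariates, never as outputs.
Observed cells always take precedence in the completed table, exactly;
per-cell provenance records observed / imputed-mean / imputed-q90.

Quantile (90th percentile) imputation for the five size traits uses a
quantile regression forest: the forest is grown as usual and each
prediction takes the weighted 0.90-quantile of the training responses
co-resident in the target's leaves (weight 1/leaf-size per tree). The
weighted quantile is the inverted-CDF convention, which makes
q-monotonicity exact.

Model-family selection (phylogeny-only vs combined) compares buffered-CV
VEcv computed on the *same* focal-species folds for both families — a
paired comparison; unpaired folds make the selection noisy. Ties go to the
combined model. Relative importance of environment vs phylogeny sums
nonnegative permutation importances (negative values floored at zero)
within each covariate group and normalises per trait; the overall split is
the unweighted mean across traits. It is computed on the stage-1 models,
whose covariates are exactly the phylogenetic + environmental sets.
A minimum of 30 observed values per trait is required to fit (prevents
degenerate forests).

## Validation

VEcv = 1 − Σ(ŷ−y)²/Σ(y−ȳ)² against the 1:1 line; it equals the classical
R² when predictions are an OLS fit on the same data, may be negative, and
is undefined for constant observations. The median relative absolute error
is reported in percent on the unlogged scale. Moran's I uses binary
great-circle distance-bin weights (haversine, radius 6,371 km); empty bins
are missing, not zero. Taxonomic autocorrelation replaces the spatial
weights with same-taxon adjacency per rank.

The buffered leave-one-species-out CV takes all of the focal species' rows
as the test set and removes from training every row of the same genus (or
family, for traits with deeper residual autocorrelation) within 250 km of
*any* test point; rows strictly beyond the radius are retained. Focal
species are sampled without replacement up to the iteration cap, and all
out-of-fit pairs are pooled into a single VEcv (matching the metric's
single-summation form); a per-fold average is recoverable from the stored
iterations. The random-split k-fold CV exists purely as the contrast that
demonstrates how much accuracy the buffer removes.

## Trait axes and attribution

Weighted PCA normalises weights to sum 1, centres by the weighted mean and
eigendecomposes the weighted covariance; no small-sample correction (traits
are already z-scored, so covariance- and correlation-PCA coincide up to
sampling noise). Axis signs follow the largest-|loading| convention. Axes
beyond the data rank are flagged rather than dropped. Scores are computed
for all observations, including imputation-supported ones.

Shapley values are interventional (marginal): coalition values average the
model over a background sample (≤ 256 rows drawn from the training split).
For p ≤ 5 the exact 2^p enumeration is used (efficiency holds to machine
precision; a never-used feature gets exactly zero). Otherwise a
permutation Monte-Carlo estimator samples feature orderings and averages
each marginal contribution over a small background batch (default 16) —
the batching cuts the estimator's variance several-fold at fixed ordering
count, and per-ordering totals telescope so efficiency holds up to the
Monte-Carlo error of the baseline, for which a per-observation standard
error is reported. Attribution is computed on the 15% held-out split only.

## Clustering

Trait distance is 1 − |ρ| by default: anti-correlated trait pairs (e.g.
specific leaf area vs leaf thickness on the leaf-economics axis) belong to
the same functional cluster, so the association must be sign-blind; a
signed 1 − ρ switch exists. Linkage is average ("high average intra-group
correlation" is precisely what average linkage optimises locally);
silhouette widths are computed on the same distance matrix used for
linkage, candidates k = 2…p−1, ties to the smaller k. PIC correlations go
through the origin (contrasts have zero expectation under Brownian
motion); a centred variant is available. Trait pairs sharing fewer than 4
species are reported missing. With two traits the silhouette is undefined
and the split is trivially k = 2.

## Orchestration and problem sizes

A single master seed is hashed with the stage name to give each stage an
independent, reproducible substream, so stages can be rerun in isolation.
Stage outputs are pure functions of (inputs, config, seed); manifests
record input hashes and seeds. All tabular outputs are delimited text;
dendrograms are Newick.

Test-suite and acceptance-script problem sizes are chosen desk-scale as
the package's own defaults: the full pipeline at 200 species / 2,000
observations; λ recovery at 200 tips × 100 replicates per bound; PIC
correlation recovery at 300 tips; CV conservativeness at 80 species × 20
seeds; cluster recovery at the default world × 20 seeds; forests at
40–100 trees. The paper-scale regime (tens of thousands of species,
sparse eigensolvers) is explicitly out of scope.

## Known limitations

- Imputation uncertainty is not quantified beyond the q90 path.
- The λ likelihood assumes a single trait optimum (no
  Ornstein-Uhlenbeck alternative).
- Buffering is taxonomic-rank based, not branch-length based.
- The environmental covariate table must be supplied (or simulated);
  raster compositing and taxonomy harmonisation against external
  databases are out of scope.
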