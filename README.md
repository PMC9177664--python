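# treetraits

Global syntheses of tree functional traits (wood density, specific leaf
area, maximum height, seed mass, ...) face a pervasive problem: trait
databases are extremely sparse and uneven, with some traits measured for a
majority of species and others for only a few percent. `treetraits`
implements a complete, tested pipeline for analysing such data by
gap-filling the trait matrix from two complementary sources of signal —
**phylogenetic history** and **local environment** — and then analysing the
completed matrix as a functional trait space.

The pipeline, end to end:

1. **Phylogenetic eigenvectors.** From a rooted, branch-lengthed phylogeny,
   the cophenetic distance matrix D is Gower-centred,
   G = −½ C (D∘D) C with C = I − 11ᵀ/n, and the leading eigenvectors of G
   become continuous covariates encoding relatedness.
2. **Random-forest imputation.** Each trait y is modelled as
   y = f(E₁…E_k, env₁…env_k) with a regression forest (500 trees, √p
   candidate splits, minimum node size 5). A two-step refit adds every
   *other* trait's first-round predictions as covariates, transferring
   information across traits' disjoint observation sets. Size traits are
   imputed as the conditional 90th percentile from a quantile regression
   forest, minimising ontogenetic variation. Per trait, a phylogeny-only
   model competes with the phylogeny+environment model and the one with the
   higher cross-validated accuracy wins.
3. **Buffered cross-validation.** Accuracy is scored by leave-one-species-out
   CV that also removes all congeners (or confamilials) within a 250 km
   haversine buffer of the test points, so spatial and phylogenetic
   autocorrelation cannot leak into the score. The metric is
   VEcv = 1 − SSE/TSS against the 1:1 line, which can be negative and is a
   conservative lower bound on accuracy.
4. **Species-weighted PCA.** Observations are weighted 1/n_obs(species) so
   every species contributes equally while intraspecific variation is
   retained; the weighted covariance eigendecomposition gives the dominant
   trait axes.
5. **Shapley attribution.** A forest models each PC axis from the
   environmental covariates; interventional Shapley values on a 15%
   held-out split partition each prediction among covariates (exact 2^p
   enumeration for p ≤ 5, a permutation Monte-Carlo estimator otherwise).
6. **Trait clustering.** Species-weighted Spearman correlations between
   traits are clustered (average linkage on 1 − |ρ|, silhouette-selected
   k), with phylogenetic-independent-contrast correlations as the
   ancestry-corrected cross-check and Pagel's λ quantifying per-trait
   phylogenetic signal.

Because real trait databases are access-restricted, the package ships a
first-class synthetic-data generator (`treetraits.synthetic`) producing a
Yule phylogeny, λ-Brownian traits with block covariance, spatially
autocorrelated environmental fields, intraspecific replicates and
missingness — with full ground truth, so every stage of the pipeline is
testable for *recovery*, not just for running.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic world (200 species, 18 traits in 8 correlation blocks, 10
covariates, 2000 observations, 30% missingness, master seed 1):

```sh
cd analysis
python 01_simulate.py   # writes results/tree.nwk, traits_observed.csv, ...
python 02_impute.py
python 03_validate.py
python 04_axes.py
python 05_attribute.py
python 06_cluster.py
```

which prints (abridged):

```
relative importance: environment 0.48 vs phylogeny 0.52
mean buffered VEcv across traits: 0.354
  bark_thickness         buffered +0.451  random-split +0.615
  conduit_diameter       buffered +0.669  random-split +0.756
  ...
variance explained per axis: 24.1%, 14.6%, 9.7%, 8.4%, 7.4%, 6.7%, 5.8%, 4.5% ...
7 axes reach 75% of trait variation
PC1: test R2 0.62; top covariates: env_07, env_02, env_08
silhouette-selected number of trait clusters: 9
  cluster 4: leaf_thickness, leaf_density
  cluster 7: leaf_area, specific_leaf_area, seed_dry_mass
  ...
```

Read: environment and phylogeny contribute almost equally to imputation
accuracy; the buffered VEcv sits well below the naive random-split score
(the leakage the buffer removes); seven weighted-PC axes are needed for 75%
of trait variation, i.e. the trait space is genuinely high-dimensional; and
the clustering recovers the generator's correlation blocks (nine found
versus eight generated, one block split).

The same stages are available as a CLI (`treetraits simulate|impute|
validate|axes|attribute|cluster|run-all|fixture`) and as library functions
(`treetraits.pipeline.run_stage` / `run_all`).

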