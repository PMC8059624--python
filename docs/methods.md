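# Methods

`funcvar` quantifies the reorganization of a species community through
the lens of its functional traits. It was designed around a concrete
ecological setting — boreal demersal fish expanding into an Arctic shelf
sea under ocean warming — but the statistics are generic: any station ×
species abundance table with station metadata (region, year, position)
plus a species × trait table can be analysed.

## Trait handling and species distances

Traits are mixed-type. Quantitative traits (body length, age at
maturity, …) are z-scored over the full species pool (population sd);
ordinal traits are rank-coded (average ranks on ties) and then treated
as quantitative. Categorical traits are fuzzy-coded: a species holds
graded memberships over the trait's categories, non-negative and
summing to one. Membership columns are *not* z-scored — they already
live on a common [0, 1] scale, and z-scoring them would inflate rare
categories. Standardization parameters are frozen from the full pool
and reused everywhere, so community-level statistics are comparable
across stations and years.

Pairwise species dissimilarity is the Gower distance,

d_ij = Σ_t w_t δ_t(i, j) / Σ_t w_t,

with δ_t = |x_i − x_j| / range_t for quantitative/ordinal traits and
δ_t = ½ Σ_c |m_ic − m_jc| (total-variation distance between membership
vectors) for fuzzy traits; all category columns of a fuzzy trait
jointly carry that trait's single weight. Missing values are handled
by pairwise deletion (the trait drops out of both sums for that pair);
a pair sharing no trait at all is an error. d is symmetric with values
in [0, 1].

The trait dendrogram is built by UPGMA (average linkage) on the Gower
matrix, the convention of the dendrogram-based functional-richness
literature. The linkage is implemented directly (O(n³), fine for pools
of tens of species) rather than via a library call so that ties break
deterministically — the pair of clusters whose smallest member indices
are lowest merges first — giving bit-reproducible trees; agreement with
`scipy`'s average linkage is verified in the test suite via cophenetic
distances. Merge heights are half the linkage distance, so leaf-to-leaf
path length equals the average-linkage distance and the tree is
ultrametric.

## Diversity indices

Per station, with p_i the relative abundances of the species present
(strict positivity is the presence criterion):

* **Species richness** S: count of present species.
* **Shannon entropy** H = −Σ p_i ln p_i (natural log; a `base` argument
  exposes base-2/10).
* **Evenness** J = H / (ln S + 1). This is the regularized variant with
  the +1 in the denominator, not classical Pielou H / ln S; it is
  implemented literally because it is the definition this pipeline is
  built around, and the +1 conveniently makes the single-species case
  0/1 = 0. Its upper bound at fixed S is ln S / (ln S + 1) < 1.
* **Functional richness** FRic: total branch length of the minimal
  subtree of the full-pool dendrogram spanning the present species.
  Abundance-free; monotone non-decreasing as species are added; 0 for a
  single species.
* **Functional dispersion**, Rao's quadratic entropy
  Q = Σ_i Σ_j p_i p_j d_ij — the full double sum over ordered pairs, the
  quadratic-entropy convention (no division by two).

## Community-weighted variance and functional variance PC1

For each expanded trait column t, the community-weighted mean and
variance at a station are

CWM_t = Σ_i p_i x_it,  CWV_t = Σ_i p_i (x_it − CWM_t)²,

a population-style weighted variance: relative abundances are weights,
not sample counts, so no Bessel-type correction applies. CWV is
non-negative, zero iff all present species share the column value, and
for a crisp (0/1) fuzzy category column reduces to the Bernoulli
variance q(1 − q) of the abundance-weighted category frequency.

The station × trait CWV matrix is decomposed by PCA (SVD of the
column-centered matrix; all stations of all regions jointly, so scores
share one axis). Columns are centered but by default not rescaled to
unit variance: species-level traits were standardized upstream, so CWV
columns are already commensurate, and rescaling would equalize traits
that genuinely differ in how much community-level variance they carry.
A `scale_columns` flag exposes the correlation-matrix alternative. PC
signs are arbitrary in principle; PC1 is oriented so that its
correlation with Rao's Q across the same stations is non-negative,
because the score is meant to be read as a magnitude of functional
variance (the orientation is recorded in the result). A station's PC1
score is its **functional variance PC1**; the PC1 loadings, ranked by
magnitude, characterize *which* traits drive the variance — the
information that scalar dispersion indices lack.

## Trend decomposition

Functional dispersion is regressed on the three classical indices,

Q ~ S + J + FRic, random intercept per survey year,

fitted by maximum likelihood (not REML, so fits with different fixed
effects are comparable). Reported r² is the squared Pearson correlation
between the fixed-effect fitted values and the observed response — the
share of variation attributable to the three predictors themselves, not
to the year effects. p-values are Wald z on the fixed effects.
Predictor collinearity (|r| ≈ 1) is an error naming the offending pair;
fewer than three year levels degrades the model to fixed-intercept OLS
with a warning (with one year this reproduces closed-form OLS exactly,
which the tests exploit as an oracle).

With the `spatial` flag, residuals within each year additionally carry
an exponential correlation exp(−d/ρ) on great-circle distance d between
stations, nested by region (zero correlation across regions). The
variance ratio of the year effect and the range ρ are estimated by
profiled maximum likelihood (Nelder–Mead over the two log-parameters;
β and the residual variance are profiled out per evaluation, with
per-year Cholesky factorizations). The flag is off by default: the
non-spatial fit is faster and deterministic across optimizer versions,
and the spatial structure matters for inference (standard errors) more
than for the point estimates, which the tests show agree closely when
no spatial correlation is present.

## The synthetic survey generator

The generator exists so that every pipeline stage can be validated
against a constructed truth. It emulates a two-region ecosystem survey:

* **Species pool** — 20 Arctic + 29 boreal species by default (a
  49-species demersal pool). Fifteen traits in five categories (habitat
  affinity, life history, body size, feeding ecology, food-web role):
  13 quantitative, drawn from pool-specific normals, and 2 fuzzy
  (habitat use, diet; 3 categories each) drawn from pool-specific
  Dirichlets. The boreal pool is larger-bodied, later-maturing, more
  piscivorous, warmer-affiliated and more trait-variable (sd 1.0 vs
  0.6 raw units); the Arctic pool is concentrated on benthivory. Pool
  mean gaps on contrasted traits are ~0.8–1.2 raw units (≥1 pooled sd
  for body size by construction).
* **Stations** — a jittered rectangular lat/lon grid, 20 stations per
  region-year by default over 2004–2017 (14 years); the Arctic
  rectangle (75.5–79.5° N) sits poleward of the boreal one (70–74° N).
  A per-(region, year) station-count override reproduces
  effort anomalies such as ice-limited years. Station density, not
  coastline realism, is the only geographic feature mimicked.
* **Occupancy and abundance** — presence is Bernoulli. Species in their
  home region have occupancy 0.5; strays in the foreign region 0.02.
  Borealization raises boreal occupancy at Arctic stations by β = 0.05
  per year (clamped to [0, 1]); an off-by-default local-extinction knob
  decays Arctic occupancy analogously. Abundances of present species
  are lognormal(0, 0.8) — the standard occupancy × lognormal
  species-abundance convention; units are arbitrary since only relative
  abundances enter the statistics. Each (region, year) cell has its own
  RNG substream, so the boreal region's draws are bit-identical across
  different β values, and a fixed seed makes the whole survey
  bit-reproducible.

These defaults produce the qualitative structure the package is built
to detect: Arctic functional variance PC1 and Rao's Q rise and converge
to boreal levels (the Arctic−boreal PC1 gap falls below a quarter of
its initial value within the 14 years), and the CWV-based gap halves
years before the CWM-based gap — trait *variance* reacts to incipient
mixing while the trait *mean* still reflects the resident community,
which is what makes functional variance an early-warning indicator.
With identical pools and β = 0 the pipeline shows no Arctic trend
(type-I control).

What the generator does **not** emulate: mechanistic population
dynamics, dispersal, temperature fields, sampling-gear selectivity,
zero-inflation beyond Bernoulli occupancy, or spatially autocorrelated
abundances (station draws are independent given the occupancy
probabilities). Passing tests therefore demonstrate that the statistics
recover a planted borealization signal of realistic size and shape, not
that they are robust to every failure mode of real survey data.

## Numerical choices and scales

* Fuzzy memberships must sum to 1 within 1e-6 (renormalized below that
  tolerance, rejected above).
* Zero-variance quantitative traits standardize to all-zero columns
  (sd treated as 1) with a warning rather than failing, keeping
  downstream shapes stable.
* Zero-abundance stations are dropped with a logged count; all-zero
  rows reaching the index functions are errors.
* The PCA keeps min(n_stations, n_columns) components; explained
  fractions sum to 1 by construction and the reconstruction
  (scores · loadingsᵀ + center) is exact to 1e-10.
* Analyses in the test suite and acceptance script run at 20 stations
  per region-year (560 stations per survey) and 20 replicate seeds —
  chosen as the package's own validation scale: small enough to iterate
  on, large enough that the planted trends dominate sampling noise.
* All output CSVs use `%.12g` floats; reruns with the same seed and
  config are byte-identical (the run manifest carries no timestamps).
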