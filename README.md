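# funcvar

Multi-trait **functional variance** analysis of community
reorganization, for community ecologists tracking how climate-driven
range shifts rewrite the trait composition of regional species
assemblages — the motivating case being boreal demersal fish expanding
into an Arctic shelf sea.

Scalar functional-diversity indices (functional richness, Rao's Q) tell
you *that* a community's trait diversity changed, not *which* traits
changed. `funcvar` implements the community-weighted variance (CWV)
approach: for every station with relative abundances p_i and
standardized, fuzzy-coded trait values x_it,

    CWM_t = Σ_i p_i x_it        (community-weighted mean)
    CWV_t = Σ_i p_i (x_it − CWM_t)²   (community-weighted variance)

and a PCA of the station × trait CWV matrix. A station's PC1 score —
its **functional variance PC1** — measures the magnitude of multi-trait
variance (it tracks Rao's Q closely), while the PC1 loadings identify
the traits responsible. Because trait *variance* reacts to incipient
mixing of resident and incoming species years before the trait *mean*
converges, rising functional variance is an early-warning indicator of
an ecological transition.

Alongside the CWV core the package provides:

* mixed-type **Gower distances** (quantitative, ordinal, fuzzy-coded
  traits, per-trait weights, pairwise deletion of missing values) and a
  deterministic **UPGMA** trait dendrogram;
* per-station **diversity indices**: species richness S, Shannon H,
  evenness J = H/(ln S + 1), dendrogram functional richness FRic
  (spanning-subtree branch length), Rao's quadratic entropy Q;
* **trend models**: Q ~ S + J + FRic with a random year intercept (ML,
  via statsmodels), optional exponential spatial residual correlation
  nested by region, globally and per region;
* a **synthetic two-region borealization survey generator** with known
  ground truth (contrasted Arctic/boreal species pools, linearly rising
  boreal occupancy in the Arctic), used throughout the tests;
* a CLI (`funcvar simulate | indices | cwv | pca | trends | all`)
  writing plain-CSV outputs plus a JSON run manifest; reruns on a fixed
  seed are byte-identical.

## Worked example

Simulate a 14-year, two-region survey (49 species, 15 traits, 20
stations per region-year) and run the functional-variance PCA and the
trend decomposition:

```sh
funcvar simulate --seed 7 --out-dir demo
funcvar pca    --abundance demo/abundance.csv --traits demo/traits.csv \
               --traits-meta demo/traits.yml --out-dir demo/out
funcvar trends --abundance demo/abundance.csv --traits demo/traits.csv \
               --traits-meta demo/traits.yml --out-dir demo/out
```

prints

```
PC1 explains 26.7% of CWV variation; r2 with Rao's Q = 0.517
[all] r2 = 0.694 (n = 560)
[arctic] r2 = 0.755 (n = 280)
[boreal] r2 = 0.645 (n = 280)
```

i.e. the first principal component carries about a quarter of all
community-weighted trait variance and is a good indicator of functional
dispersion (r² ≈ 0.52 with Rao's Q), and the three classical indices
explain ~69% of the spatio-temporal variation in dispersion. In
`demo/out/pc1_regional.csv` the Arctic regional mean of functional
variance PC1 rises from −1.62 (2004) to 0.20 (2017) while the boreal
region stays near 0.25–0.31: the Arctic−boreal gap shrinks to ~6% of
its initial value as boreal species colonize the Arctic stations —
exactly the planted borealization signal. `demo/out/pca_loadings.csv`
ranks the traits driving the variance for this realization.

The same pipeline runs on real data: provide `abundance.csv` (stations
× species with `region`, `year`, `lat`, `lon` columns), `traits.csv`
(species × traits, fuzzy categories as `trait.category` columns) and a
`traits.yml` metadata sidecar declaring each trait's type, categories
and weight.

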