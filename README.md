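# barrier-slr

Probabilistic modeling of how barrier-island vegetation communities respond
to sea-level rise (SLR), for coastal ecologists and land managers who need a
first approximation of community change from just two rasters: a digital
terrain model and a land-cover map.

## The model

Low-relief barrier islands sort their vegetation along the elevation
gradient, a proxy for depth to water table and salinity.  The package
treats community type as the class variable of a naïve Bayes classifier
whose single measure is elevation above mean lagoon high water (MLHW):

1. **Stratified GLS.**  The community–elevation relationship is quantified
   by maximum likelihood for
   `z_i = μ_c(i) + ε_i`, with `Cov(ε_i, ε_j) = σ_c(i) σ_c(j) exp(−d_ij / r)`
   — a per-community mean, per-community residual SD (the *stratum SD*),
   and exponentially decaying spatial residual correlation with range `r`.
   Fit quality is summarized by Nagelkerke's pseudo-R².
2. **Community-elevation proportion matrix.**  Each community's elevation
   distribution is smoothed with a Gaussian KDE `f_c`; at each 0.001 m
   elevation step the probability of community `c` is the abundance-weighted
   posterior `p(c|e) = n_c f_c(e) / Σ_j n_j f_j(e)`.
3. **Monte-Carlo transition simulation.**  An SLR scenario lowers every
   pixel's relative elevation by the rise.  Pixels that fall below mean
   lagoon water (MLW, 0.2 m below MLHW) enter the absorbing open-water
   state; every other pixel is independently redrawn from the multinomial
   `p(·|e_new)`.  Replicates (default 1000) give the median and central-95%
   interval of each community's final proportion, on a *total-area* basis
   (absorbed pixels kept in the denominator) and a *remaining-land* basis.
4. **Subsample sensitivity.**  The replicates are repeated on random pixel
   subsamples of decreasing size to show how interval widths grow roughly
   as `1/√N`.

A seeded synthetic-landscape generator (spatially autocorrelated elevation
surface rank-mapped onto a community-weighted normal mixture, labels drawn
from the exact elevation posterior) stands in for survey rasters, so every
stage is testable end to end.

## Worked example

```sh
python analysis/01_generate_landscape.py   # 380x380 cells, seed 2026
python analysis/04_slr_scenarios.py        # 200 replicates per scenario
```

prints, among other things:

```
rise_0.2: absorbed 8290 pixels (7.8% of land)
rise_0.4: absorbed 17892 pixels (16.9% of land)
rise_1.2: absorbed 52903 pixels (50.0% of land)

percent change in community area vs current conditions (medians over 200 replicates):
          SMAR  WETS  MANG  PALM  FWET  HAMM  PINE  FRST  SCRB
rise_0     2.2  -0.4  -0.6  -1.1   0.8  -0.8  -0.1  -1.4  -0.8
rise_0.2   1.8  -5.6  -6.5  -9.8  -5.8  -9.7  -9.2 -13.7 -13.4
rise_1.2 -34.0 -44.6 -46.0 -52.1 -46.5 -52.9 -52.4 -60.3 -60.3

baseline validation: max |median - observed| proportion = 0.0034
```

Reading: under no rise the simulation reproduces the current landscape
almost exactly (the model's self-consistency check); with rising sea level
half the land is inundated at 1.2 m, losses steepen up the gradient (the
xeric oak scrub SCRB and upland forest FRST lose the most), and the hydric
salt marsh SMAR gains area under small rises as mesic communities convert.
`02_elevation_gls.py`, `03_density_and_matrix.py` and
`05_subsample_sensitivity.py` produce the regression table, the density
profiles/proportion matrix, and the interval-vs-sample-size table; all CSVs
land in `results/analysis/`.

The same stages are available as a CLI (`barrier-slr generate | fit-gls |
build-matrix | simulate | run-all`) and as library functions
(`barrier_slr.run_pipeline` with a YAML config).

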