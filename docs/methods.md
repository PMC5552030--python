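# Methods

## Model

The landscape is a set of pixels, each with a ground elevation relative to
mean lagoon high water (MLHW; conversion from the raster's vertical datum
happens once at ingestion) and one of nine vegetation communities ordered
hydric → xeric: SMAR, WETS, MANG, PALM, FWET, HAMM, PINE, FRST, SCRB.  Open
water and nodata cells are excluded from all modeling.  Mean lagoon water
(MLW) sits 0.2 m below MLHW and is the open-water boundary: a pixel below
MLW carries no emergent vegetation.

**Classifier.**  Community type is treated as the class variable of a naïve
Bayes classifier with elevation as its only measure.  The class-conditional
densities are Gaussian KDEs `f_c` of the observed within-community
elevations (Silverman's rule per community, overridable); the prior is the
community's pixel count `n_c`.  Discretizing the posterior
`p(c|e) = n_c f_c(e) / Σ_j n_j f_j(e)` on a regular elevation lattice gives
the *community-elevation proportion matrix*.

**Simulation.**  A scenario with rise `Δh` maps every pixel's elevation
`e → e − Δh`.  Pixels ending below −0.2 m MLHW are absorbed (deterministic,
hence identical across replicates and non-decreasing in the rise); every
other pixel is independently redrawn from the multinomial at its new
elevation.  The matrix is always built from the *current* landscape and
reused across scenarios.  There is no spatial interaction: the model
describes collective proportions, not the fate of particular locations, so
even the no-change scenario shuffles labels among pixels of similar
elevation while preserving community totals — that fixed-point behavior is
the model's internal validation.

**Stratified GLS.**  The community–elevation relationship is estimated on a
pixel subsample (default n = 2,000; supported to 10,000, a heavy
dense-covariance run) by maximum likelihood for a per-community mean,
per-community residual SD, and exponential spatial residual correlation
`exp(−d/r)` in the inter-pixel distance (Euclidean meters between cell
centers).  ML rather than REML is used so nested models are comparable by
likelihood.  Implementation: the correlation Cholesky depends only on `r`,
so the optimizer is a bounded scalar search over `log r` whose inner step
optimizes the log SD ratios with the factorization fixed; stratum means and
the overall variance scale are profiled in closed form.  Wald 95% CIs come
from the profiled information.  `correlation="none"` gives the nested
heteroscedastic model in closed form.  No nugget by default (an option adds
one); strata with fewer than two pixels are flagged unidentifiable.
Nagelkerke's pseudo-R² is computed against the intercept-only iid null —
the simplest defensible null, since the index's construction for GLS models
is convention-dependent; with continuous densities the index can touch 1
only if the fitted likelihood reaches 1, so it stays in [0, 1) in practice.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, not
any particular island's hypsometry:

* **Elevation surface** — white noise smoothed by a moving-average kernel
  (default 5 cells) and rank-mapped onto the target marginal distribution:
  a community-weighted mixture of per-community normals plus a uniform
  sub-MLW "sea floor" tail (default 15% of cells on (−1.5, −0.2) m).  Rank
  mapping preserves the smoothed field's spatial ordering, giving plausible
  ridge/swale clumping without a geostatistical simulator — sufficient
  because the transition model itself is aspatial.
* **Labels** — cells at or above −0.2 m are assigned by the *exact* normal
  posterior `p(c|e) ∝ w_c φ_c(e)`; lower cells become open water.
* **Defaults** — per-community means/SDs are the published stratum
  estimates (SMAR 0.14/0.55 … SCRB 1.96/1.65 m) and the weights are the
  observed landscape shares normalized to 1.  Salt marsh and freshwater
  wetland are optionally (and by default) bimodal; the second-mode
  locations/weights are arbitrary plausible values chosen only to produce
  two well-separated peaks, since no published parameters exist.

Two consequences of the open-water truncation are intentional: land-cell
community frequencies equal the configured weights *rescaled by each
community's probability mass above −0.2 m*, and the elevations of cells
labeled `c` follow `φ_c` truncated at −0.2 m, so low-lying communities'
sample means sit above their generating means by the closed-form truncation
shift.  Tests compare against these exact truncated quantities.

What the generator does **not** emulate: real class-label patchiness beyond
what elevation induces, elevation measurement error (LiDAR vertical error
is not propagated), accretion or erosion, salinity and fire/freeze drivers,
and any particular observed hypsometric peak.  Passing tests therefore
demonstrate that the estimators and the simulation machinery are correct
and self-consistent under the assumed structure — not that the assumed
structure captures any specific real landscape.

## Parameters that matter

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| rise scenarios | 0, 0.2, 0.4, 1.2 | m | projected low/middle/high SLR by late century |
| MLW offset | 0.2 | m below MLHW | open-water boundary of the micro-tidal lagoon |
| matrix step | 0.001 | m | small enough that discretization artifacts vanish (lookup changes < 10⁻³ under 10× refinement) |
| KDE bandwidth | Silverman per community | m | standard default; logged in outputs |
| replicates | 1000 (500 for subsample runs) | — | stabilizes medians and central-95% endpoints |
| GLS subsample | 2000 | pixels | dense-covariance ML in seconds-to-minutes on one core |
| subsample sizes | 10⁶, 10⁵, 10⁴, 500, 250 | pixels | spans detectable-signal to noise-dominated regimes |

## Numerical choices

* Matrix rows are exact sums over kernels (chunked, no binned/FFT
  approximation), so they agree with a naive evaluation to ~1e-9 relative.
  Rows whose densities all underflow (possible only in the padded tails)
  are copied from the nearest supported step.
* Elevation lookup snaps to the nearest step with ties toward +∞ and clamps
  beyond the lattice ends.
* Multinomial draws consume one uniform per non-absorbed pixel in table
  order; the selected class is the first whose cumulative proportion
  exceeds the variate (the last cumulative value is pinned to 1).  Replicate
  `r` of a batch seeds a fresh generator with `base_seed + r`.
* The correlation Cholesky retries with diagonal jitter (1e-10 … 1e-6)
  before failing; the search range for `r` is bounded by the observed
  distance spectrum.
* Central-95% endpoints are the 2.5th/97.5th linear-interpolation
  percentiles across replicates (the natural reading of "end-points of the
  central 95%").
* Percent-change entries are `100 (median final − initial)/initial` counts;
  a zero initial count yields an explicit NaN.

## Analysis problem sizes

The shipped drivers and tests run at desk scale by choice: a 380×380
landscape (≈1.06×10⁵ land pixels), 100–200 replicates per scenario, GLS at
n = 2,000 and subsample sensitivity at 50 replicates over sizes
250–10⁴.  All sizes are flags; the full-scale settings (10⁶-pixel
subsamples, 1000 replicates, GLS at n = 10⁴) are supported but take
correspondingly longer.

## Known limitations

* The model is aspatial and memoryless: it predicts proportions, not maps,
  and cannot represent inertia, dispersal limits or neighborhood effects.
* No geomorphic feedbacks (accretion, erosion, saltwater intrusion), so
  marsh persistence under moderate rise is likely underestimated.
* The GLS Nagelkerke R² depends on the chosen null and on landscape
  composition; values are comparable within, not across, datasets.
* KDE smoothing leaks small probability across community boundaries, which
  is visible as the (sub-0.005) bias of the no-change fixed point.
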