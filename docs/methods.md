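# Methods

`viperpcm` implements a phylogenetic comparative workflow for testing
whether dorsal pigmentation in Eurasian vipers tracks the climate of
lineages' geographic ranges — the macroevolutionary version of the thermal
melanism hypothesis (darker ectotherms are favoured where heating
opportunities are scarce). This note records the models, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical conventions.

## Traits

Two specimen-level traits quantify dorsal pigmentation:

* **DM** — the number of dorsal marks (angles of the zigzag pattern along
  the right side of the body, excluding head and tail); a non-negative
  integer.
* **WPI** — the weighted pigmentation index,

  ```
  WPI = (1 · RECT_DES + 0.5 · RECT_HALF) / (10 · N_sample)
  ```

  the pigmented fraction of a standardized sampling rectangle 10 scales
  long and `N_sample` scale rows wide, with fully pigmented scales counting
  1 and half-pigmented scales 0.5. WPI lies in [0, 1] by construction and
  is stored at full precision; rounding (3 decimals) happens only when a
  report table is written.

Lineage-level values are the arithmetic means over the ten largest
zigzag-patterned specimens of the lineage (all of them when fewer than ten
exist). Specimens without a zigzag pattern (melanistic, striped, uniform)
are removed first; unknown pattern labels are rejected at parse time.
"Largest" is an opaque ordering key on the recorded body size — the package
does not care whether it is snout–vent or total length — and ties are broken
by specimen id so the selection is platform- and order-independent.
Specimens without a lineage assignment are placed by overlapping their
collection coordinates with the range masks; a point inside two ranges is
an error (reported, never silently resolved), a point inside none is left
unassigned with a warning.

## Trees and evolutionary units

Chronograms are rooted trees with edge lengths in My and contemporaneous
tips; ultrametricity is enforced within a relative tolerance of 1e-6 of the
root depth (trees beyond tolerance are rejected for covariance construction
unless explicitly extended tip-wise).

Evolutionary units are delimited by slicing the chronogram at a fixed age
(default 2.5 My) before present: every edge spanning the slice defines one
unit containing the tips below it, so recently diverged tips merge into one
unit. A node sitting exactly at the cut age keeps its clade together
(closed slice on the rootward side) — a deterministic boundary rule. The
tree is then pruned to one representative tip per unit (lexicographically
smallest label unless a map is supplied; whole units can be dropped, e.g.
for missing phenotypes). Pruning preserves every retained node's depth
exactly, so the pruned tree is ultrametric at the original root depth; the
tests assert that restricted MRCA depths are unchanged. This differs from
re-estimating a new phylogeny for the delimited units: the package supports
only the pruning route, which keeps the delimitation and the working tree
consistent by construction.

The Brownian covariance `C` has `C[i, j]` equal to the root-to-MRCA path
length of tips i and j and tip depths on the diagonal; it is symmetric and
positive semi-definite for every ultrametric tree (property-tested over
simulated trees up to 64 tips).

## Range descriptors

Ranges are sets of 10-arcmin grid cells (WGS84). From monthly rasters of
mean/max/min temperature, precipitation, solar radiation and water vapour
pressure plus a static elevation layer, 21 descriptors are computed per
lineage:

* temperature and vapour pressure: the spatial range mean per month, then
  mean/max/min across the 12 monthly means (`TAVGavg/max/min`,
  `TMAXmax/min`, `TMINmax/min`, `VPRavg/max/min`);
* precipitation and solar radiation: cell-wise annual sums, then spatial
  mean/max/min over the range (`SRADavg/max/min`, `PRECmax/min`);
* elevation: spatial mean/max/min (`ELEVavg/max/min`);
* latitude: mean/max/min of the cell-centre latitudes (`LATavg/max/min`).

Before any climatic or topographic summary the 5% lower and upper sample
quantiles are trimmed, except for ranges smaller than 20 cells. Quantiles
use the linear-interpolation convention and trimming drops values strictly
outside `[Q(0.05), Q(0.95)]`; since no quantile type or inclusivity is
canonical, both are explicit parameters. Trimming is applied per
distribution — per monthly layer for the monthly families, per annual
raster for the summed families, per elevation layer — and never to
latitude, which defines the range rather than sampling an environment.
Missing cells are excluded before trimming; a usable mask needs at least
one non-missing cell per required layer.

Rasters are read and written in a self-describing plain-grid CSV dialect
(header line with shape, origin and cell size); masks as two-column CSVs of
row-major cell indices, or rasterized from polygons by the cell-centre rule.

## Statistics

All comparative statistics condition on the Brownian covariance `C` of the
working tree, and all inference is by permutation with the observed
statistic included in the reference set, so p-values are valid and bounded
below by `1/(n_perm + 1)`. One master seed drives counter-keyed substreams
(one per tree, one per analysis), so multi-tree runs are order-independent
and reproducible.

**Phylogenetic signal (Blomberg's K).** With the GLS root estimate
`â = (1'C⁻¹1)⁻¹ 1'C⁻¹x`,

```
MSE0 = (x-â1)'(x-â1)/(n-1),   MSE = (x-â1)'C⁻¹(x-â1)/(n-1)
K    = (MSE0/MSE) / [ (tr C − n/(1'C⁻¹1)) / (n−1) ]
```

K equals 1 exactly on star phylogenies and in expectation under Brownian
motion; K < 1 means less resemblance among relatives than Brownian motion
predicts. The implementation is cross-checked against an independent R
implementation to 1e-8 in the tests. Significance: K is recomputed under
random tip permutations of the trait and the upper tail is counted — the
simplest faithful test statistic; the permutation machinery is vectorized
so 999 permutations cost one matrix solve.

**PGLS with RRPP.** The regression (WPI on DM, and each trait on each
descriptor) premultiplies the intercept-augmented design and response by
the symmetric inverse square root of `C` (eigendecomposition, eigenvalues
clipped at a relative 1e-10 floor) and runs OLS in that whitened space;
R² and F are computed there against the GLS-mean reduced model. The
symmetric root is used rather than a Cholesky factor because its residuals
are closer to exchangeable, which is the assumption residual randomization
rests on. RRPP permutes the reduced-model residuals, adds them back to the
reduced fitted values, refits the full model per permutation (vectorized as
projections), and reports `p = (1 + #{F* ≥ F}) / (n_perm + 1)` plus the
effect size `Z = (ln F − mean ln F*) / sd(ln F*)` on the log scale, the
convention of the residual-randomization framework. With `C = I` this
reduces exactly to OLS (asserted to 1e-10) and the permutation p agrees
with the parametric F-test within 0.02. Pairwise trait-descriptor models
are flagged at raw p < 0.05 by default, matching how such coefficient
panels are usually reported; a Holm step-down correction is available
behind a flag.

**Two-block PLS.** The first singular pair of the cross-covariance
`X'Y/(n−1)` between centered blocks gives one loading vector per block;
`r` is the absolute Pearson correlation of the paired scores and its
p-value comes from permuting rows of the right block. The phylogenetic
variant GLS-centers each column and premultiplies both blocks by the
symmetric inverse square root of `C` before the same machinery, permuting
the transformed rows; which rows a phylogenetic permutation test should
shuffle is not uniquely defined in the literature, and the transformed-row
choice is the one coherent with RRPP's exchangeability argument. On an
equal-depth star phylogeny the two variants coincide to 1e-10. Sign
convention: only the joint flip of both singular vectors preserves the
factorization, so the left (trait) block's largest-magnitude loading is
made positive and the environment loadings carry the direction of the
association. Blocks are standardized (column z-scores) before PLS in the
pipeline, since the descriptors mix units spanning three orders of
magnitude.

**Multi-tree uncertainty.** Every tree-dependent statistic is recomputed
over a posterior sample of chronograms (default 1000, sampled without
replacement when a larger pool is supplied); tables report the mean, a
dispersion column (SD across trees by default, switchable to SD/√n — the
two readings of "± SE" over tree collections), and the count of iterations
with p < 0.05. Single-tree failures are warned about and excluded rather
than fatal, and the long-format per-tree archive is persisted so the counts
are auditable and the summary tables can be re-rendered without
recomputation.

## Synthetic data

The generator produces every input class with known ground truth: Yule
chronograms (crown-conditioned pure birth, rescaled to an exact crown age),
Brownian traits with a tip-variance-preserving signal dial (off-diagonal
rescaling; 1 = Brownian, 0 = no signal), environment blocks with a planted
first-singular-pair correlation, specimen-level scale counts, and monthly
rasters with latitudinal gradients, seasonal cycles and sinusoidal
elevation. Defaults are the study's conditions: 39 lineages, 26 My crown
age, cut at 2.5 My, 1638 specimens (42 per lineage) with a 106/1638
non-zigzag fraction, sampling-rectangle widths of 12–21 rows, 21
descriptors, 1000 posterior trees.

Scale counts are drawn per rectangle from a three-outcome distribution
(full, half, background) with probabilities `(wpi − h/2, h, 1 − wpi − h/2)`
for half-scale fraction `h` (default 0.2), so the expected specimen WPI
equals the lineage mean; infeasible `(wpi, h)` pairs are a parameter error.
DM is a rounded Gaussian around the lineage mean (SD 2 marks), body sizes
lognormal, and a quarter of specimens have their lineage id blanked so the
coordinate-assignment path is exercised. The pseudo-posterior jitters node
ages lognormally (SD 0.08 on the log scale) on the fixed topology — a
synthetic stand-in for a Bayesian divergence-time posterior, deliberately
without topological uncertainty.

**The showcase contrast.** The real study's two traits behave oppositely:
the pigmentation fraction associates with environment *beyond* phylogeny,
while the mark count's environmental association dissolves once shared
ancestry is conditioned away. The second pattern requires the trait and the
environment to be dependent *only through the tree*. A linear coupling of
raw values cannot produce it — GLS whitening is a linear map, so any such
dependence survives phylogenetic correction. The showcase therefore builds
a deep biogeographic radiation: a standardized axis of Brownian increments
accumulated on edges older than 24 My is shared (fraction 0.7 of variance)
between the DM analogue and the axis that places range latitudes, while all
evolution after 24 My is independent. Range latitudes are assigned by rank
along the gradient, which bounds the environmental side and keeps the
handful of deep whitened contrasts from dominating the phylogenetic test.
Clades end up in different latitude bands, descriptors inherit the band
structure from the rasters, and the naive association between DM and
climate is strong while the phylogenetically-informed one is null — the
classic signature of phylogenetic-plus-spatial autocorrelation. A side
effect of concentrating variance deep is that the showcase DM's K sits
above 1 (more structure than homogeneous Brownian motion), unlike a pure
Brownian trait; the calibration checks use pure Brownian traits, where mean
K ≈ 1.

The WPI analogue is planted on phylogenetic residuals: the realized
`LATavg` descriptor is whitened, standardized, and mixed (correlation 0.7,
exact by orthogonalization) with whitened low-signal Brownian noise; the
mixture is de-whitened and squashed into a feasible WPI range (0.5 ± 0.12
SD). Planting in the whitened space puts the association exactly where
phylogenetic PLS looks for it while remaining visible to the naive
analysis. Environment blocks built directly by `simulate_env_block` use a
sparse cold-climate loading pattern (positive latitude, negative minimum
solar radiation and minimum elevation — largest entry positive so the sign
convention leaves it unflipped) plus low-rank nuisance variation (four
shared factors per block), mimicking the strong collinearity of real
climate descriptors.

What the generator does **not** emulate: coastlines and irregular range
shapes (masks are rectangles in disjoint longitude bands), spatial
autocorrelation beyond smooth gradients plus iid cell noise, topological
posterior uncertainty, sex/ontogeny structure in specimens, and any direct
elevation–latitude dependence (elevation varies independently, so
elevation descriptors couple to traits only weakly). Passing tests
therefore certify the statistical machinery and the pipeline contracts on
data with these simplifications; they say nothing about empirical estimates
from real viper data, which would require the museum specimen measurements
and the dated phylogeny, neither of which is publicly deposited.

## Problem sizes and runtime choices

The test suite and the acceptance script run at the following sizes, chosen
to keep full runs in the minutes range on one CPU while leaving Monte-Carlo
error well inside the asserted bands: 500 replicates for the Brownian K
calibration; 1000 null simulations with 499 permutations for each type-I
check; 200 replicates (499 permutations) for planted-association recovery;
50 end-to-end showcase replicates; 100 posterior trees and 499 permutations
in the scripted showcase run (the pipeline default remains 1000/999).

## Numerical conventions and degenerate inputs

* Permutation p-values always include the observed statistic (`+1`
  convention); minimum attainable p is `1/(n_perm + 1)`; fewer than 99
  permutations triggers a resolution warning.
* `C^{-1/2}` by eigendecomposition with eigenvalues clipped at a relative
  1e-10 floor; matrices with materially negative eigenvalues are rejected.
* Exact-fit regressions report `F = inf` and the minimum p.
* Constant traits are an error for K (the statistic is undefined); constant
  block columns in PLS warn but proceed.
* Body-size ties, unit naming, representative choice and mask enumeration
  are all deterministic, so identical configurations yield byte-identical
  reports (asserted in the tests).

## Known limitations

* Brownian motion is the only correlation structure (no
  Ornstein–Uhlenbeck or Pagel-lambda optimization in PGLS), matching the
  analysis this package reproduces.
* The phylogenetic-PLS permutation scheme (transformed rows of the right
  block) is one defensible reading among several; it is isolated in one
  method and easy to swap.
* The dispersion reported "± SE" across trees is the SD of per-tree
  statistics by default; the alternative SD/√n reading is a flag away.
* GeoTIFF rasters are not read; the plain-grid CSV dialect covers the
  fixture and pipeline needs.
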