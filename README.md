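# viperpcm

Phylogenetic comparative analysis of dorsal pigmentation and range climate
in Eurasian vipers (Viperinae).

Eurasian vipers carry a dark zigzag dorsal pattern whose pigmented extent
varies across ~39 lineages spanning Mediterranean to boreal climates. The
*thermal melanism hypothesis* predicts darker phenotypes where heating
opportunity is scarce. `viperpcm` implements the full comparative workflow
for testing this at the macroevolutionary scale:

1. **Traits** — specimen scale counts become two lineage-level traits: the
   dorsal mark count **DM** and the weighted pigmentation index
   **WPI = (RECT_DES + 0.5·RECT_HALF)/(10·N_sample) ∈ [0, 1]**, averaged
   over the ten largest zigzag-patterned specimens per lineage.
2. **Trees** — dated chronograms are sliced at 2.5 My to delimit
   evolutionary units, pruned to unit representatives (depths preserved
   exactly), and converted to Brownian covariance matrices
   `C[i,j] = depth of MRCA(i,j)`.
3. **Range descriptors** — 21 ecogeographic variables per lineage
   (latitude, elevation, monthly temperature/vapour-pressure summaries,
   annual precipitation/solar-radiation totals) from 10-arcmin raster
   stacks, with 5%/95% quantile trimming inside each range.
4. **Statistics** — Blomberg's K with a tip-permutation test
   (`K = (MSE0/MSE)/E_BM[MSE0/MSE]`, K = 1 under Brownian motion), PGLS
   (`y = Xβ + ε`, `ε ~ N(0, σ²C)`) with residual-randomization (RRPP)
   inference, and two-block PLS (SVD of the cross-covariance `X'Y/(n−1)`)
   in phylogenetically naive and informed variants — every tree-dependent
   statistic repeated over a posterior sample of chronograms and reported
   as mean ± dispersion with the count of significant iterations.
5. **Synthetic data** — a first-class generator for every input (Yule
   trees, Brownian traits with tunable signal, planted trait–environment
   associations, specimen scale-count sampling, gradient rasters), so the
   whole pipeline runs with no downloads and known ground truth.

The statistical core is exposed as sklearn-style estimators
(`PhylogeneticSignal`, `PGLS`, `TwoBlockPLS`: `fit`, fitted `*_`
attributes, `get_params`) with thin functional wrappers
(`blomberg_k`, `phylosig_test`, `pgls_fit`, `rrpp_significance`,
`two_block_pls`, `phylo_pls`, `multi_tree_run`).

## Worked example

Generate the default synthetic study (39 lineages, 26 My crown age, 1638
specimens, monthly rasters) and run the complete analysis over 100
posterior trees:

```bash
viperpcm simulate --out demo/data --seed 0
viperpcm analyze --data demo/data --out demo/run \
    --n-trees 100 --n-perm 499 --seed 0
```

or equivalently from Python:

```python
from viperpcm.pipeline import RunConfig, run_full_analysis
from viperpcm.synth import SyntheticScenario

config = RunConfig(scenario=SyntheticScenario(seed=0, n_posterior_trees=100),
                   out_dir="demo/run", n_posterior_trees=100, n_perm=499, seed=0)
bundle = run_full_analysis(config)
```

The run directory contains five report artifacts (plus config, log and the
per-tree archive). With seed 0 the phylogenetic-signal table
(`signal_table.csv`) reads:

```
trait  K_mean  K_disp  p_mean  p_disp  n_significant  n_trees
  WPI   0.752   0.043   0.003   0.001            100      100
   DM   2.296   0.099   0.002   0.000            100      100
```

Both traits carry significant phylogenetic signal in all 100 tree
iterations; the mark count is far more conserved (its variance sits deep in
the tree), the pigmentation index much less so. The PLS table
(`pls_loadings.csv`, r and p rows) shows the study's key contrast:

```
          naive_wpi  phylo_wpi  naive_dm  phylo_dm
r             0.858      0.745     0.614     0.158
p             0.002      0.002     0.004     0.762
```

WPI associates with the range descriptors both ignoring and conditioning on
phylogeny — an environment effect beyond shared ancestry — while DM's naive
association (r = 0.61, p = 0.004) collapses once phylogeny is taken into
account (r = 0.16, p = 0.76): its climate link is an artifact of related
lineages occupying neighbouring latitudes. The pairwise PGLS table flags,
for WPI, positive latitude/precipitation coefficients and negative solar
radiation coefficients in 100/100 tree iterations — pigmentation increases
towards colder, dimmer ranges, exactly the thermal-melanism signature the
loadings table localizes on latitude and minimum solar radiation.

## Layout

```
src/viperpcm/
  traits.py     specimen records -> lineage trait means
  treeops.py    chronogram IO, time-slicing, pruning, Brownian covariance
  rangeenv.py   rasters, masks, quantile trimming, 21 descriptors
  pcm.py        K / PGLS-RRPP / two-block PLS, multi-tree summaries
  synth.py      scenario-driven generators with ground truth
  pipeline.py   end-to-end orchestration and report tables
  cli.py        viperpcm simulate | traits | ranges | analyze | report
docs/methods.md   models, conventions, generator design, limitations
```
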