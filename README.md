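# commphylo

Community phylogenetics of environmental filtering: does phylogenetic niche
conservatism of cold tolerance structure tree communities along a temperature
gradient?

`commphylo` is a toolkit for the analysis design in which a continental plot
network (a forest inventory), a dated species phylogeny, species traits, and
climate rasters are combined to ask four linked questions:

1. Do communities in colder places consist of species from *younger* families?
   The plot statistic is the **mean family age (MFA)**: each species inherits
   the crown age of its family and the plot value is the unweighted mean over
   the species present.
2. Is community mean **realized cold tolerance** — the coldest
   minimum-temperature-of-the-coldest-month value inside each species' range —
   the trait most strongly associated with MFA?
3. Is site minimum temperature the environmental variable that best accounts
   for MFA, compared with local covariates?
4. Has cold tolerance evolved under a **niche conservatism** constraint, i.e.
   does an Ornstein–Uhlenbeck (OU) model fit better than Brownian motion (BM)
   or white noise (WN)?

## What is implemented

* **phylo** — Newick I/O (via dendropy), BLADJ-style even-interpolation age
  calibration against node-age constraints, patristic-distance and shared-path
  (Brownian covariance) matrices, taxon pruning.
* **trait_models** — ML fits of WN / BM / OU by phylogenetic GLS. With the
  mean (optimum) and rate profiled out in closed form, OU needs one bounded
  1-D search over log α. Model comparison via likelihood-ratio tests
  (χ², optional boundary mixture) and Akaike weights `exp(-0.5 ΔAIC)`.
* **psr** — phylogenetic eigenvector (PVR) decomposition, **PSR curves**
  (sequential R² against cumulative eigenvalue fraction; linear along the 45°
  diagonal under BM, below it under OU), the signed **PSR area**, and
  Blomberg's *K*.
* **discrete_null** — Brownian-simulation nulls for discrete traits: simulate
  BM on the tree, discretize preserving the observed category frequencies
  exactly, recompute PSR area or 2LR(OU–BM) per simulation, and report
  add-one empirical P values (250 simulations by default).
* **community** — plot filters (≥ 2 species, natural stands), MFA, community
  trait means, realized cold tolerance from range × raster overlay, ESRI
  ASCII grid I/O.
* **spatial** — Moran's I and equal-frequency distance-class correlograms
  (haversine distances) for raw MFA and model residuals.
* **env_models** — bagged regression trees (100 trees) with out-of-bag
  permutation importance rescaled to max = 1 and an OOB squared-error risk
  estimate; OLS variance partitioning of the top predictor vs the full set.
* **synthetic_data** — a generator for the whole study system: pure-birth
  phylogeny with families cut at a fixed age, traits under WN/BM/OU (plus a
  declining-optimum variant that freezes each family's optimum at its crown
  origin), a latitudinal minimum-temperature raster, tolerance-limited ranges,
  and plot communities sampled from each cell's climatically available pool.

## Worked example

Generate a full synthetic study system and run the core analyses:

```python
import numpy as np, pandas as pd
import commphylo as cp
from commphylo.synthetic_data import ScenarioConfig, generate_scenario

sc = generate_scenario(ScenarioConfig(seed=1))   # 300 species, 2,000 plots

# 4. trait evolution: does cold tolerance fit OU better than BM/WN?
tol = sc.traits["cold_tolerance"]
fits = cp.fit_all(sc.tree, tol)
comp = cp.compare_models(fits)
print(f"2LR(OU-BM) = {comp.lr2[('OU','BM')]:.1f}   "
      f"2LR(OU-WN) = {comp.lr2[('OU','WN')]:.1f}   "
      f"wAIC(OU) = {comp.waic['OU']:.3f}")

basis = cp.decompose(cp.patristic_matrix(sc.tree))
area = cp.psr_area(cp.psr_curve(tol, basis, tips=sc.tree.tips))
print(f"PSR area = {area:.3f}   Blomberg K = {cp.blomberg_k(sc.tree, tol):.3f}")

# 1. the emergent gradient: MFA against site minimum temperature
mfa = cp.mean_family_age(sc.communities, sc.families)
temp = np.array([sc.raster.grid[r, c] for r, c in
                 zip(sc.communities.plots["cell_row"], sc.communities.plots["cell_col"])])
print(f"corr(MFA, minimum temperature) = {np.corrcoef(mfa, temp)[0,1]:.3f}")

# 2. which community trait mean explains MFA?
trait_means = pd.DataFrame({t: cp.community_trait_mean(sc.communities, sc.traits[t])
                            for t in sc.traits.columns})
imp = cp.ensemble_importance(mfa, trait_means, n_trees=100, seed=11)
for name, val in imp.ranked():
    print(f"  {name:<16s} {val:.3f}")
print(f"OOB risk = {imp.risk:.1f} Myr^2")
```

Output:

```
2LR(OU-BM) = 52.0   2LR(OU-WN) = 183.3   wAIC(OU) = 1.000
PSR area = -0.171   Blomberg K = 0.241
corr(MFA, minimum temperature) = 0.887
  cold_tolerance   1.000
  leaf_phenology   0.006
  seed_size_log    0.005
  height           0.003
  dispersal_mode   0.001
OOB risk = 8.7 Myr^2
```

Reading the numbers: the large positive likelihood ratios and the OU Akaike
weight of 1 say cold tolerance evolved under constraint (niche conservatism);
the negative PSR area and K « 1 say the same thing — less trait divergence
than Brownian motion predicts. Downstream, plot MFA tracks site minimum
temperature (r = 0.89: cold plots hold young families), cold tolerance is by
far the top-ranked trait (importance 1.0, all others < 0.01), and the OOB
risk of 8.7 Myr² against an MFA variance of ≈ 139 Myr² means the trait model
accounts for most of the plot-to-plot variation.

The same analyses are available from the shell:

```bash
commphylo simulate --out-dir sim/ --n-species 300 --n-plots 2000 --seed 1
commphylo fit-models --tree sim/tree.nwk --traits sim/traits.tsv \
    --trait cold_tolerance --out fits.json
commphylo mfa --plots sim/plots.tsv --ages sim/families.tsv \
    --plot-meta sim/plot_meta.tsv --out mfa.tsv
commphylo discrete-test --tree sim/tree.nwk --traits sim/traits.tsv \
    --trait leaf_phenology --n-sims 250 --seed 42 --out test.json
```

Given a real calibrated phylogeny, a long-format trait table and a plot
occurrence list in the same formats, the identical commands reproduce the
model-selection table and geographic analyses for observed data.

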