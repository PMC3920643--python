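# Methods

This note documents the statistical models, the synthetic study design, the
numerical choices, and the limitations of `commphylo`. Nothing here reports a
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Phylogenies and their matrices

A `Phylogeny` is a rooted tree with polytomies allowed and per-node ages in
millions of years (Myr); branch lengths are derived as `parent_age −
child_age`, so a tree with extant tips (age 0) is ultrametric by construction.
Newick input with branch lengths is converted to ages by measuring depth from
the root and anchoring the deepest tip at age 0; topology-only input is
*uncalibrated* until dated.

**Age calibration** follows the branch-length-adjustment idea used to date
supertrees against a reference chronogram: the root, tips, and any constrained
internal nodes (identified order-independently by their tip set) are fixed,
and every undated node receives an age that spaces nodes evenly along the path
between dated anchors. Where a node lies on several paths to dated
descendants, each downward path to its *first* dated node proposes an
even-spacing age and the oldest proposal wins. This reproduces even spacing
along undated chains (a chain of two undated nodes between a root at 90 and
tips at 0 is dated 60, 30), can never place a node below a dated descendant,
and is clamped by the parent's age so no negative branch lengths can arise.
How the original tool resolved polytomies adjacent to dated nodes is not
documented; results may differ there.

Two matrices drive everything downstream, both computed from MRCA ages in
O(n²): the **patristic distance** `d_ij` (tip-to-tip path length; `2 ×
MRCA age` on ultrametric trees) and the **shared path** `s_ij`
(root-to-MRCA length, the Brownian covariance structure), linked on
ultrametric trees by `s_ij = T − d_ij/2`.

## Trait-evolution models (pGLS)

For a trait `x` on `n` tips, three Gaussian models are fitted by maximum
likelihood:

| model | covariance | free parameters (k) |
|---|---|---|
| WN | `σ² I` | mean, σ² (2) |
| BM | `σ² S` | root state, σ² per Myr (2) |
| OU | `σ²/(2α) · e^(−α d_ij) (1 − e^(−2α s_ij))` | optimum, σ², α (3) |

The mean/optimum is always the GLS mean `(1'V⁻¹x)/(1'V⁻¹1)` and σ² is
profiled in closed form (`r'C⁻¹r/n`), so WN and BM are closed-form and OU
reduces to a 1-D profile-likelihood search over log α. The OU form is the
stationary single-optimum covariance; multi-regime OU, early-burst and
branch-length transforms are out of scope. Discrete traits (0/1 phenology,
1–3 dispersal rank) are fitted with the same Gaussian machinery; their
validity is handled by the simulation null below.

Numerical contract: covariances are Cholesky-factorized; matrices with
condition number above 1e12 are refused with a hint about zero-length
duplicate tips. The α search runs on log scale over `[1e-9, 1e4]` per Myr: a
30-point log-grid bracket (the profile can be bimodal, with an interior mode
competing against a boundary plateau) followed by bounded refinement to 1e-8
on log α. The bounds are wide enough that both nested limits are numerically
reachable — at the lower bound the fit is within ~1e-6 log-likelihood units
of BM on century-depth trees, and at the upper bound the between-tip
correlations vanish (WN) even for very recent divergences — which is what
guarantees the ordering `lnL_OU ≥ max(lnL_BM, lnL_WN)` up to optimizer
tolerance.

Model comparison reports `2ΔlnL` with a χ² tail probability on `Δk` degrees
of freedom, plus Akaike weights. The plain χ²(1) for OU-vs-BM ignores that α
sits on the boundary of its space; the standard 50:50 mixture of χ²₀ and χ²₁
is available via `boundary_mixture=True` but is not the default, and the
boundary effect makes the default test conservative.

## PSR curves, PSR area, Blomberg's K

The eigenbasis is a principal-coordinate decomposition with Gower centering
of **−½D** (the patristic matrix treated as squared Euclidean distances —
which, on an ultrametric tree, it is: `−½ J D J = J S J`, the centered
Brownian covariance). Under this convention a BM trait projects independent
variance `σ² λ_k` onto axis `k`, so the expected PSR curve (R² of the trait
regressed on the first k axes, against the cumulative eigenvalue fraction) is
the 45° diagonal — the Brownian linearity that makes the signed **PSR area**
(trapezoidal integral of `R² − cum_frac`, origin included) a deviation
measure: negative under OU-like constraint, positive for anti-conserved
traits. Centering `−½D²` (classical PCoA of raw distances) is available via
`squared=True`; it does not have the linearity property (BM mean area ≈ −0.15
on a 100-tip tree) and is provided only because the eigenvector-regression
literature is ambiguous about squaring.

Because the axes are orthonormal and orthogonal to the intercept, sequential
OLS R² values equal cumulative squared correlations; they are computed that
way (the normal-equations route is the test oracle). All positive-eigenvalue
axes are retained, so the curve ends at (1, 1); negative eigenvalues (only
possible for non-Euclidean inputs) are dropped.

*Finite-sample bias.* The PSR area of a BM trait is not exactly centred on 0:
R² is a ratio of correlated quadratic forms, so `E[R²_k]` sits slightly below
the cumulative eigenvalue fraction, more so on unbalanced trees. Measured
over ten 100-tip pure-birth trees (200 BM simulations each) the per-tree mean
area was −0.014 to −0.040. Interpret small negative areas accordingly; the
pGLS likelihood-ratio test is the sharper instrument.

**Blomberg's K** is `(MSE0/MSE)` observed over expected, with `MSE0` the mean
squared deviation from the GLS mean, `MSE` the GLS quadratic form, and
expectation `(tr V − n/1'V⁻¹1)/(n−1)`; K = 1 under BM (exactly 1 on a star
tree), < 1 under constraint. PSR area and K are strongly positively
correlated across mixed WN/BM/OU regimes (tested at r > 0.5).

## Brownian-simulation nulls for discrete traits

PSR and pGLS assume continuous traits. For a discrete trait the test
statistic (PSR area, or `2LR(OU−BM)`) is referred to an empirical null built
by simulating BM on the phylogeny (default 250 simulations, σ² = 1 — both
statistics are scale-invariant), rank-discretizing each simulation so
category counts match the observed trait *exactly* (largest-remainder
apportionment; ties broken by tip order), and recomputing the statistic. The
headline P is one-tailed toward constrained evolution (PSR area below the
null; 2LR above it) with the add-one convention `P = (1 + #extreme)/(1 +
n_sims)`; both tails are always reported since the tail convention behind a
published single P value is rarely stated. Calibration: with the observed
trait itself a discretized BM draw, the rejection rate at the 0.05 level over
500 runs (99 simulations each, 64-tip tree) stays within [0.02, 0.09].

## Community statistics

MFA and community trait means are presence-based (unweighted over the species
present), not abundance-weighted. Species missing a trait value are excluded
from that trait's mean only — never from MFA; plots with no covered species
are dropped with a warning. Plot inclusion mirrors inventory practice: at
least two species, optionally natural stands only. Realized cold tolerance is
the minimum raster value over a species' range cells (nodata skipped);
enlarging a range can only keep or lower it. Rasters are plain-text ESRI
ASCII grids, cells addressed row-major from the north-west corner, 0-based;
coordinates are WGS84 decimal degrees. Dispersal mode is coded by dispersal
distance (unassisted = 1 < animal = 2 < wind = 3), phenology evergreen = 0 /
deciduous = 1, and seed size enters as log₁₀ mass so community means are
geometric.

## Spatial analysis

Moran's I uses the standard double-sum form with binary distance-class
weights; correlograms use haversine great-circle distances (spherical Earth,
6371 km) and equal-frequency classes (the original software's binning is
undocumented; the class count is a parameter). Empty classes merge with a
neighbor. For large plot sets the pairwise matrix is O(n²), so a seeded
random subsample (`subsample_n`) bounds memory, mirroring the common practice
of correlogram subsampling. Comparing the raw-MFA correlogram with the
correlogram of model residuals (same subsample seed) quantifies how much
spatial structure the model explains per distance class.

## Variable importance and variance partitioning

The tree-ensemble model is 100 bagged regression trees (scikit-learn tree
inducer; bootstrap size n, unlimited depth, minimum leaf 5 — stated because
the originating protocol specifies only the tree count). Importance is
out-of-bag permutation increase in squared error, averaged over trees, summed
over a categorical's one-hot columns, floored at zero and rescaled so the
maximum is exactly 1; the risk estimate is the OOB-aggregated mean squared
error (a held-out split is available as an option). Everything is
deterministic under a seed. Variance partitioning is plain OLS: R² of the
top predictor alone vs the full set; the increase is the contribution of
predictors not collinear with the top one.

## The synthetic study system

The generator produces every input the pipeline needs, all reproducible from
one seed, at a desk-scale stand-in for the real design (defaults: 300 species
vs 500 in a full continental phylogeny; 2,000 plots vs ~90,000; 40 × 40
minimum-temperature grid over latitudes 25–50° at −1.6 °C per degree with
2 °C cell noise, spanning roughly +4 to −35 °C).

* **Tree**: pure-birth (Yule) at 0.05 per Myr — root ages around 105–120 Myr
  at 300 species. Extinction adds nothing the fitted statistics need.
* **Families**: clades subtended by branches crossing a 70 Myr cut; family
  age is the crown (MRCA) age, monotypic families take the cut age. If a
  rare young tree makes the cut exceed the root age, the cut falls back to
  0.6 × root age with a warning.
* **Traits**: WN, BM, OU (exact branch-wise transitions), a shared
  `trend-OU` whose optimum declines linearly from root to present (exact
  linear-optimum transitions), and `family-trend-OU`, in which that declining
  optimum is *frozen per family at its crown origin* and tips evolve by OU
  around the family optimum. The freeze is the load-bearing mechanism: with
  any optimum path shared by all lineages, every tip has the same marginal
  law regardless of topology, so family age cannot correlate with family
  trait means even in expectation. Freezing at the crown encodes niche
  conservatism at the family rank — the biology the analysis presumes — and
  yields the young-family/cold-tolerance coupling by construction (measured
  r ≈ 0.95 between family age and family mean tolerance at default scale).
  Cold tolerance uses `family-trend-OU` (α = 0.1/Myr, σ² = 2, optimum from
  −2 °C at the root to −38 °C at present); height is stationary OU, log seed
  size BM, and the two discrete traits are frequency-matched discretized BM.
* **Ranges**: a species occupies every cell no colder than its tolerance,
  with a 20 °C warm-edge cap so ranges turn over along the gradient rather
  than nesting.
* **Plots**: placed in random cells; each draws Poisson(6) species without
  replacement from the cell's pool; draws with fewer than two species are
  discarded (the inventory inclusion rule). Local covariates (elevation,
  slope, aspect, physiographic class) are generated independent of climate,
  so they should — and do — rank at the bottom of the environmental model.

What passing tests on this system do and do not show: the generator encodes
exactly one assembly force (cold tolerance filtering), so top-ranked
importances are a *recovery* check, not evidence about real forests; real
inventories add abundance, dispersal limitation, disturbance history,
spatially structured local covariates, taxonomic error and imperfect
detection, none of which are emulated. The PSR-area signature of the
family-conserved tolerance trait is the weakest indicator at this scale
(negative on most but not all scenario seeds — between-family trend spread
acts Brownian-like, e.g. +0.08 on one seed against −0.08 to −0.18 on
others), while the pGLS likelihood ratio is decisive (2LR(OU−BM) ≈ 45–100
across seeds). Community trait means inherit phylogenetic structure from the
species-pool gradient, so a neutral trait can occasionally compete in
importance on a given realization — the same collinearity the variance
partition is there to expose.

## Problem sizes and determinism

Default analysis sizes were chosen so the whole pipeline — generation, model
selection, 250-simulation null, importances, correlograms and calibration
studies — completes in well under a minute on one CPU: correlograms are
O(n²) in plots (2,000 plots ≈ 4 s), OU fits are O(n³) per likelihood
evaluation (a 300-species fit ≈ 0.3 s), and the discrete-null calibration
uses 99 simulations per run, 500 runs, on a 64-tip tree. Every stochastic
step takes an explicit seed or numpy Generator; fixed seeds give bit-for-bit
reproducible output, including the 30-decade α grid search and bootstrap
resampling.

## Known limitations

* Single-optimum stationary OU only; no measurement-error term in the pGLS.
* The χ²(1) OU-vs-BM test is conservative at the α boundary (mixture
  available, not default).
* PSR area carries the finite-sample negative bias described above.
* BLADJ polytomy handling may diverge from the original tool (undocumented
  there).
* Equal-frequency correlogram binning is a choice, not a reproduction of any
  specific legacy default.
* Realized cold tolerance floors at the coldest habitable cell, so it
  compresses differences among the hardiest species — in range-overlay data
  and in this package alike.
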