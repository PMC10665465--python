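# Methods

This note documents the models and procedures the package implements,
the defaults it fixes where the underlying methodology leaves choices
open, and what the synthetic benchmarks do and do not establish.

## Rate regimes on dated trees

A diversification history is a set of regimes anchored to branches of a
rooted ultrametric tree (branch lengths in Ma) at absolute times
measured from the root. Within a regime started at `t0`,
`lambda(t) = lambda0 * exp(b (t - t0))` and
`mu(t) = mu0 * exp(z (t - t0))`. Every lineage is governed by the
nearest upstream regime on its root-to-tip path — when several events
sit on one path, the latest anchor time wins. The event-table CSV
dialect (columns `generation, leftchild, rightchild, abstime,
lambdainit, lambdashift, muinit, mushift`) anchors each row at the
branch subtending `MRCA(leftchild, rightchild)`, with an empty
`rightchild` denoting a pendant branch. The default dialect uses
`z = 0` (constant extinction within a regime), since regime extinction
curvature is rarely identifiable; `z` is carried through all code paths
regardless.

**Tip rates** are the instantaneous regime rates evaluated exactly at
the present (`dt = tree height - anchor time`). A defensible alternative
is the mean rate over the terminal branch segment; we chose
instantaneous-at-present because branch rates are conventionally
discretized into segments of 2% of tree height and the terminal segment
spans at most a few Ma on trees of ~100 Ma, making the two readings
nearly indistinguishable at that discretization.

**Rates through time** restrict the tree to the spanning subtree of a
tip subset and average, at each grid time (Ma before present), the
rates of all branches crossing that time. Branch rates are
piecewise-constant on segments of `seg_frac * height` (default 0.02),
evaluated at segment midpoints, clamped so a regime is never evaluated
before its own anchor; the present is evaluated exactly so the curve at
t = 0 coincides with the mean tip rate.

**Genus age** is stem age: the node time of the tip's parent.
**Sampling fractions** for genus-level trees are `1/richness` per tip
plus a backbone completeness fraction (0.725 for a molecular-only tree,
0.97 for a complete genus-level tree are the conventional settings).

**Polytomy resolution** replaces Bayesian resolvers with a desk-scale
stochastic one: children of each polytomy are joined pairwise in
uniform-random order, each join time drawn uniformly strictly between
the parent's time and the older child. This preserves all existing node
times and tip sets and is reproducible from a single seed. It samples
*a* uniform-ish resolution, not the birth-death posterior; studies that
need posterior-calibrated resolutions should treat it as a placeholder
topology generator.

## Supermatrix marker selection

Duplicate records per (species, marker) are reduced to one by
precedence *longest → published → most recent*. The methodology that
motivated this package states the longest-sequence and
most-recent rules explicitly and a publication preference separately;
the relative precedence of publication status and date at equal length
is not stated anywhere, so this package fixes length first, publication
second, date third.

Greedy composite-terminal selection per genus: (1) sort markers by
ascending species count (alphabetical at ties); (2) for each
not-yet-covered marker, add the candidate species covering the most
markers overall, breaking ties by highest total relative sequence
length (length / genus-wide maximum per marker), then alphabetically;
(3) stop when all available markers are covered; (4) take the longest
sequence per marker among the chosen species. Because the loop
continues until every available marker is covered, the selection always
attains the brute-force-maximal coverage; the test suite verifies this
by subset enumeration for genera with ≤ 6 species.

Monophyly screening declares a genus monophyletic iff the MRCA of its
tips contains no foreign tips; otherwise its tips decompose into
maximal genus-pure clades and the largest becomes the *core* used to
represent the genus (ties: more deduped records, then alphabetical
first tip). Para- and polyphyly are treated identically — no separate
criterion exists for a "polyphyletic core", so the single largest pure
clade rule is applied uniformly.

## Occurrence QC and assemblages

Spatial acceptance by record granularity: locality records need ≥ 80%
footprint overlap with a unit, grid cells strictly > 50%, coordinates
must fall inside, range maps pass (they were digitized against the unit
system). Introduced-range records are removed. Presences are then
thresholded by corroborating source counts per region group: Europe 3;
Australia, China, Madagascar, North America 2; all other regions 1.
When several records support one (genus, unit), the best-corroborated
record speaks for the presence (max source count, after dropping
introduced records).

Assemblage metrics are unweighted arithmetic means over incident genera
(no range-size or abundance weighting). Quartile partitions cut at the
globally interpolated 25/50/75 percentiles, boundary values falling to
the lower bin; per-unit proportions are counts over the unit's
richness. Units join one of 13 ten-degree latitudinal belts
(S55 … N75) iff strictly more than half their area lies in it; units
without a majority belt stay unassigned and drop out of belt unions.
Belt genus sets are unions over member units, so widespread genera
enter several belts.

Growth-form labels: woody if > 60% of species woody, herbaceous if
< 40%, otherwise unclassified (the two published thresholds leave a
deliberate gap); CAM/C4 are any-species flags.

## Spatially corrected statistics

The modified t-test estimates, for each of `k` distance classes
(Sturges' rule on the number of pairs; equal-width classes on
great-circle centroid distances), a Moran-type autocorrelation of each
variable, clips it to [-1, 1], assembles correlation matrices
`S = I + sum_k rho_k W_k`, and computes
`ESS = 1 + tr(B Sx) tr(B Sy) / tr(B Sx B Sy)` with `B` the centering
matrix. Degenerate or negative denominators (no usable evidence of
positive autocorrelation) fall back to `ESS = n`, and the estimate is
clamped to [1, n]. The p-value refers `(ESS - 2) r^2 / (1 - r^2)` to
`F(1, ESS - 2)`. Both the df-scaled F and the unscaled ratio
`r^2/(1-r^2)` are reported because published tables conventionally
print the unscaled ratio. Note that published df/ESS pairs for this
test are sometimes internally inconsistent with `df = ESS - 2` (one
quoted pair has df = ESS + 2); this implementation always uses
`df = ESS - 2`. Simulation checks: on iid fields (n = 60, 500
replicates) the empirical type-I error sits at the nominal 5%, with
mean ESS/n ≈ 0.97; on fields sharing a smooth latitudinal trend the
corrected test rejects substantially less often than the naive Pearson
t-test.

RMA (model II) regression uses the closed form
`slope = sign(r) sd_y / sd_x` through the means. Quadratic latitude
fits are ordinary least squares on `lat + lat^2`; lowess uses tricube
local linear smoothing with span 0.5 by default.

The richness-preserving null model redraws, per unit and replicate,
exactly the observed number of genera uniformly without replacement
from the full pool, recomputes per-unit means and the chosen scalar
statistic, and reports the two-sided empirical p
`(1 + #{|null| >= |obs|}) / (reps + 1)` (default 999 replicates). The
empirical p is primary because null distributions of correlations need
not be normal; a z-test against the null mean/sd is retained as an
option. Rank-based group comparisons use the Wilcoxon rank-sum /
Mann–Whitney U test (exact for tie-free pooled n ≤ 20, tie-corrected
normal approximation otherwise) with Holm adjustment for pairwise
batteries; Holm was chosen because it controls FWER without
independence assumptions.

## The synthetic generator

The generator produces the structure the analyses assume, with ground
truth attached. Topologies are constant-rate birth-death trees grown
forward from two crown lineages (lambda 0.08, mu 0.02 events/lineage/Ma
by default — net diversification 0.06, in the range of genus-level seed
plant estimates), conditioned on the target tip count by rejection of
extinct runs, and stopped uniformly inside the next waiting interval.
Shift events fall on branches as a Poisson process (0.002 per
lineage-Ma), each multiplying the parental speciation rate by a
lognormal factor (log-sd 0.5), drawing `b ~ U(-0.01, 0.005)` per Ma and
inheriting extinction. Geographic units draw lognormal areas matched to
the published unit system (mean 329,670 km², sd 198,191 km²), uniform
centroids over latitudes -55° to 70°, belt fractions from the unit's
latitudinal extent, and round-robin region groups.

Occupancy is Bernoulli with
`P(g in u) = logistic(alpha_u + (beta_age z(age_g) + beta_rate z(r_g)) |lat_u|/90)`,
with `alpha_u` solved by bisection so expected richness follows the
equator-peaked profile `p0 (1 - gamma (lat/90)^2)`; defaults
`beta_age = -2`, `beta_rate = +2`, `gamma = 1.2`, `p0 = 0.25` encode
the empirical pattern (old, slow genera toward the equator; a roughly
four-fold richness drop by |lat| = 70°, comparable to real latitudinal
diversity gradients). Records carry granularities (30% coordinates, 20%
localities, 20% grid cells, 30% range maps), overlaps drawn so QC has
realistic rejections, source counts `1 + Poisson(1.5)`, and a 5%
introduced rate. Occupancy is independent across units given the tip
covariates — no dispersal or range cohesion — which suffices for
testing assemblage statistics but understates the spatial coherence of
real ranges; passing benchmarks therefore demonstrate correctness of
the statistical machinery, not realism of range dynamics. Species
richness per genus is rounded-lognormal (median ≈ 6), woody fractions
U-shaped beta, CAM/C4 rare flags.

All draws descend from one integer seed through spawned substreams;
identical seeds give byte-identical trees, tables and records.

## Problem sizes and numerical choices

The benchmark suite uses desk-scale sizes chosen to make the Monte
Carlo statements sharp while keeping runs comfortably short: 50–100
simulated studies of 100–300 genera over 60 units, 999-replicate null
ensembles for single runs and 199-replicate ensembles inside
200-seed calibration sweeps (0.005 p-resolution is ample at the 0.05
level), 500 iid simulations for the type-I error of the modified
t-test. Ultrametricity is validated at 1e-6 relative tolerance;
tip-rate oracle equivalence is asserted at 1e-9; rate-through-time
discretization error is bounded by `|b| * lambda * seg` per segment.

## Known limitations

* The polytomy resolver is uniform-stochastic, not posterior-based.
* Regime extinction uses `z = 0` by default; event tables with nonzero
  `mushift` are honored but not produced by the generator.
* The null model assumes a single shared genus pool; region-restricted
  pools are not implemented.
* The effective-sample-size estimator uses equal-width distance
  classes; irregular unit configurations with very skewed distance
  distributions may deserve quantile classes.
* Quartile boundaries use interpolated percentiles with lower-bin
  ties; nearest-rank conventions would shift labels of boundary genera.
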