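# Methods

This note records what `elevbeta` computes, the assumptions behind each
step, the defaults and why they were chosen, and the places where a
genuine design choice had to be made.

## Pairwise decomposition

All dissimilarity is pairwise and incidence-based. For matching
components *a*, *b*, *c* the package reports

- total dissimilarity β_sor = (b + c)/(2a + b + c),
- turnover β_sim = min(b, c)/(a + min(b, c)),
- nestedness-resultant β_sne = β_sor − β_sim.

β_sim is insensitive to richness differences (it compares the poorer
site's unique fraction), so β_sne isolates the part of β_sor caused by
one assemblage being a subset-like reduction of the other. Integer
components are decomposed in exact rational arithmetic and converted to
float once, so β_sor − (β_sim + β_sne) is zero to machine precision;
float components (branch lengths, areas) compute β_sne as the literal
difference, which preserves additivity by construction.

**Empty assemblages.** If one member of a pair is empty the turnover
ratio is 0/0. Default policy: the pair is flagged `excluded` with a
reason and carries no indices. The alternative `empty_pair="as_one"`
records β_sor = 1 (an empty vs non-empty pair is maximally dissimilar)
while leaving the component split undefined, so such pairs enter
whole-index analyses but never component comparisons. The choice matters
only for gradients whose extremes hold no species (e.g. summit sites
above a group's range limit); both policies are explicit, neither is
guessed.

## Phylogenetic dimension

Branch-length components are measured on the tree pruned to the regional
species pool — the union of species over *all* sites of the group — with
the root stem dropped. A branch belongs to an assemblage when at least
one of its descendant tips occurs there; *a* sums branches on both
assemblages' root-to-tip paths, *b* and *c* the private remainders. This
is the standard shared-branch-length (PhyloSor-family) construction; on a
unit-branch star tree it degenerates exactly to the taxonomic counts,
which the test suite checks.

Pruning to the pool (rather than per pair) keeps *a*, *b*, *c* additive
across pairs and makes the null model's label shuffle meaningful: the
tree is fixed, the species → tip assignment is permuted.

**Tree distributions.** When several trees are supplied (e.g. a
posterior sample), the default is to compute indices per tree and report
the per-pair arithmetic mean with across-tree standard deviations —
uncertainty in the phylogeny propagates into visible spread rather than
being collapsed early. A majority-rule consensus tree (mean split branch
lengths) is available via `aggregation="consensus"` for workflows that
require a single tree.

**Blomberg's K.** For a tip trait x on a tree with Brownian covariance V
(V_ij = shared root-to-MRCA path length),

    K = (MSE0 / MSE) / E[MSE0 / MSE],

with the phylogenetic mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), MSE0 the ordinary mean
square about â, MSE the V-weighted mean square, and
E[MSE0/MSE] = (tr V − n/(1ᵀV⁻¹1))/(n − 1). K = 1 is the Brownian
expectation on that tree; K < 1 means less signal. On a star tree V is
proportional to the identity and K is exactly 1 for any trait — a useful
closed-form anchor. Significance comes from tip permutations (default
999, seedable): p is the share of permutations (observed included) whose
MSE0/MSE ratio reaches the observed one. A singular V (zero-length
cherries) is refused with a remediation hint rather than regularized
silently. Pipeline-level signal tests are run on log-transformed size
attributes, the scale on which the traits are modelled.

## Functional dimension

Traits are strictly positive size measurements. The trait space is built
by natural log → z-score (ddof 1) → PCA via SVD of the centred matrix;
with z-scoring this is correlation-based PCA regardless of trait units.
Axis signs are fixed deterministically (largest-magnitude loading
positive). Two axes are kept: assemblage hulls and their intersections
are computed in 2-D, which is why the three-species minimum richness
filter exists (min_richness = d + 1 = 3). With exactly two traits the two
axes carry 100% of the variance.

Hulls and hull intersections use exact convex-polygon geometry (shapely's
convex hull and clipping); unique areas b = V₁ − a and c = V₂ − a are
clamped to zero when within 1e−9 below it (clipping float seepage) and
any larger negative is an error. Collinear (zero-area) hulls are excluded
with a flag, never jittered: jitter would silently perturb results.
Trait spaces are built per species group; size axes of a passerine and an
ant are not comparable, so no cross-group common space exists. PCA scores
are computed on all species in the group's trait table (the natural
sampling frame when the table is the group's regional pool).

## Null models and SES

SES = (observed − null mean)/null sd per pair and index, with the sample
standard deviation over `n_rand` (default 999) randomizations. Schemes:

- `richness_preserving_draw` — each site keeps its richness; species are
  drawn equiprobably from the pool. The least constrained community null.
- `fixed_fixed_swap` — 2×2 checkerboard swaps preserving row and column
  sums (default 10 000 burn-in attempts, 1 000 thinning between samples,
  one sequential chain). Margins are asserted after every sample.
- `label_shuffle` — the community matrix is untouched; the species → tip
  or species → coordinate assignment is permuted, isolating tree/trait
  structure from composition.

Default pairing: taxonomic SES uses the margin-conserving swap null;
phylogenetic and functional SES use label shuffles. These are the
field-standard pairings for these metrics; the scheme is a parameter and
is recorded in every output row, so no output can be misread as coming
from a different null. The seed is mandatory and recorded likewise.

Pairs whose null standard deviation is indistinguishable from float
noise (≤ 1e−12 relative) are flagged `degenerate_null` with NaN SES; if
*every* pair degenerates the run is refused as uninformative (e.g. a tip
shuffle on a star tree, which cannot change any branch component).

Calibration: when the observed data are themselves drawn from the null
scheme, SES is approximately standard normal. The acceptance suite
verifies mean SES within ±0.15 and an |SES| > 1.96 rate between 2% and 9%
over 100 replicates at 999 randomizations.

## Comparative statistics

**Wilcoxon rank-sum.** W is the first sample's rank sum with average
ranks for ties; z = (W − μ_W)/σ_W with tie-corrected σ_W and no
continuity correction; two-sided p from the normal tail. An
exhaustive-enumeration mode (all C(n, n₁) rank assignments, feasible to
n ≈ 14) serves as a cross-check. The normal approximation tracks the
exact p to within 0.01 wherever the exact p ≤ 0.05 at these sample
sizes; in the non-significant mid-range the discrete rank-sum
distribution genuinely departs from the normal curve by up to ~0.07 in
two-sided p at n₁ = n₂ = 6 (and more for smaller samples), which is a
property of the statistic, not of the implementation. Decisions are
reported at α = 0.05 with an additional "nearly significant"
band 0.05 < p ≤ 0.1.

**Distance decay.** OLS of an index on pairwise elevational distance in
metres. The slope's t-test treats pairs as independent, which pairwise
distances are not; this matches the standard practice the pipeline
mirrors, and a Mantel-style permutation p (site elevations permuted) is
available behind `mantel_permutations=` for readers who want it. Slopes
are compared across groups only where significant (p ≤ α), ranked
descending, ties in input order.

**Forward AIC.** Greedy forward selection over pairwise environmental
predictors using AIC = n·ln(RSS/n) + 2k (Gaussian form, constants
dropped consistently; k counts intercept and slopes). Selection starts
from the intercept-only model and stops when no candidate lowers AIC;
ties break by column order; perfectly collinear candidates (|r| = 1) are
dropped with a warning, keeping the earlier column. Predictors default to
absolute between-site differences of AMT, AP, AMH, NPP and PET; a
`form="midpoint"` variant (pair means) exists because "how far apart" and
"where on the gradient" are different questions. Note the +2 penalty
accepts a pure-noise predictor ~16% of the time; with five candidates an
intercept-only outcome is therefore *not* the majority expectation under
pure noise, and the tests assert the per-candidate behaviour.

**Climate interpolation.** AMT/AP/AMH at a site are linearly
interpolated between the two elevation-nearest weather stations;
out-of-bracket sites are extrapolated and flagged. Two nearest stations
at identical elevation are an error (the line is undefined).

## Synthetic gradients

The generator emulates a ~2500 m montane gradient: default 11 sites
evenly spaced from 2000 to 4500 m, 24 species with contiguous elevational
ranges. Group-sized presets mirror the three surveyed assemblage types
(17 sites / 116 species; 9 / 14; 11 / 18, with 6 / 5 / 2 size traits).
Three range geometries give the analytic anchors the tests rely on:

- **turnover** — equal-breadth ranges (default 30% of the span),
  midpoints staggered across the gradient: distant sites share no
  species; fully disjoint pairs have β_sim = 1, β_sne = 0.
- **nested** — every range starts at the base with a random upper limit
  (uniform up to one site-spacing above the summit, so the top site is
  usually occupied): assemblages are ordered subsets and β_sim = 0 on
  every pair, exactly.
- **mixed** — uniform midpoints, breadths uniform in 20–60% of the span:
  both components present, no closed form (`expected_behaviour` marks
  this).

The phylogeny is pure-birth (rate 1) grown to the target tip count, with
all terminal branches extended by one exponential waiting time so the
tree stays ultrametric with a non-singular Brownian covariance. Range
midpoints can be coupled to the tree: the latent score is
κ·(standardized BM) + √(1−κ²)·iid noise, linearly rescaled to the
gradient (κ = 0, the default, gives independent uniform midpoints; κ = 1
a pure BM realisation, under which Blomberg's K of the midpoint averages
≈ 1). Size traits are geometric Brownian motion — BM on the log scale
(sd 0.5 over the tree depth around a log-mean of 3) — so the functional
module's log transform recovers exactly the simulated process.

Environment columns: AMT falls at 6.5 °C/km from 25 °C at sea level;
AP and AMH rise monotonically; PET falls; NPP is hump-shaped with its
peak mid-gradient (to exercise non-monotone predictor selection); all
with Gaussian noise (scale set by `env_noise_sd`). These are plausible
monsoonal-mountain shapes chosen once for realism, not fitted to any
dataset.

What the generator does *not* emulate: abundance, dispersal dynamics,
range fragmentation (ranges are contiguous by construction), observation
error, or correlated trait evolution. Tests passing on synthetic data
therefore validate the estimators and their qualitative behaviour, not
any claim about a particular field system.

One seed drives a single named RNG stream for all sub-draws;
configurations that leave a site empty are redrawn up to 100 times
(ranges only) before erroring, unless empty sites are explicitly allowed.

## Pipeline

`run_pipeline` runs, per group: observed beta tables in the enabled
dimensions, within-dimension component comparisons, cross-dimension
comparisons, SES tables, distance-decay fits for observed and SES
indices, forward-AIC selection, and per-trait Blomberg's K; then the
cross-group slope ranking. Cross-dimension comparisons default to the
*shared* computable-pair subset (pairs valued in every compared
dimension), because comparing a functional index computed on a filtered
subset against a taxonomic index on all pairs would confound the
comparison with the filter; `shared_subset=False` reverts to
per-dimension subsets. Group failures are isolated; the run fails only
when every group fails. Identical config + seed reproduces every table
byte for byte (sub-seeds are derived from the master seed and a stable
hash of the group name), and the manifest records the config hash, seed
and library versions.

## Problem sizes in the shipped checks

The test suite and the acceptance script use sizes chosen to make the
statistical checks decisive while staying lightweight: exhaustive
decomposition checks over 6-species worlds, 50 polygon pairs at 10⁵
Monte-Carlo points, 100 calibration replicates at 999 randomizations on
8 × 15 matrices, 200 Brownian replicates on 100-tip trees, and 100
seeded recovery runs per range geometry.

## Known limitations

- Functional beta is strictly 2-D; higher-dimensional hull volumes are
  out of scope (and would need a different richness filter).
- Pairwise regressions inherit the non-independence of pairs; the Mantel
  option mitigates but the default mirrors common practice.
- The swap null's chain is a heuristic sampler of the fixed-margin
  ensemble; burn-in and thinning defaults are conventional, not proven
  mixing times.
- Multi-site (non-pairwise) dissimilarity and abundance-based indices
  are out of scope.
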