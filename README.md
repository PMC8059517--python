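# elevbeta

Multi-dimensional pairwise beta-diversity along elevational gradients.

Community ecologists working on mountain systems routinely ask *why*
assemblages differ between sites: do species get **replaced** as the
environment changes (turnover), or do poorer assemblages form ordered
**subsets** of richer ones (nestedness)? And does the answer change when
"different" is measured by species identity, by shared evolutionary
history, or by functional traits? `elevbeta` implements the complete
comparative toolkit for these questions: pairwise dissimilarity in three
dimensions, its additive decomposition, null-model standardization, and
the statistics used to compare components, dimensions and species groups
along a gradient. A seedable synthetic-gradient generator stands in for
field data, so every analysis is runnable end to end out of the box.

## The indices

For one pair of assemblages with matching components *a* (shared), *b*
and *c* (unique to either side):

```
β_sor = (b + c) / (2a + b + c)          total Sørensen dissimilarity
β_sim = min(b, c) / (a + min(b, c))     turnover component
β_sne = β_sor − β_sim                   nestedness-resultant component
```

The same three formulas are applied in three currencies:

| dimension    | a, b, c measured as | module entry point |
|--------------|---------------------|--------------------|
| taxonomic    | species counts | `beta_matrix_taxonomic` |
| phylogenetic | shared / unique branch length on the pool-pruned tree (PhyloSor family) | `beta_matrix_phylo` |
| functional   | intersection / unique convex-hull areas in a 2-D PCA trait space | `beta_matrix_functional` |

Functional measures require at least three species per assemblage (a 2-D
hull needs three non-collinear points); smaller assemblages are flagged
and excluded, never silently dropped.

Around the indices the package provides:

- **Null models and SES** (`ses_beta`): standardized effect sizes
  (observed − null mean)/null sd under richness-preserving draws,
  fixed-fixed checkerboard swaps, or tip/trait label shuffles. Negative
  SES flags environmental filtering, positive SES limiting similarity.
- **Phylogenetic signal** (`blomberg_k`): Blomberg's K with a
  tip-permutation test.
- **Gradient statistics** (`wilcoxon_z`, `distance_decay`,
  `compare_slopes`, `forward_aic`, `interpolate_station_climate`): the
  three comparison levels — turnover vs nestedness within a dimension,
  the same component across dimensions, and distance-decay slopes across
  species groups — plus forward-AIC selection of environmental predictors
  and climate interpolation from the two elevation-nearest weather
  stations.
- **Synthetic gradients** (`simulate_metacommunity`): metacommunities
  with controlled turnover / nested / mixed range geometry, a pure-birth
  phylogeny, Brownian size traits, and elevation-driven environmental
  columns; presets size the data like surveys of passerines (17 sites,
  116 species), rodents (9, 14) and ants (11, 18).
- **A pipeline** (`run_pipeline`, CLI `elevbeta`) orchestrating all of it
  into tidy CSVs with a manifest and a human-readable summary.

## Worked example

```python
from elevbeta import (SimulationConfig, simulate_metacommunity,
                      beta_matrix_taxonomic, wilcoxon_z, distance_decay)

cfg = SimulationConfig(seed=42, mode="mixed", n_sites=11, n_species=24)
ds = simulate_metacommunity(cfg)            # community, sites, tree, traits

tab = beta_matrix_taxonomic(ds.community)   # 55 pair rows
ok = ~tab["excluded"]
print(tab.loc[ok, "beta_sim"].mean())       # 0.652
print(tab.loc[ok, "beta_sne"].mean())       # 0.033

res = wilcoxon_z(tab.loc[ok, "beta_sim"], tab.loc[ok, "beta_sne"])
print(f"|z| = {res.abs_z:.3f}, p = {res.p:.2e}")   # |z| = 7.695, p = 1.41e-14

fit = distance_decay(tab, ds.sites, "beta_sor")
print(f"S = {fit.slope:.3e} per m, r² = {fit.r2:.2f}")  # S = 4.484e-04, r² = 0.69
```

Read: on this simulated gradient turnover dominates (mean β_sim 0.652 vs
mean β_sne 0.033; the Wilcoxon rank-sum test rejects equality decisively),
and total dissimilarity increases by ≈0.45 per vertical kilometre of
elevational separation.

The same analysis from the shell:

```bash
elevbeta simulate --mode mixed --seed 42 --out data/
elevbeta beta --matrix data/community.csv --out beta.csv
elevbeta ses  --matrix data/community.csv --n-rand 999 --seed 1 --out ses.csv
elevbeta run-all --config config.yaml --seed 1 --out results/
```

## Layout

```
src/elevbeta/
  datatypes.py    CommunityMatrix, SiteTable, TraitTable, StationRecords, PhyloTree
  io.py           CSV/newick readers, tidy result writer + data dictionary
  decompose.py    the Sørensen-family additive decomposition
  taxonomic.py    species-identity beta
  phylo.py        branch-length beta, tree distributions, Blomberg's K
  functional.py   trait space (log → z-score → PCA) and convex-hull beta
  nullmodels.py   randomization schemes and SES
  stats.py        Wilcoxon, distance decay, slope ranking, forward AIC, climate
  simulate.py     synthetic elevational metacommunities
  pipeline.py     end-to-end orchestration
  cli.py          simulate / beta / ses / compare / run-all
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
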