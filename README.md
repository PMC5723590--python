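# betascale

Scale-dependent beta diversity of stem-mapped forest plots: total community
variance with local contributions (LCBD), PCNM spatial eigenvectors, and
RDA-based variation partitioning of composition into environmental and
spatial fractions — plus a synthetic stem-map generator with known
environmental-filtering and dispersal-limitation structure.

## The problem

In a fully mapped forest plot, how different are the tree communities of
neighbouring quadrats ("grains"), how does that difference change with the
grain size used to sample a fixed extent, and how much of it is driven by
habitat (soil, topography) versus by spatial processes such as dispersal
limitation? These are core questions for community ecologists working with
large forest-dynamics plots, and the same toolkit (Hellinger distances,
constrained ordination, Moran eigenvector maps) is standard in microbiome
and metagenomics beta-diversity analysis.

## The statistics

Given a grains-by-species abundance table `X`, each row is
Hellinger-transformed,

    y_ij = sqrt( x_ij / Σ_k x_ik ),

and beta diversity is the total variance of `Y`:

    SS_Total = Σ_ij (y_ij − ȳ_j)²,     BD_Total = SS_Total / (n − 1),

which lies in [0, 1] for Hellinger data. Each grain's share
`LCBD_i = SS_i / SS_Total` measures its compositional uniqueness
(Σ LCBD_i = 1).

Spatial predictors are PCNM eigenvectors: eigendecompose the Gower-centered,
truncated inter-grain distance matrix (truncation t = longest minimum
spanning tree edge, distances beyond t replaced by 4t) and keep eigenvectors
with positive eigenvalue and Moran's I above its null expectation −1/(n−1).

Variation partitioning uses redundancy analysis (RDA) with the Ezekiel
adjustment `R²_adj = 1 − (1 − R²)(n − 1)/(n − m − 1)`:

    [a+b] = adjR²(Y ~ E)   environment (pure + spatially structured)
    [b+c] = adjR²(Y ~ S)   space (marginal)
    [a+b+c] = adjR²(Y ~ E ∪ S),   [d] = 1 − [a+b+c]   unexplained

so `[a] = abc − bc`, `[c] = abc − ab`, `[b] = ab + bc − abc`, and
`a + b + c + d = 1` exactly. Predictors enter after permutation-based
forward selection (global gate at α, per-step residual-permutation F tests,
optional adjusted-R² ceiling); fractions `[a+b]` and `[c]` carry permutation
p-values (`[c]` by residual permutation under the environmental model).

## Worked example

```python
import betascale as bs

env, stems = bs.scenario("mixed", seed=1)     # 260 x 200 m synthetic plot
table = env.sample_table()                    # soil samples + vertex elevations
ga = bs.analyze_grain(stems, table, 20.0, n_perm=999, seed=1)
print(f"BD_Total at 20 m = {ga.bd_total:.3f} (n = {ga.n_grains} grains)")
print(ga.partition.summary())
```

prints

```
BD_Total at 20 m = 0.390 (n = 130 grains)
Variation partitioning (adjusted R^2)
----------------------------------------------
grains n = 130, env predictors = 8, spatial predictors = 59, permutations = 999
fraction                      adjR2        p
[a] pure environment         0.0168  0.0010**
[b] spatially struct. env    0.2443       --
[c] pure space               0.4006  0.0010**
[d] unexplained              0.3384       --
[a+b] environment            0.2610  0.0010**
[b+c] space (marginal)       0.6449       --
[a+b+c] total explained      0.6616  0.0010**
```

Read: at the 20 m grain the average between-grain Hellinger dissimilarity is
0.39; two thirds of the compositional variance is explainable, with pure
space ([c] = 0.40) dominating the environmental signal ([a+b] = 0.26) — the
expected signature of the half-dispersal-limited `mixed` scenario at the
smallest grain. `bs.run_all(bs.RunConfig(...))` runs all four grain sizes
(20–50 m) and writes `bd_by_grain.tsv`, `lcbd_*.tsv` and `varpart.tsv`;
`bs.render_figures(report, outdir)` draws the BD-vs-grain curve, shaded LCBD
maps and the environment/space bar chart. The same operations are available
from the shell via `betascale simulate | aggregate | betadiv | pcnm |
select | varpart | run-all`.

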