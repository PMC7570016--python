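# diallelkit

Analysis toolkit for **half-diallel maize trials evaluated under multiple
plant densities and locations**: combined split-plot ANOVA, Griffing
Method 4 combining ability, density-response summaries, SSR marker
diversity with UPGMA clustering, and genetic-distance/performance/SCA
correlations — plus a synthetic-data generator with the same statistical
structure, so the whole chain is testable without field data.

## Who this is for

Maize (and general plant) breeders analysing diallel mating designs: `n`
inbred parents crossed in all `n(n-1)/2` combinations (no selfs, no
reciprocals), with the F1 hybrids grown in a split-plot
randomized-complete-block trial — plant densities on main plots, hybrids
on sub-plots — replicated across locations. The toolkit answers the
standard questions of such a trial: which parents transmit superior
performance (GCA), which specific crosses exceed their parental
expectation (SCA), whether gene action is predominantly additive
(MS_GCA/MS_SCA ratio), how traits respond to denser planting, and whether
marker-based parental distance predicts hybrid performance.

## The model

For cross means `y_ij` within a stratum, Griffing's Method 4, Model I
fits the saturated fixed-effects decomposition

```
y_ij = mu + g_i + g_j + s_ij,   sum_i g_i = 0,   sum_{j!=i} s_ij = 0
```

with closed forms `g_i = [n T_i - 2T] / [n(n-2)]` and
`s_ij = y_ij - (T_i + T_j)/(n-2) + 2T/[(n-1)(n-2)]`, where
`T_i = sum_j y_ij` and `T = sum_{i<j} y_ij`. The hybrids sum of squares
splits orthogonally into GCA and SCA components (df `n-1` and
`n(n-3)/2`), and the same partition applied per environment cell yields
the GCA×E / SCA×E interaction rows of the combined split-plot ANOVA.
Standard errors of every effect come from exact propagation of
`Var(cell mean) = MS_error / r` through each effect's linear
coefficients.

Marker diversity uses allele counts over the (homozygous) inbred lines:
gene diversity `1 - sum p_i^2`, Botstein's
`PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2`, Jaccard distance on the
binary band expansion, and UPGMA (size-weighted average linkage, heights
`d/2`) for the dendrogram.

## Worked example

```python
from diallelkit import simulate, anova, griffing, ssr, datasets

cfg = simulate.make_standard_config(seed=42)   # 8 parents, 28 crosses,
obs = simulate.simulate_diallel_trial(cfg)       # 2 loc x 3 dens x 3 reps
design = cfg.design()

tab = anova.combined_anova(obs, design, "GYPP")
print(tab.table[["source", "df", "MS", "F", "sig"]].head(8).to_string(index=False))
```

```
       source  df           MS          F sig
Locations (L)   1 11626.493665 129.852743  **
       Rep(L)   4    89.535988        NaN
Densities (D)   2 62067.498455 811.824144  **
        L x D   2   289.520147   3.786836
      Error a   8    76.454364        NaN
  Hybrids (H)  27  3522.161632  84.180406  **
          GCA   7 11328.512242 270.753831  **
          SCA  20   789.938918  18.879707  **
```

The df column is the canonical 504-plot layout (27 hybrid df split 7 GCA
+ 20 SCA; Error b carries 324 df). `tab.gca_sca_ratio` (here 14.34 —
this simulation draws strong additive effects) is the MS_GCA/MS_SCA
ratio breeders read as the additive/non-additive balance.

Per-density combining-ability effects with tests and LSDs:

```python
err = tab.row("Error b")
et = griffing.effect_table(obs, design, "GYPP", density="D1",
                           ms_error=err.MS, df_error=int(err.df))
print(et.gca_frame().round(2))      # g_i with stars; et.sca for s_ij
print(round(et.lsd_gca[0.05], 2))   # 3.0 -> LSD for comparing two g_i
```

Marker side, on the bundled reference distance matrix of eight inbred
lines (four local, four exotic):

```python
d = datasets.reference_distance_matrix()
s = ssr.summarize_distances(d)       # min 0.31 (L1,L4), max 0.78, mean 0.6164
tree = ssr.upgma(d)
ssr.depth1_leafsets(tree)            # {L1..L4} | {L5..L8}: clusters by origin
```

A command-line interface wraps the same functions
(`diallelkit simulate | validate | anova | diallel | summarize | ssr |
correlate | report`); `diallelkit report --input plots.csv --panel
markers.csv --out-dir out/` writes the full bundle of ANOVA, effect,
summary, marker and correlation tables.

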