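# Methods

## Scope and data model

The package analyses half-diallel trials: `n` inbred parents, all
`n(n-1)/2` unordered crosses (Griffing's Method 4 — no selfs, no
reciprocals), evaluated in a split-plot RCBD with plant densities on main
plots and hybrids on sub-plots, replicated within each of several
locations. Plot observations live in a tidy DataFrame (one row per plot
per trait) with a closed 12-trait vocabulary covering phenology (DTS,
ASI), architecture (PLHT, EHT, LANG), physiology (CHLC) and yield
components (ED, NRPE, NKPR, TKW, GYPP, GYPH). Cross identity is the
sorted parent pair; commercial check hybrids are carried through
summaries but never enter the diallel arithmetic (a complete diallel's
hybrid df would otherwise not be `n(n-1)/2 - 1`).

All closed forms assume a balanced complete design. Unbalanced data are
rejected, not approximated: there is deliberately no Type-III or
missing-plot machinery, because every formula in the chain (marginal-mean
sums of squares, Griffing totals, coefficient-propagation SEs) is exact
only under balance.

## Combined split-plot ANOVA

Sums of squares are sums of squared marginal means times their
replication factor; Error b is the residual. The df layout for the
standard 8-parent, 2-location, 3-density, 3-rep trial is
L 1, Rep(L) 4, D 2, L×D 2, Error a 8, H 27 (= GCA 7 + SCA 20), H×L 27,
H×D 54, H×L×D 54, Error b 324; total 503.

Denominator conventions: Locations are fixed and tested against Rep(L)
(the classical combined analysis admits either Rep(L) or Error a; the
choice is a documented convention here, and only affects the Locations
row). Densities and L×D test against Error a (the main-plot error, the
L×Rep×D residual); every hybrid-containing source tests against Error b.
Stars use the `*`/`**` vocabulary at 0.05/0.01; full p-values are always
reported alongside.

Before combining locations, Bartlett's test on the per-location sub-plot
error variances gates the combined analysis (at α = 0.05 by default).
The test is computed from summary statistics — (variance, df) pairs —
since per-location mean squares are what the workflow retains; it agrees
with a raw-data Bartlett test exactly. The gate's verdict is logged, not
enforced: heterogeneity produces a warning, matching the practice of
reporting the combined analysis with a caveat.

## Griffing Method 4, Model I

Effects use the closed-form estimators (see README for the formulas);
the implementation is validated in the test suite against an independent
constrained least-squares fit of the saturated model for n = 3..8.
Model II (random-effects variance components) is out of scope: the
GCA/SCA ratio is implemented as MS_GCA/MS_SCA exactly as the combined
ANOVA table computes it.

Effects are presented per density level on means across locations ×
replicates (r_basis = 6 in the standard trial), which is the standard
multi-density presentation. Their significance tests use the Error b
mean square and df from the combined ANOVA of the full trial: the cell
variance entering every SE is `MS_error_b / r_basis`.

Standard errors come from exact coefficient propagation rather than
transcribed textbook constants: each effect is a fixed linear
combination of the cross means, so its variance is
`sum(coef^2) * MS_error / r`. This reproduces the classical closed forms
(e.g. `Var(g_i) = (n-1) MS / (n(n-2) r)`) and is immune to
formula-edition discrepancies; it is checked against a Monte-Carlo
simulation oracle to 2%. For SCA differences both variants are provided:
crosses sharing one parent and disjoint crosses. The LSD for SCA
comparisons uses the disjoint-pair SE (the more common table-wide
comparison); the shared-parent SE is exposed as
`EffectSE.se_sca_diff_shared`.

## Density response and summaries

`Change% = 100 (mean_D - mean_D1) / mean_D1` is computed from per-density
means over all crosses, locations and replicates — not per-plot
weighting, which under balance is identical anyway. Extremes use a
lexicographic tie-break on the sorted parent pair; the per-cross optimum
density is the argmax of GYPH with exact ties resolved to the denser
planting (equal yield at higher population is operationally preferable).
Check comparisons classify the signed difference against LSD thresholds
at 0.05/0.01.

## SSR diversity and clustering

Inbred lines are homozygous, so allele frequencies are exact multiples
of `1/n_lines` and are always computed from counts. Gene diversity is
`1 - sum p^2`; PIC is Botstein's
`1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2` (so PIC ≤ gene diversity, with
equality only for monomorphic loci — property-tested over random simplex
draws). Distances are Jaccard on the binary band expansion (joint
absences ignored); Dice is available as an option. UPGMA uses the
standard size-weighted average-linkage recurrence with merge height
`d/2` and a deterministic lexicographic tie-break on the smallest member
label, so dendrograms and their Newick serializations are reproducible
byte for byte; the implementation is cross-checked against
scipy's average-linkage clustering on tie-free matrices.

The bundled reference data (an eight-line panel: four local, four exotic
inbreds) include per-locus allele counts reconstructed from printed
marker statistics. Where a printed major-allele frequency admitted
several count splits, the split was chosen to also reproduce the printed
gene diversity — e.g. three-allele loci with major count 4/8 must be
(4, 3, 1), since (4, 2, 2) gives 0.625 rather than the printed 0.59.

## Correlation analysis

Per trait, Pearson correlations over the crosses relate parental genetic
distance, mean F1 performance and SCA. "Across all environments" is
implemented as: F1 mean per cross averaged over every
location × density × replicate cell, and SCA per cross averaged over the
per-density effect tables. Per-environment pooling is available by
passing a different set of effect tables. p-values use the exact t
transform with n-2 df; report formatting marks significance at 0.01
only, following the convention for this table.

## Synthetic-data generator

The trial generator is the generative twin of the ANOVA model:

```
y = mu + L + R(L) + D + LD + e_a(l, r, d)
    + g_i + g_j + s_ij + hL + hD + hLD + e_b
```

with `e_a` shared by all sub-plots of a main plot (the whole-plot unit
is location × replicate × density) and `e_b` independent per plot.
Random interaction effects are drawn as independent normals and centered
within their constraint groups (double/triple centering; the SCA draw is
projected onto the zero-row-sum space by the exact closed-form
projection), so realized effects satisfy the estimability constraints
exactly and zero-noise recovery tests are exact rather than asymptotic.
A single integer seed drives every stream via `numpy.random.SeedSequence`
spawning, giving bit-identical reproduction across platforms.

Default conditions (`make_standard_config`): 8 parents, 28 crosses,
2 locations × 3 densities × 3 replicates (504 plots per trait), on a
grain-yield-per-plant scale — grand mean 153 g, density effects
(+17, +1, −18) g mimicking the characteristic per-plant yield decline
under denser planting, GCA SD 10 g, SCA SD 8 g, sub-plot error SD 6.7 g
and interaction SDs back-solved approximately from the expected-mean-
square identities of a combined analysis at this scale. No
variance-component estimates were published for this design, so these
defaults are illustrative of a realistic yield trait rather than fitted.

The marker generator draws one allele per line per locus; each origin
group leans on its own anchor allele with probability `divergence`
(default 0.8 over 10 loci with 2–6 alleles), otherwise a uniform allele.
At divergence 0 there is no group structure; at 1 the groups carry
private anchors and between-group Jaccard distance is 1 at polymorphic
loci.

What the generator does *not* emulate: spatial field trend, genotype
competition between neighbouring plots, trait-trait correlations,
heteroscedastic errors, missing plots, marker linkage or residual
heterozygosity. Passing tests therefore demonstrate estimator
correctness under the model the classical analysis assumes, not
robustness to field artefacts the analysis itself does not model.

## Numerical conventions and problem sizes

- Internal precision is full double; half-up rounding to 2 decimals is
  applied only at report serialization (`round_half_up`), matching how
  printed tables round 0.375 → 0.38.
- Tiny negative SS from interaction-partition subtraction (round-off
  below 1e-9 relative) are clamped to zero.
- Monte-Carlo checks in the test suite use 1000 null replicates for the
  hybrids F-test calibration, 200 replicates per design size for the
  RMSE ∝ 1/√r scaling, 10,000 draws for the SE oracle and 100 seeded
  panels for cluster recovery — sizes at which the binomial/χ² tolerances
  quoted in the tests are ≥ 4 standard errors.
- Degenerate inputs fail loudly: n < 3 parents (Method 4 undefined),
  non-positive variances in Bartlett's test, zero baseline in Change%,
  all-zero band rows in Jaccard, zero-variance vectors in Pearson.

## Known limitations

- Balanced complete data only; no mixed models, no missing-plot
  recovery.
- Model I (fixed parents) only; no Model II variance components, no
  Hayman graphical analysis, no heterosis estimation.
- The homogeneity gate warns rather than blocks, and only Bartlett's
  test is offered.
- UPGMA is the only clustering method; for very small panels the binary
  root split is reported as-is (a two-group interpretation is a reading
  of the tree, not a statistical test).
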