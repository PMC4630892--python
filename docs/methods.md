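# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of `xbreed`.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Relationship matrices

**Pedigree (A).** The numerator relationship matrix is built by the
tabular method, `a_ij = ½(a_{j,sire(i)} + a_{j,dam(i)})`, diagonal
`1 + ½ a_{sire,dam}`, in topological order. Ancestors beyond
`max_ancestor_generations` (default 3, matching evaluations that trace
a fixed number of ancestor generations) above every subject are treated
as unknown founders. Disconnected pedigree components — the two breeds
— are detected by union–find and computed as separate blocks, since
their cross-relationships are structurally zero; this also keeps the
O(n²) tabular pass off structurally-zero memory. Inbreeding is carried
exactly by the recursion.

**Genomic (G).** VanRaden's first method with identity blending:
`G = b·ZZᵀ/(2Σp(1−p)) + (1−b)·I` with blend `b = 0.95`, where Z holds
0/1/2 codes column-centred by `2p_i`. The default allele frequencies
are computed on the *combined across-breed* animal set; within-breed
frequencies are available via the `frequencies` argument. The identity
blend bounds the smallest eigenvalue at `1−b`, so every G is
invertible; a principal submatrix (e.g. cows only) inherits the bound.
Monomorphic markers are dropped with a logged count; missing genotypes
are mean-imputed (centred contribution zero) — the denominator is
unaffected. These two choices are our own defaults where the field is
silent; both are the conventional neutral ones.

## The REML engine

All variance-component models have the form
`y = Xb + Σ_k Z_k u_k + e`, `u_k ~ N(0, Γ_k ⊗ K_k)`, with a diagonal
per-trait residual. Trait-covariance blocks are either `full` or
`diagonal` (cross-trait covariance structurally zero — used for the
pedigree term across breeds, which share no ancestors). Records map to
exactly one trait; the observation covariance V is assembled densely,
which is the right trade-off for the intended n ≤ ~4,000.

*Algorithm.* Average-information REML on V: gradient
`−½(tr(P B_m) − yᵀP B_m P y)` and AI matrix `½ w_mᵀ P w_l` with
`w_m = B_m P y`, where `B_m = ∂V/∂θ_m` decomposes into trait-pair
blocks of each `K_k`. The AI step is tried with step halving
(1 … 1/32); any step that would lower the restricted log-likelihood is
discarded in favour of an **exact EM update**
(`Γ ← Γ + Γ(F−W)Γ/q` with `F_st = yᵀP B_st P y`, `W_st = tr(P B_st)`,
`q` the number of levels), which cannot decrease the restricted
likelihood — so the reported log-likelihood trace is non-decreasing,
and the tests assert it on every fit.

*Constraints.* Variances are floored at `1e−6 ×` the per-trait
phenotypic variance; full blocks are kept positive semidefinite by
eigenvalue clipping. We deliberately do **not** cap the cross-trait
covariance element-wise: projecting the whole block onto the PSD cone
moves variances and covariance jointly, so boundary solutions with
|correlation| = 1 are reached cleanly instead of being approached by
ever-smaller steps along a moving cap (an element-wise cap was tried
and interacts badly with the AI direction). A floored parameter whose
gradient points outward is removed from the AI solve (active set).

*Convergence.* Relative restricted-log-likelihood change < 1e−8 and
parameter change < 1e−6 (×phenotypic-variance scale), capped at 200
iterations; additionally, five consecutive iterations with negligible
likelihood gain count as converged, because a boundary solution can
keep drifting along a flat ridge in vanishing increments.
Non-convergence is flagged on the returned object and warned, never
silent. Starting values split half the phenotypic variance equally
among the random terms, cross-covariances at zero. Standard errors come
from the inverse AI matrix at convergence and are flagged approximate.

*Solutions.* `solve_mme` computes BLUEs/BLUPs through the equivalent
GLS identities (`β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`, `û_k = (Γ_k⊗K_k)Z_kᵀPy`),
verified in the tests against a hand-assembled Henderson system.
Fixed-effect identifiability uses drop-first coding (first level of
every factor constrained to zero), with aliased columns removed by
pivoted QR, so BLUEs are reproducible; records with masked (missing)
responses are excluded from estimation but predicted through their
relationships.

*Derived parameters.* `r_G = σ_u,BT/√(σ²_u,B σ²_u,T)` (undefined —
NaN with a warning — if either variance sits at the floor) and
`C_miss = 1 − σ²_u/(σ²_u+σ²_a)` per breed, also expressible as
`h²_P/(h²_P+h²_G)`, which is the identity used to check the published
tables' internal consistency.

## GWAS

Each marker is tested as a fixed 0/1/2 covariate in a uni-variate
animal model with the full fixed-effect set and a pedigree polygenic
term. The default mode is the standard two-stage approximation: the
null variance components are estimated once — by an exact spectral
profile REML (one eigendecomposition of A; the restricted likelihood
profiles to a 1-D function of the heritability ratio, maximised by
bounded search; it agrees with the generic engine to ~7 significant
digits in the tests) — and every SNP is then scored by GLS on the
whitened data with a Wald t-test. An `exact` mode refits REML per SNP
and reports a likelihood-ratio p-value; fast and exact agree in effect
sign on ≥99 % of markers in the tests. Within-subset monomorphic
markers are flagged and excluded from ranking. No multiple-testing
correction is applied: downstream selection takes a fixed fraction, so
only the ordering matters.

## SNP selection

For each trait, markers whose estimated effects have the same
(opposite) sign in the two breeds are ranked by the **sum of −log₁₀ p
over the two breeds** and the top `⌈0.10 × panel⌉` are kept — the quota
counts against the full panel, matching the published 7,173 = 10 % of
71,726 even though fewer markers sign-qualify. The joint ranking rule
is our choice where the source procedure says only "most significant in
both breeds"; `min_p` and `max_p` alternatives are selectable, and
Fisher's combination would order identically to the default. Exact zero
effects carry no direction and are excluded. Per-direction lists are
unioned over traits; markers in both unions are removed from both
(logged); ties break by summed |Wald statistic| then marker id, so
selection is order-independent. `G_S`/`G_D` are then ordinary blended
GRMs restricted to each list, with across-breed frequencies.

## Prediction and validation

GBLUP uses the merged two-breed, two-sex data with a single genomic
random term (no pedigree term, mirroring the prediction-model
specification). For each scheme, phenotypes outside the calibration
cell (cows of one breed) are masked *before* variance components are
re-estimated; schemes sharing a calibration cell share the fit. GEBVs
for every animal in the GRM come from the genomic BLUP. The no-leakage
property (perturbing a masked phenotype changes nothing) is asserted in
the tests.

Adjusted phenotypes subtract the fixed-effect BLUEs from per-breed
two-sex bi-variate pedigree fits (sex as trait), the package's
reduction of the source study's 10-variate within-breed analyses: the
engine is exercised at the same structure — two correlated responses,
one relationship matrix — without estimating a 55-parameter covariance
(our single simulated trait makes the reduction exact in spirit; with
five traits it is an approximation). Records with factor levels unseen
in the within-breed fit are dropped with a logged count. Accuracy =
Pearson correlation(GEBV, adjusted phenotype) over validation animals;
bias = OLS slope of adjusted phenotype **on** GEBV (1 = unbiased;
deliberately not the inverse regression). `Average` rows are plain
arithmetic means of the per-trait cells.

## Synthetic data

The generator emulates the structure the estimators assume, with
ground truth recorded for recovery tests.

* **Pedigree:** per breed, founder sires and dams; calibration cows are
  daughters of founder matings; each validation bull is the son of a
  calibration cow (litter limit 4, as in the motivating design where
  cows averaged ~1.5 sons). The same founder sire pool serves both
  offspring generations — a simplification; the real design used
  disjoint sire sets.
* **Genotypes:** independent biallelic loci. Ancestral frequencies
  U(0.1, 0.9); breed frequencies from the Balding–Nichols model with
  divergence `fst_divergence` (default 0.10, giving cross-breed G
  entries with spread comparable to a few percent — the "hidden
  relationship" the method exploits); founders Hardy–Weinberg;
  descendants by Mendelian gene drop.
* **Effects and phenotypes:** `n_qtl` panel markers get
  allele-substitution effects drawn from a zero-mean normal with
  correlation `rho_qtl` across breeds and `rg_sexes` across sexes
  (Kronecker of the two 2×2 correlation matrices). A pedigree-sampled
  polygenic component (founders ~ N(0,Σ), offspring = parent average +
  Mendelian deviate) carries `h2_polygenic`; components are rescaled so
  marked and polygenic fractions hit their targets over phenotyped
  animals of each breed (phenotypic variance 1). Fixed effects:
  breed-specific contemporary groups (10 levels, sd 0.5), age-of-dam
  classes (4, sd 0.2) and a uniform breed-composition covariate (slope
  0.3). Residual takes the remainder; a configuration whose fractions
  exceed 1 is rejected.
* **Defaults** are desk-scale: 800 calibration cows + 800 validation
  bulls per breed, 5,000 SNPs, 500 QTL, `h2_marked = 0.4`,
  `h2_polygenic = 0.2` (total h² 0.6, one third pedigree-only),
  `rho_qtl = 0.8`, `rg_sexes = 0.9` — magnitudes chosen to match the
  moderate-to-high heritabilities and near-unity sex correlations of
  the motivating tropical-cattle traits.
* Identical seed + config gives bit-identical output; the three
  generator stages draw from independent child streams of the seed.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: linkage disequilibrium and recombination
(markers are independent; cross-breed LD-phase consistency is emulated
*directly* through `rho_qtl` rather than through shared haplotypes),
genotyping and imputation error, selection in the pedigree,
breed-composition structure within a "composite" population, and
multi-trait genetic architecture (one trait; the five-trait list merge
is exercised with synthetic GWAS tables instead).

## Problem sizes used in the tests

Chosen so each check measures what it claims at the smallest scale
that is statistically meaningful:

* r_G parameter recovery: 20 replicates × rho ∈ {0, 0.8} at 800
  cows/breed and 5,000 SNPs (the generator's default study scale).
* Qualitative orderings (r̂_G and accuracy under G_W/G_S/G_D): 20
  replicate full-pipeline runs at 400 cows + 200 bulls per breed,
  3,000 SNPs, 300 QTL, `h2_marked = 0.5`.
* Planted-QTL enrichment of the same-direction list: 200 equal-sized,
  fully sign-consistent QTL (joint variance 0.65) among 5,000 markers
  at 2,400 cows per breed over 150 sire families — sized so each QTL
  carries per-breed non-centrality ≈ 2, the regime in which "large
  effects" is true and ≥80 % recovery is the expected behaviour; with
  normally-drawn effects half the QTL are individually weak and no
  sample size makes them all selectable.
* GWAS calibration: one 5,000-marker scan on permuted phenotypes at
  800 cows (binomial SE ≈ 0.003 around 0.05); planted single-QTL
  recovery over 20 small replicates.
* Oracle checks (tabular NRM recursion, hand-computed GRM, profile
  restricted-likelihood grid at n = 200, hand-built Henderson system)
  are exact or at stated tolerances.

`scripts/acceptance.py` uses 5 pipeline replicates and 5 recovery
replicates at the same per-replicate sizes.

## Known limitations

* The sampling error of r̂_G at the default study scale is large:
  information about the cross-breed genomic covariance comes from the
  cross-breed block of G, whose entries have spread ~1/√m, giving
  Fisher information ∝ n_B·n_T/m. At 800 cows/breed and 5,000 markers
  the per-replicate standard error is around 0.2, so individual
  estimates at high true correlation pile up on the |r| = 1 boundary
  and a ratio-of-noisy-variances inflation appears. This is a property
  of the design, not the estimator (the grid-oracle and nesting checks
  pass, and the pseudo-true projection of the covariance equals the
  generating value); larger samples or denser cross-breed relationships
  shrink it.
* Element-wise standard errors from the AI matrix are asymptotic and
  unreliable at boundaries; none are reported for r_G or C_miss.
* The GWAS fast mode fixes null components across markers (two-stage
  approximation); per-marker refits are available but O(#SNP) REML
  fits.
* Dense algebra throughout: memory is O(n²) per relationship matrix
  and the REML cost O(n³) per iteration; beyond ~5,000 animals a
  sparse-NRM/mixed-model-equation formulation would be the right tool.
* PLINK I/O is text (.ped/.map) plus a delimited dialect; binary .bed
  is not read or written.
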