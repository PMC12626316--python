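# Methods

This note documents the statistical models and conventions implemented in
`teadiv`, the choices made where the workflow is conventionally
underspecified, and what the synthetic-data generator does and does not
emulate.

## Phenotypic diversity

Descriptive traits are ordinal integer codes from the tea germplasm
descriptor standard (e.g. tree type: 1 shrub, 2 small tree, 3 arbor). Two
statistics summarise each trait over the accessions:

- **Shannon–Weaver index** H′ = −Σ Pᵢ ln Pᵢ (natural log, nats), where Pᵢ
  is the observed proportion of category i; 0·ln 0 ≡ 0. H′ is 0 for a
  monomorphic trait and ln k for k equally frequent categories.
- **Coefficient of variation** CV = 100 · s/x̄ with the sample SD
  (n−1 denominator), computed **on the ordinal codes themselves**. This is
  the convention that reproduces the reference survey's printed CVs (e.g.
  tree type 15.76% from 35×code 2 + 5×code 3) and only holds with the n−1
  SD; both choices are therefore pinned.

Quantitative traits (leaf length, width, length/width, leaf area = length ×
width × 0.7) are graded into ordinal classes before H′ is computed: with
the default 10 classes, class 1 collects x < mean − 2 SD, class 10 collects
x ≥ mean + 2 SD, and the 8 interior classes are each 0.5 SD wide. The
grading convention in the literature is cited by author name only and
varies; the printed quantitative H′ values (1.70–1.93) are treated as soft
references, not exact targets. With zero SD every value falls in the
central class and a warning is raised.

For clustering, all traits (codes included) are standardized to z-scores
(mean 0, sample SD 1; zero-SD traits dropped with a warning), pairwise
Euclidean distances are computed, and accessions are clustered by average
linkage through the shared UPGMA engine. The source names only a generic
"system clustering method"; average linkage was chosen for consistency with
the population-level trees and is the only linkage exposed.

### Inconsistent printed rows

Several printed descriptive-trait rows are internally inconsistent: the
printed H′ or CV cannot be recomputed from the row's own printed frequency
distribution (e.g. a four-category 37.5/37.5/12.5/12.5 distribution implies
H′ = 1.26, printed 1.00; two rows share a distribution but print different
statistics). The bundled table carries per-row `cv_consistent` /
`h_consistent` flags (6 rows are consistent on both counts, 13 on CV, 11 on
H′); the formulas are reproduced, not the misprints, and checks cover only
the consistent rows. Similarly, the printed per-accession leaf-width column
is corrupted (its mean is 3.51, printed 3.61; one value is 0.94 amid a
population of ~2.6–2.9): the repaired cells are documented in
`teadiv.datasets`, S34's width is retained but flagged suspect, and
leaf width is excluded from exact checks.

## Marker diversity statistics

All statistics derive from per-locus allele frequencies estimated by
counting allele copies (2 per non-missing call). Missing data policy is
per-locus deletion: an individual missing at a locus is dropped from that
locus only, never from the whole analysis.

- Na — observed allele count; Ne = 1/Σp² — effective allele count;
  I = −Σp ln p (natural log).
- Ho — fraction of non-missing calls with two distinct labels.
- He = 1 − Σp², the "biased" form that matches the GenAlEx convention the
  reference tables come from; the unbiased 2n/(2n−1) correction is an
  explicit option, off by default.
- F = 1 − Ho/He, computed from unrounded Ho and He (recomputing from the
  printed 2-dp values gives slightly different numbers; those are not used
  as targets). Undefined (None) when He = 0.
- PIC = 1 − Σpᵢ² − Σ_{i<j} 2 pᵢ² pⱼ² (Botstein form). The identities
  PIC ≤ He ≤ 1 − 1/Na and Ne ≤ Na (equality iff uniform) hold for every
  frequency vector and are property-tested.

Per-population summaries average Na, Ne, I, Ho, He across loci; the
"percent of effective alleles" column is 100 · mean(Ne)/mean(Na) on the
unrounded means.

## AMOVA, Fst and gene flow

The AMOVA is the standard three-level decomposition for diploid codominant
data with the 0/1 allele-mismatch distance summed over loci (no stepwise
mutation model — appropriate when allele labels are fragment sizes and no
mutational ordering is assumed). Sums of squares use the group form
SS = (1/n)Σ_{i<j} d_ij over allele copies, computed per locus and summed;
degrees of freedom are k−1, N−k and N for N individuals in k populations
(totalling 2N−1). Variance components follow the moment equations
σ²_c = MS_WI, σ²_b = (MS_AI − MS_WI)/2, σ²_a = (MS_AP − MS_AI)/(2n₀) with
n₀ = (N − Σnᵢ²/N)/(k−1). Negative components are truncated to zero for
percentages and F-statistics (standard practice; raw values are retained
and a warning is raised). Fst = σ²_a/Σσ², so overall Fst equals the
among-population percentage/100 by construction. A published AMOVA table
of this design labels its third stratum "among individuals" with df 40;
arithmetically that is the within-individual stratum of this decomposition
and it is stored under that name.

Pairwise Fst runs the two-population AMOVA for each pair, truncating
negative estimates to zero. Gene flow uses the island-model identity
Nm = (1 − Fst)/(4 Fst); Fst ≤ 0 maps to an infinite-flow sentinel with a
warning and Fst ≥ 1 to 0. Because Nm is steep in Fst near zero, checks
against published Nm values compare to the Nm interval induced by the 2-dp
rounding interval of the published Fst.

Nei's (1972) standard distance D = −ln(J_XY/√(J_X·J_Y)) uses identity sums
averaged over loci, excluding loci with no data in either population
pairwise; J_XY = 0 maps to +∞ with a warning. The distance choice is a
convention (the source names only the software used); Nei 1972 is the
default.

Individual-level genetic distance is allele sharing,
1 − shared/(2·loci compared), counting shared alleles with multiplicity
over pairwise non-missing loci. The metric behind the published
individual-level dendrogram is not stated, so individual-level results are
treated as illustrative, not as reproduction targets.

## UPGMA convention

Merge height = half the average inter-cluster distance, so "cutting the
dendrogram at genetic distance x" means cutting at height x. This is
pinned by the published worked example: the closest population pair at
distance 0.24 joins at 0.12, and the narrative thresholds 0.12/0.17/0.20
then reproduce exactly. New-to-old cluster distances are size-weighted
averages (i.e. plain averages over leaf pairs — the "unweighted" in UPGMA).
Ties break on the lexicographically smallest pair of cluster
representatives (smallest member label), making the merge list invariant
to input order. Heights are provably monotone under average linkage and
asserted. The cophenetic matrix doubles merge heights back to the distance
scale; on an already-ultrametric input, UPGMA then cophenetic is the
identity (tested as a fixed point).

## Admixture model and ΔK

The sampler implements the admixture model with independent allele
frequencies: each allele copy of individual i carries a latent origin z ~
Categorical(qᵢ); given z = k the allele is drawn from that cluster's
frequency vector at the locus. Priors are Dirichlet(λ=1) on each cluster ×
locus frequency vector and Dirichlet(α=1) on each ancestry vector qᵢ. α is
held fixed — no Metropolis update of the ancestry concentration — because
ΔK-based selection of the cluster number does not require it; this is a
deliberate simplification relative to the full reference implementation of
the model. Gibbs updates cycle z | q,P → q | z → P | z; Q and P are
reported as posterior means over retained sweeps, and the model evidence is
summarised as lnPD = mean(lnL) − var(lnL)/2 (sample variance), the standard
estimator the ΔK statistic was designed around. It is exact only for
Gaussian lnL; on a one-locus toy its offset from the closed-form
Dirichlet-multinomial evidence is under half a nat, which is the tolerance
used in tests. For K = 1 the ancestry vectors are degenerate and every Q
entry is exactly 1.

Evanno's ΔK: per replicate r, L″ᵣ(K) = Lᵣ(K+1) − 2Lᵣ(K) + Lᵣ(K−1); ΔK(K) is
the mean of |L″ᵣ(K)| across replicates divided by the SD of L(K) across
replicates, defined for 2 ≤ K ≤ Kmax−1; zero SD yields an infinite
sentinel with a warning. The optimal K is the argmax. Replicate seeds
derive deterministically from one master seed; identical seeds give
bit-identical runs.

Membership classification assigns each individual to its argmax cluster and
flags it "admixed/complex" when max Q < 0.6, the threshold convention used
for interpreting Q in this literature. Label switching is handled only at
evaluation time by greedy cluster matching; lnPD is label-invariant.

Default run lengths are desk-scale (20 000 sweeps, 5 000 burn-in, 10
replicates, Kmax 5); the reference survey's heavier settings (100 000 /
10 000 / 20 replicates / Kmax 10) are reachable through the same
parameters. The ΔK recovery checks use further-reduced settings (600
sweeps, 150 burn-in, 4 replicates, Kmax 4) — at 14 multi-allelic loci and
Fst 0.2 the evidence gap between K = 1 and K = 2 is large and these
settings select the true K in 10/10 independent experiments.

## Mantel test

r is the Pearson correlation of the strictly-lower-triangle entries of two
label-aligned distance matrices; the one-tailed p-value is
(#{r_perm ≥ r_obs} + 1)/(n_perm + 1) under simultaneous row/column
permutation of the second matrix, with a seeded generator (default 9 999
permutations; the source states none). The implementation is cross-checked
against scikit-bio's `mantel` and against exhaustive enumeration of all 24
permutations of a 4×4 input; under the null its p-values are uniform on
(0,1].

## Synthetic-data generator

Subpopulation allele frequencies follow the Balding–Nichols construction:
ancestral frequencies from a flat Dirichlet, cluster frequencies from
Dirichlet(p_anc · (1 − F)/F), so F is exactly the expected Fst — the moment
identity Var(p) = p(1−p)F is tested directly. Genotypes are drawn
Hardy–Weinberg within population; admixed individuals draw each copy's
cluster of origin from their q vector first. Uniform missingness is the
only genotyping-error model.

The study-like bundle mirrors the reference survey's design: 40 accessions
in 7 populations of sizes (5,5,10,5,5,5,5), 14 loci with 4–15 alleles, two
ancestral clusters with the first population drawn alone from the minor
cluster (the divergent-outlier pattern). Differentiation is two-level:
cluster divergence F = 0.35 and a within-cluster level F = 0.08 that gives
each population its own frequencies around its cluster's. These two values
were calibrated once so the AMOVA among-population share is ≈20%
(19.8 ± 2.9% over 14 seeds), the survey-scale differentiation the design
targets, and are fixed.

Phenotypes are population-correlated through the same cluster structure.
Quantitative leaf dimensions are **lognormal** (multiplicative noise,
medians 9.5 cm length / 3.2 cm width, log-SDs 0.22/0.20) with the cluster
offset applied on the log scale in SD units; the ratio and area are then
derived exactly as the descriptor standard prescribes (area = length ×
width × 0.7). Lognormal is the usual morphometric model and keeps the
derived ratio well-behaved — an additive Gaussian model produces
near-zero widths and heavy-tailed ratios that dominate Euclidean distances.
Descriptive traits are ordinal codes obtained by discretizing a latent
standard Gaussian with a cluster mean offset (`descriptive_effect`, SD
units): descriptor codes are ordinal scores, and divergent populations
shift along them systematically. Zero effect sizes make phenotypes
independent of genotypes (the null for the Mantel test); 3-SD offsets make
the planted clusters fully recoverable by phenotype clustering.

What the generator does **not** emulate: SSR mutation (no stepwise model —
allele labels are arbitrary sizes, consistent with the mismatch-distance
AMOVA), linkage between loci, genotyping error beyond uniform missingness,
environmental covariance among traits, and measurement replication. Tests
that pass on this generator therefore demonstrate estimator correctness
under the stated model, not robustness to those real-data features.

## Numerical conventions

- Distance matrices must be symmetric within 1e-12 with an exactly zero
  diagonal; they are re-symmetrized on construction.
- Frequency vectors must sum to 1 within 1e-9; Q rows and P vectors are
  renormalized draws and sum to 1 by construction at every sweep.
- Genotypes are unordered pairs stored sorted; allele labels are positive
  integers and identity is exact label equality.
- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  replicate seeds derive from a master `SeedSequence`. Reruns with the
  same seed are byte-identical, including every pipeline artifact.
- Report tables render floats at 2 decimals as the reference tables do;
  full-precision sidecars (`*.full.tsv`) are written alongside.

## Problem sizes used in checks

The test suite and acceptance checks run at deliberately modest sizes
chosen as sufficient for each property: Hardy–Weinberg F at 500 individuals
× 20 loci; Fst recovery at 50/population × 14 loci against a 1 500/
population realization of the same frequencies; ΔK recovery over 10
independent 40×14 surveys at the reduced MCMC settings above; Mantel null
uniformity over 200 datasets at 199 permutations. The whole suite runs in
about a minute on one CPU.

## Known limitations

- The admixture sampler omits the α update and the correlated-frequencies
  prior; on very weakly differentiated data the fixed-α model selects K
  more conservatively than the full model.
- lnPD is a heuristic evidence summary; it is used comparatively (ΔK), not
  as a calibrated marginal likelihood.
- AMOVA significance is not assessed by permutation (none is reported in
  the reference workflow); no hierarchical (region) level is implemented.
- The individual-level distance choice is not identifiable from the
  reference tables; population-level quantities should be preferred for
  comparisons.
- Printed-table reproduction is limited to internally consistent rows; the
  genotype-derived tables (per-locus Ho/He, population distances, Fst/Nm,
  AMOVA components) cannot be recomputed without the raw genotypes and are
  bundled as fixtures for arithmetic and layout checks only.
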