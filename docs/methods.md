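# Methods

This note records the models implemented in `plustree`, the assumptions they
make, the defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## The study design being modeled

The package targets cohorts of *unrelated* plus trees: phenotypically
superior founders selected from natural or artificial forests, clonally
archived, and evaluated through vegetative copies (ramets) across field
trials. Three features dominate the statistics: (1) no pedigree — all
relationship information comes from markers; (2) rapid linkage
disequilibrium decay within a few centimorgans, since the populations are
essentially undomesticated; (3) clonal replication, which makes the
genotype-level "clonal value" (total genetic value, not just breeding value)
estimable from trial records.

## Synthetic cohorts

**Ancestral frequencies.** K cluster frequency vectors are drawn
Balding–Nichols style: per SNP a base frequency p ~ Uniform(0.1, 0.9), then
each cluster draws Beta(p(1−F)/F, (1−p)(1−F)/F). F (`divergence`) is an
F_ST-scale knob: at F = 0.2 the realized mean pairwise Hudson F_ST of the
simulated clusters is 0.2 within sampling error (tested). Frequencies are
clipped to (0.02, 0.98) so no cluster is fixed.

**Genotypes.** Each genotype samples an admixture row Q from its
population's Dirichlet; each of its two haplotypes is a mosaic of ancestral
segments with exponential lengths (mean `recombination_block_cM`), cluster
labels i.i.d. from Q, and alleles drawn from the segment cluster's
frequencies. This *admixture-LD* mechanism was chosen over coalescent
simulation deliberately: it is desk-scale, produces the observed
map-distance decay directly, and lets per-population block lengths create
the "one population holds LD longer" pattern. Two consequences matter for
interpreting tests: LD decays to a nonzero genome-wide baseline (mixture LD
from Q variation), so decay-monotonicity holds over the first few block
lengths, not out to the plateau; and a genotype's realized ancestry
fractions converge to its Q row only as the *segment* count grows — with
1 cM blocks on an 11 × 120 cM map the mean L1 gap is below 0.05.

**Defaults** mirror a three-population cedar-breeding cohort: populations of
181/159/136 genotypes, K = 4 clusters, two broadly admixed populations
sharing a cluster palette and a third, less admixed one with longer blocks
(5/5/8 cM), 6,455 mapped SNPs on 11 linkage groups of 120 cM (≈1,300 cM
total, the right order for a conifer map), divergence 0.1, 2% missing calls.
Unmapped SNPs are generated as per-genotype noisy copies (2% score
re-draws) of random mapped SNPs, so the r² > 0.6 placement rule has known
truth. The default 200 unmapped SNPs exist to exercise that rule, not to
mirror an array's full unmapped content.

**Traits.** Additive values are Σ score × effect over `n_qtl` QTL SNPs
(Gaussian or geometric-decay effects); an optional heterozygote-deviation
term is rescaled so a requested fraction of genetic variance is
non-additive; genetic values are standardized. Trial records add
N(0, σ²) site, block-in-site, genotype-by-site and residual effects to the
genetic value for each genotype × block at the sites where the genotype is
planted (a fraction-based overlapping-incidence rule is available).

## Quality control and imputation

Filters run in a fixed order — monomorphic, then missing rate > 0.5, then
pooled-cohort MAF < 0.05 — because the surviving-count bookkeeping is
order-dependent; MAF is computed once on the pooled cohort, before any
per-population split. Imputation is relationship-based and iterative:
missing entries start at the SNP mean; each sweep recomputes the realized
relationship matrix from the current complete matrix and re-predicts each
missing entry as a weighted mean of observed genotypes at that SNP, with
weights clip(K − 3/√m, 0)² (soft-thresholded at the sampling noise of a
zero relationship, squared so close relatives dominate) plus a small prior
weight on the SNP mean. Observed entries are never touched; imputed values
live in [−1, 1]; plain mean imputation is a documented mode. The twin and
no-relatives limits (imputed value → twin's score / column mean) are
tested.

## Population structure

* **Heterozygosity**: H_E = 2p̂(1−p̂) with the n/(n−1) small-sample
  correction on by default (toggle available); H_O = fraction of
  heterozygous calls.
* **LD r²**: two-locus EM maximum-likelihood haplotype frequencies for
  unphased diploids under random mating (only the double heterozygote is
  phase-ambiguous); r² = D²/(p_A p_a p_B p_b). Significance uses the
  asymptotic χ²₁ statistic n_hap·r² on the haplotype-count scale — the
  standard choice where no test is otherwise dictated — and a composite
  (genotypic correlation) estimator is available as a faster alternative.
* **Kinship**: VanRaden, K = WW′ / 2Σp(1−p), W the column-centered scores.
  Off-diagonals carry the usual −1/(n−1) centering offset.
* **PCA**: centered, unscaled scores (scaling optional); deterministic sign
  convention (largest-magnitude loading positive).
* **Ancestry**: alternating projected least squares on allele dosages,
  F ≈ QG with simplex-constrained Q rows (per-row NNLS + normalization) and
  G clipped to [0, 1] — the same model family as sparse NMF ancestry
  estimators, which is sufficient because only Q, the cross-entropy and
  N_Q are consumed downstream. Model choice over K masks 5% of observed
  entries, fits on the rest and scores the masked allele counts under the
  binomial likelihood; best of `n_runs` restarts kept. On simulated
  4-cluster cohorts the masked cross-entropy bottoms out at K = 4.
* **N_Q**: the effective number of clusters per genotype is the inverse
  Simpson index 1/ΣQᵢ². This is the only simple form satisfying both
  defining properties — range [1, K], increasing under stronger admixture
  (Schur-concavity is property-tested).

## Clonal values

REML via direct maximization of the restricted log-likelihood of
y = Xβ + Z_C u_C + Z_SC u_SC + e, with all n-dimensional cross-products
precomputed once and each evaluation reduced to a q × q Cholesky through the
Woodbury identity; the residual variance is profiled out analytically, so
the search is over the two (or one) log variance ratios (Nelder–Mead, two
starts). BLUPs and reliabilities (1 − PEV/σ²_C) come from the mixed-model
equations at the converged components. Single-site data automatically drop
the genotype-by-site term. The deviance test compares REML log-likelihoods
with and without the genotype term against χ²₁; because the null places
σ²_C on the boundary this is conservative (simulated size ≈ 0.02 at
α = 0.05), and a 50:50 χ²₀/χ²₁ mixture option is provided. The plain χ²₁
referent remains the default as the field-standard reporting convention.

## GWAS

Per SNP: trait = intercept + n_pc genotype PCs + marker + polygenic random
effect with covariance σ²_g K. Variance components are estimated once on the
marker-free model (P3D/EMMAX) via the spectral decomposition of K; each
marker is then a weighted (GLS) regression on the rotated scale, tested
two-sided with a t statistic. With K = I and no PCs this reduces *exactly*
to single-marker OLS (tested to 1e−6). PCs are computed from the same
imputed matrix as the kinship, without LD pruning. p-values are floored at
1e−300 before −log10. BH q-values are the step-up adjustment with enforced
monotonicity. Unmapped significant SNPs take the map position of their
highest-r² mapped partner when that r² > 0.6 (ties: smaller cM, then SNP
id). Cross-population regions are maximal same-linkage-group groups of
placed SNPs with −log10 P > 3 spanning < 10 cM and containing every
required population (all populations by default; `min_populations`
relaxes).

## Genomic prediction

* **GBLUP**: REML (1-D search over σ²_e/σ²_g on the training eigenbasis),
  then conditional-mean prediction through the kinship cross-block. Exactly
  dual to marker ridge regression when K = WW′/c (tested to 1e−6).
* **BayesB**: Gibbs sampler over spike-and-slab marker effects — zero with
  probability 1 − π, else normal with a per-marker scaled-inverse-χ²
  variance (marginally scaled-t). Defaults follow common whole-genome
  regression practice: π = 0.5, slab df 5, prior R² 0.5 apportioned over
  markers, burn-in 10,000 / 20,000 iterations (tests use 1,000/3,000
  chains, which change held-out predictions by < 0.02 correlation on fixed
  instances). The sampler's inner loop is numba-compiled.
* **Random forest**: scikit-learn regression forest at the R-package
  regression defaults (500 trees, p/3 features per split, leaf size 5).
* **Cross-validation**: per replicate, a fresh random partition into folds;
  accuracy is the Pearson correlation between observed values and the
  *pooled* validation predictions of that replicate (per-fold averaging is a
  switch); mean ± SE over replicates. Pooled was chosen as the
  lower-variance reading of the ambiguous convention.

A caution the simulations make explicit: with unrelated genotypes, rapid LD
decay and desk-scale n, within-population accuracy for diffuse polygenic
traits is near zero — and pooled-correlation k-fold CV is slightly
negatively biased at zero signal, so moderately negative accuracies are
expected output, not bugs. Accuracy emerges for few-large-QTL traits
(variable-selection models and forests lead there) and in pooled cohorts
where structure carries relationship information.

## Panel selection

The greedy loop: take the highest-score SNP; exclude everything within ±d cM
*on the same linkage group* (a cross-group radius would be meaningless);
repeat; when no candidate remains, halve d and re-admit SNPs at distinct map
positions satisfying the relaxed radius around the already-selected SNPs.
(Measuring the relaxed radius from every *excluded* SNP instead of from the
selected ones would empty the candidate set immediately — every excluded SNP
is by construction near another SNP — so that reading is not implemented.)
Once every distinct position is selected,
fill remaining slots purely by descending score. Ties break by higher
score, lower linkage group, lower cM, lexicographic id — full determinism,
hence nested panels across sizes. Semi-random selection assigns a uniform
random permutation of ranks 1..m as scores and runs the same loop; its
score range follows the mapped-SNP count.

The accuracy-curve experiment recomputes the association scores inside each
training fold by default, so panel choice never sees validation genotypes;
`whole_cohort_scores` uses one whole-cohort scan for every fold (the simpler,
optimistic protocol). Each panel size's replicate accuracies are compared
to the best size's with a two-sample t test; p ≥ 0.05 flags "not
significantly different from the best".

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run everything at reduced scale —
cohorts of 200–300 genotypes, 1,500–3,000 mapped SNPs, 5-fold CV with 1–3
replicates, 1,000/3,000 BayesB chains — sizes chosen so the full pipeline
completes in minutes while every qualitative contrast (decay ordering,
K selection, calibration, architecture-dependent model ranking, panel
curves) is still resolvable. EM LD iterates to 1e−10 or 200 iterations;
REML ratio searches are bounded in log space at e^±25; kinship eigenvalues
are clipped at zero; a 1e−6 ridge guards GBLUP factorizations; collinear
markers are flagged untestable rather than crashing a scan.

## Known limitations

No coalescent realism (site-frequency spectra and haplotype diversity are
not those of a real conifer population); no phasing; no reference-panel
imputation; trial records have no spatial field trend; the LRT default
ignores the boundary issue by design (documented above); BayesB π is fixed
rather than sampled; the ancestry solver is a least-squares factorization,
not a full sparse-NMF implementation, and its cross-entropy values are
comparable across K within a run, not across datasets.
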