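# Methods

`clonetrack` identifies clonally propagated crop varieties in field
collections from genome-wide biallelic SNP dosages and estimates their
founder ancestries. This note documents the models, the estimators, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Genotype model and QC

Genotypes are alternate-allele dosages g_ij ∈ {0, 1, 2} with an explicit
missing mask. Locus curation drops loci with more than 40 % missing calls,
then loci with minor-allele frequency below 0.01 (computed on non-missing
calls, MAF = min(p, 1−p), p = mean dosage / 2). Missingness is evaluated
before MAF; the order matters only for loci failing both rules, which are
reported under "missing". Residual missing calls are imputed either by the
per-locus mean dosage rounded to the nearest integer (default) or by a
k-nearest-sample rule using IBS similarity on jointly complete loci. The
downstream statistics are distance- and frequency-based and insensitive to
the imputer at MAF-filtered loci; distances themselves are computed
pre-imputation by default (imputation toward the locus mean would shrink
duplicate distances artificially).

## Clone identification

The IBS distance between samples a and b is the mean over jointly observed
loci of |g_a − g_b| / 2, a bounded semimetric in [0, 1] (symmetric, zero on
identical genotypes; no triangle inequality is assumed or needed). A Ward
minimum-variance dendrogram is built from this matrix using the
Lance–Williams squared-distance update — the Ward.D2 convention applied to
the IBS distances as-is, without assuming a Euclidean embedding. Merge order
under exact ties follows scipy's nearest-neighbor-chain implementation; on
continuous distances ties have probability zero, and the test-suite oracle
comparison uses cophenetic matrices, which are invariant to merge-order
conventions.

Ramets of a genet are identical up to genotyping error, dominated in
multiplexed sequencing genotyping by heterozygotes miscalled as homozygotes
at low read depth. The identity threshold is therefore calibrated
empirically on re-genotyped duplicate DNAs of the reference library:
t = 1.25 × max(duplicate-pair distance), rounded up to two decimals. The
safety factor and ceiling are configurable; the defaults turn duplicate
distances just under 0.04 into the conventional 0.05 working threshold. A
warning fires when t reaches the smallest distance between distinct
duplicate groups — note that a library containing independently re-collected
accessions of the same genet (synonyms) will trigger this warning benignly.

Clone groups are formed either as connected components of the graph with an
edge wherever d < t (default; transitive closure, monotone coarsening in t)
or by cutting the Ward tree at height t. The two rules can differ on chains
(A–B and B–C below t but A–C above); both are exposed. The reference library
is collapsed to one representative genotype per clone group (representative:
fewest missing calls, ties lexicographic), retaining all member names as
synonyms and flagging conflicting released-variety names rather than
resolving them. Field accessions are matched to the nearest collapsed
library representative and accepted only below t; ties break by distance
then library order.

## Admixture model

Individual i's genotype at locus j is Binomial(2, p_ij) with
p_ij = Σ_k q_ik f_kj, q_i on the K-simplex (ancestry fractions) and f_k the
founder allele-frequency vectors: unlinked loci, founders in
Hardy–Weinberg equilibrium. The log-likelihood is
ℓ = Σ_ij [g_ij ln p_ij + (2 − g_ij) ln(1 − p_ij)], missing entries skipped.

Fitting is by EM on the allele-origin latent variables. Both parameter
blocks are updated from the same E-step; the observed-data log-likelihood
is non-decreasing at every iteration (asserted in tests) and Q rows remain
exactly on the simplex. Frequencies are clamped to [1e-6, 1 − 1e-6].
Convergence: relative log-likelihood change below 1e-6 (default), capped at
2000 iterations, with 3 random restarts keeping the best likelihood.
EM shares its stationary points with the block-relaxation optimizers of
dedicated ancestry software; it is used here because each step is simple
enough to verify directly. Supervised mode pins the Q rows of labelled
reference individuals to founder indicators; with every sample labelled the
fitted f_kj reduce to the per-founder observed allele frequencies (checked
in tests as a closed-form limit).

A known small-sample property worth stating: for a true F1 (q = 0.5/0.5)
the ML fit places a small amount of mass (≈1 % at m = 2000) on
non-parental founders, so the estimated major ancestry is centred slightly
*below* 0.5. Classification rules with an inclusive 0.5 boundary will
therefore send a substantial minority of true F1s to the multi-ancestry
class at desk-scale marker counts; this is a property of the estimator near
a decision boundary, not an optimizer artifact (it persists when EM is
initialized at the generating truth).

K is chosen by masked-entry cross-validation: non-missing entries are
partitioned into folds by a seeded draw (entries whose masking would leave
a locus or sample with no observations are exempted and logged); each fold
is hidden, the model refit, and hidden dosages predicted by 2·p̂_ij. The
per-K score is the mean squared prediction error; on homogeneous data the
K = 1 error equals the within-locus binomial variance E[2p(1−p)]. Entry-wise
(not sample-wise) masking is used, matching the spirit of the standard
ancestry-model CV procedure.

Because mixture labels are arbitrary, fits are compared after aligning
columns by optimal assignment (Hungarian algorithm) on per-column Pearson
correlations; a zero-variance column correlates 0 with everything.

## Ancestry classes and reporting

From the fitted Q: pure if max_k q_ik > 0.90, half-hybrid if
0.50 ≤ max ≤ 0.90 (inclusive at both boundaries, so the three classes are
exhaustive and mutually exclusive), multi otherwise. The variety summary
lists pure varieties in descending accession count with roman numerals,
then ≥50 %-ancestry hybrid rows (excluding pure members, so counts
partition the sample), then one multi-ancestry row. Name–cluster
correspondence cross-tabulates clone groups against farmer-elicited names,
keeping names that occur at least 10 times by default; synonymy = distinct
names per cluster, homonymy = distinct clusters per name.

## Weir–Cockerham F_ST and marker panels

Per-locus differentiation among the subpopulations detected by the
admixture fit (samples with max ancestry > 0.90, assigned to their major
ancestry) is estimated by the Weir–Cockerham (1984) variance components:
a (among populations), b (among individuals within), c (within
individuals), θ = a/(a+b+c). At each locus only subpopulations with at
least two genotyped samples contribute; θ is flagged undefined when fewer
than two remain or when a+b+c = 0 (monomorphic). The implementation is
checked against an independently coded scalar evaluation of the component
formulas to 1e-12 on 1000 random configurations.

AIM panels are loci with θ above a threshold. The subset-accuracy
experiment refits the supervised admixture model (reference = pure samples
of the full fit) on each panel and on 20 equally sized random panels drawn
uniformly with replacement, scoring each refit by the squared Pearson
correlation between its aligned Q entries (pooled over all n×K entries;
per-column R² also emitted) and the full-marker fit.

## DAPC validation

As an assumption-free cross-check, the dosage matrix is column-centered,
reduced by PCA (deterministic sign convention: largest-magnitude loading
positive), scanned by k-means for k = 1..k_max with
BIC(k) = n ln(W_k/n) + k ln n (W_k = within-cluster sum of squares of the
best run). This BIC surrogate is this package's definition; any monotone
transformation preserves the argmin comparisons of interest. Besides the
k-means++ starts, each k > 1 tries one initialization built from the
previous k's centers plus the farthest point, which makes W_k non-increasing
in k by construction. Note the surrogate only develops a minimum at the true
k when post-true-k splits shave a small *fraction* of W — i.e. when the
retained dimensionality is appreciable (dozens of PCs, as with genotype
scores); in very low dimension it keeps declining. Discriminant axes solve
the generalized eigenproblem S_b v = λ S_w v on the retained PCs
(ridge-regularized when within-scatter is singular); membership
probabilities are a Gaussian kernel with unit covariance on
discriminant-space distances to group centroids, normalized per individual.
Agreement with admixture clusters is summarized by cross-tabulating pure
admixture members against DAPC max-membership clusters (per-cluster
best-match rate, overall rate, adjusted Rand index).

## Synthetic data generator

The generator emulates the study design end to end: K founders with iid
Beta(0.5, 0.5) allele frequencies (clamped to [1e-3, 1−1e-3]); genotypes
Binomial(2, (QF)_ij); pure genets, F1 (0.5/0.5), backcross (0.75/0.25) and
multi-founder individuals (Dirichlet(1,…,1) restricted to max < 0.5);
clonal ramets that miscall each heterozygous site to a random homozygote
independently with probability ε (default 0.03) and drop entries missing
with probability μ (default 0.02); a reference library of 34 genets behind
64 accessions (some genets re-collected under different names), each
genotyped in duplicate; ~900 field accessions (550 library-genet ramets,
150 ramets of 9 genets from founders absent from the library, 100 F1s,
50 backcrosses, 50 multi-ancestry seedlings); and a naming model with 1–3
synonyms per genet and a 5 % homonym-reuse probability. The expected
copy-vs-source IBS distance is ε·H/2 for source heterozygosity H, which is
what makes threshold calibration non-trivial.

Deliberately not emulated: linkage disequilibrium, shared founder drift (a
population tree), read-depth variation (the error model is per-call, not
depth-driven), and geography. Passing tests therefore demonstrate correct
inference under the model's own assumptions — independent loci, HWE
founders — and say nothing about robustness to LD or to structured
founders, which real GBS data possess.

## Problem sizes and determinism

Default validation experiments run at desk scale: the standard recovery
design uses K = 5, m = 2000, n = 300 (240 pure, 40 F1, 20 multi);
cross-validated K selection is exercised on a reduced replicate (m = 600,
n ≈ 200) where recovery behaves identically; the field-survey end-to-end
scenario runs at m = 1000 with ~1030 samples. Every stochastic step —
generation, EM restarts, fold assignment, random panels, k-means — is
driven by explicit integer seeds, and fixed-seed runs are bit-for-bit
reproducible (asserted in tests).

## Known limitations

* The admixture model ignores LD; clonal duplicates violate its
  independence assumptions exactly as they do for the real tools, which is
  the reason the DAPC cross-check exists.
* The half-hybrid boundary behavior described above means hybrid-class
  counts are estimator-dependent near max-ancestry ≈ 0.5.
* Ward tie-breaking follows scipy rather than a lowest-index rule; only
  exact ties are affected.
* `hapmap_like` I/O is a minimal transposed dialect with an explicit
  ref/alt column, not a full HapMap reader.
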