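# Methods

This note records the models the package implements, the assumptions
behind them, the defaults and why they were chosen, and what the test
suite does and does not demonstrate.

## Data model and coding conventions

All analyses run on ancestral-allele **dosages**: a diploid genotype is
the count (0/1/2) of the ancestral allele declared in the locus
metadata. The packaged 48-SNP panel reports ancestral-allele
frequencies, so coding genotypes the same way makes reference
frequencies and genotypes directly comparable without re-polarisation.
Missing genotypes are a distinct sentinel (−1 internally, `NA`/`0 0` on
disk), excluded pairwise from every counting step and never imputed at
I/O time. Positions are 1-based as printed in the panel table; no
liftover is performed. VCF REF/ALT are mapped onto the declared
ancestral/derived alleles; a mismatch is an error, never a silent strand
flip.

The packaged panel (`table2_fixture`) carries the four continental
groups' diploid sample sizes (African 97, American 57, European 158,
East Asian 177), which several defaults below use as weights.

## Informativeness for assignment

The multigroup statistic is the entropy difference

I_n = Σ_alleles [ −p̄ log p̄ + Σ_j w_j p_j log p_j ],  p̄ = Σ_j w_j p_j,

with natural logarithms, 0·log 0 ≡ 0, and equal group weights by
default. It is non-negative, zero iff all groups share one frequency,
bounded by log K, and invariant to swapping the allele labels (p →
1−p everywhere).

**Population-specific (one-vs-rest) In.** The "rest" of the groups is
summarised by a single pooled frequency before the two-group statistic
is taken with equal weights on the two sides. The pooling weights are
the design decision that matters: the default weights the other groups
by their diploid sample sizes (falling back to equal weights when sizes
are unknown), because pooling individuals is what an actual combined
reference sample does. On the packaged panel this default reproduces
the published cumulative values (3.4311/1.3030/3.0346/2.7727 vs printed
3.4312/1.3028/3.0343/2.7727; the ±3·10⁻⁴ residue is the 4-decimal
rounding of the input frequencies) and the high-In counts 12/3/10/11
exactly, whereas unweighted pooling does not (it gives
3.3156/1.4079/2.7852/2.3728 and counts 12/4/10/7). Equal and explicit
weights remain available via `rest_weights`.

Reported values are rounded to 4 decimals (frequencies 4, p-values 5);
full precision is retained internally.

## Hardy-Weinberg exact test

`hwe_exact` is the standard conditional exact probability test: given
the allele counts, every compatible heterozygote configuration's
probability is computed (log-gamma arithmetic, normalised in a single
pass) and those with probability ≤ the observed configuration's are
summed. No mid-p correction, matching the exact probability test of the
classical genetics tools. The p-value is undefined (NA) when fewer than
two alleles are effectively observed — the locus is monomorphic or the
minor allele is a single copy — since only one configuration exists.
A relative tolerance of 10⁻¹² absorbs floating-point ties between
equally probable configurations. The test is verified against an
exact-rational (Fraction) enumeration oracle exhaustively for all
genotype triples with n ≤ 25 and property-tested beyond.

Bonferroni correction is plain α/m; at α = 0.05 over the 48-locus panel
the level is 0.00104.

## Panel selection

Criteria are evaluated per candidate in a fixed order — bi-allelic,
intronic (metadata flag only; the package never queries genome
annotation), frequency differential, HWE, spacing — and the first
failure is the single removing criterion, so the audit partitions the
candidates. Two decisions the criteria leave open:

* **Differential scope.** The ≥ 0.3 differential is the *maximum*
  pairwise difference within a group set, satisfied if *any* named
  group set qualifies (OR semantics). This encodes the deliberate
  retention of loci differentiated either among continents or among
  regional subpopulations; AND semantics would reject panel members
  whose continental differential is below 0.3 (e.g. rs2373177,
  0.6031/0.6053/0.7152/0.7386).
* **Spacing tie-break.** Among loci closer than 10 Mb on one
  chromosome, removal is greedy: the conflicted locus with the smallest
  maximum differential is dropped first (ties: the larger position).
  This keeps the most ancestry-informative locus of each cluster and is
  deterministic. Relaxing a threshold criterion is monotone on
  conflict-free candidates; when spacing conflicts interact with newly
  admitted loci the greedy resolution can swap which member of a
  cluster survives.

An undefined HWE p-value counts as conforming, mirroring the NA
convention of the reference tools.

## Naive-Bayes ancestry classification

Per locus, the genotype likelihood under a group with corrected
frequency p′ is p′², 2p′(1−p′) or (1−p′)² by dosage; log-likelihoods
are summed over the individual's non-missing loci and combined with a
uniform prior (blind-sample treatment) in log space. Likelihood ratios
are carried as log values, so ratios beyond 10³⁰⁰ never overflow.

Zero-frequency correction defaults to the pseudocount
p′ = (2Np + 1)/(2N + 2) when the reference table carries sample sizes
(one artificial copy of each allele), else clamping at ε = 1/2000. This
keeps likelihood ratios finite while preserving their ordering; the
uncorrected mode exists for oracle comparisons.

## Multinomial logistic regression

Fitted on dosages via scikit-learn's lbfgs solver with a small ridge
penalty (default 10⁻⁶) so that separable classes — the norm at
subpopulation scale with informative panels — converge to a stable,
deterministic solution instead of divergent coefficients. Reported
probabilities are rounded to 4 decimals in summaries, so cleanly
separated classes print 1.0000. Missing dosages are mean-imputed from
the training columns (the naive-Bayes path instead drops the locus for
that individual). Non-convergence is flagged on the results object, not
silenced. Class assignments are cross-checked in the tests against an
independent statsmodels MNLogit fit.

## PCA

Loci are centred by twice the reference mean frequency and scaled by
sqrt(p̄(1−p̄)), the expected per-copy binomial standard deviation;
missing entries are mean-imputed at the centring step (standard
genotype-PCA practice) and monomorphic loci are dropped with a warning.
Scores come from the SVD of the standardised reference matrix; test
individuals are projected using reference means, scales and loadings
only, so projection of the reference individuals themselves reproduces
their fitted scores.

## Admixture model

The likelihood is binomial per genotype entry: dosage g_il ~
Bin(2, μ_il) with μ_il = Σ_k q_ik f_lk. EM alternates the closed-form
updates of Q (rows kept on the simplex) and F (clamped to
[10⁻⁶, 1−10⁻⁶] to keep the likelihood finite); missing entries simply
drop out of the sums. The log-likelihood trace is retained and checked
non-decreasing every iteration. Defaults: tol 10⁻⁶ on the
log-likelihood, max 2000 iterations, 3 random starts (Q from symmetric
Dirichlet(1), F from observed frequencies plus seeded uniform noise)
with the best final likelihood kept — plain EM is adequate at the
panel sizes this package targets (tens to hundreds of individuals,
~50 loci), so no quasi-Newton acceleration is used. K = 1 is solved in
closed form. In supervised mode F is fixed to a reference table; the
per-individual likelihood is then concave in q, and the tests verify
the EM solution against a direct per-individual optimiser.

At 48 loci the information available per individual bounds how well Q
can be recovered: with the packaged panel's divergence the mean
absolute error of supervised estimates is ≈ 0.04 for unadmixed
individuals (worst for the American group, consistent with its low
cumulative In) and ≈ 0.2 for maximally uncertain Dirichlet(1) ancestry
vectors. These are statistical limits, not estimator defects — the EM
estimates agree with direct maximum likelihood to ~10⁻³.

**Cross-validation over K.** Observed entries are partitioned into 5
seeded folds (entry-wise, not individual-wise); each fold is masked,
the model refit, and masked dosages predicted as 2μ. The per-fold
score is a root-mean-square binomial deviance residual,
d² = 2[g log(g/2μ) + (2−g) log((2−g)/(2−2μ))], and the per-K error is
the mean across folds. A fold assignment that would empty a row or
column is redrawn (bounded retries). On synthetic 3-group data the
argmin recovers K = 3 in ≥ 9/10 seeds.

**Label alignment.** Cluster labels between two fits of equal K are
matched greedily by Q-column correlation (mean absolute difference for
degenerate constant columns), which is sufficient for the label
switching of independent EM runs.

## Synthetic data

The generator emulates the study design the analyses assume: unlinked
bi-allelic SNPs; groups in HWE with divergent frequencies (independent
per-group perturbation of a shared Uniform(0.1, 0.9) baseline,
truncated to [0.01, 0.99]; scale 0.2 by default, a Balding-Nichols
option with Fst 0.15 for more realistic drift); optionally admixed
individuals with Dirichlet ancestry; uniform missingness. Sampling is
allele-wise — each allele copy draws its source group from q_i, then
its allele from that source — so unadmixed dosages are Binomial(2, p)
by construction and one-hot Q reduces *bit-exactly* to the unadmixed
path. A single seed drives named sub-streams (frequencies, ancestry,
genotypes, missingness), making generation a pure function of the spec.

What the generator does **not** emulate: linkage disequilibrium,
coalescent/demographic history, genotyping error, and the
population-within-group substructure of real reference panels. Passing
recovery tests on this synthetic data therefore demonstrates estimator
correctness under the model's own assumptions, not performance on real
cohorts with LD or cryptic structure.

`simulate_candidates` additionally engineers candidate tables whose
loci violate named selection criteria (close spacing pairs, flat
frequencies, excess-heterozygosity HWE failures, non-intronic flags)
with exact bookkeeping, so the filter audit can be checked against the
construction.

## Problem sizes in the test suite

The suite exercises the estimators at desk scale — tens to a couple of
hundred individuals, 30–48 loci, 10 seeds for the K-selection check —
sizes at which the statistical claims under test (binomial sampling
error, EM recovery bounds, CV argmin frequencies) are already sharp.
The full suite runs in well under a minute.

## Known limitations

* One-vs-rest In depends on the rest-pooling convention; only the
  sample-size-weighted default reproduces the published panel
  summaries, and per-population (rather than pooled-group) frequencies
  are not what the packaged table contains.
* The admixture EM is single-threaded plain EM; hundreds of thousands
  of loci would need acceleration this package does not attempt.
* The exact HWE test is for autosomal bi-allelic loci only; X-linked
  male hemizygotes are not modelled.
* PED/MAP input without locus metadata falls back to alphabetical
  allele ordering for the ancestral declaration, which is deterministic
  but arbitrary; supply locus records whenever polarity matters.
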