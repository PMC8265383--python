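# Methods

## Data model

All analyses consume a `BandMatrix`: individuals × loci scores in
{0, 1}, one population label per individual, optionally a locus → primer
map and a population → taxon map.  Missing scores are rejected at load
time; the only alternative policy is dropping affected loci
(`on_missing="drop-locus"`).  Silent imputation is never offered because
a filled-in cell shifts every downstream band frequency.  Duplicate
*rows* are legal and surface through `find_duplicates` (multi-locus
matching); they are reported, never removed, since apparent duplicates
in clonally propagated material are a finding, not an error.

## Allele frequencies and diversity under dominance

For a biallelic dominant locus, band absence identifies the null
homozygote only.  Assuming Hardy–Weinberg proportions, the null-allele
frequency is estimated as q̂ = √(1 − f) from the within-population band
frequency f, and p̂ = 1 − q̂.  All diversity statistics derive from
(p̂, q̂): He = 2p̂q̂, uHe = (2N/(2N−1))He, Ne = 1/(p̂² + q̂²),
I = −(p̂ ln p̂ + q̂ ln q̂) (natural log), PIC = 1 − [f² + (1−f)²] with f
pooled over all accessions.

Conventions that matter for comparability with the dominant-marker
literature (and with GenAlEx-style output):

- **Na** is reported as the band-presence indicator 1{f > 0} averaged
  over loci, so per-population values lie in [0, 1].  This is the
  convention under which published per-population Na values below 1 for
  this data type are arithmetically consistent.
- **Monomorphic loci are included** in every per-population mean; their
  zeros belong in the average and excluding them inflates all indices.
- **%P** counts loci with 0 < f < 1, no minor-frequency threshold
  (an optional threshold exists, default off).
- **Standard errors** are sd over loci (ddof = 1) divided by √n_loci.
  The grand-mean row of the diversity table instead carries SEs over
  populations, since it summarises population means.
- **Mean PIC** is the unweighted mean over loci; the mean of per-primer
  means is also computed and reported, because both conventions occur in
  published tables and they differ whenever primers contribute unequal
  locus counts.

The estimator q̂ is consistent but nonlinear, so finite-sample means of
He measured at N = 8 sit below the values implied by the true q (see
*Simulator* below); parameter-recovery tests therefore use large N
(bias of q̂ < 0.02 at N = 500 in the test suite).

## Distances and AMOVA

On 0/1 vectors the mismatch count equals the squared Euclidean
distance, and it enters the AMOVA sums of squares directly:
SS_total = (1/N)Σ_{i<j}d², SS_within = Σ_pop(1/N_p)Σ_{i<j∈pop}d²,
SS_among by subtraction; σ²_within = MS_within,
σ²_among = (MS_among − MS_within)/n0 with
n0 = (N − ΣN_p²/N)/(k−1).  The three-level design partitions SS into
among-taxa / among-populations-within-taxa / within-populations strata
with the standard nested coefficients (n1, n2, n3) for unequal sizes,
giving Φ_RT = σ²_a/σ²_tot, Φ_PR = σ²_b/(σ²_b+σ²_w),
Φ_PT = (σ²_a+σ²_b)/σ²_tot.

Numerical and inferential choices:

- **Negative variance components are floored at zero** before Phi and
  percentage computation, keeping estimates in [0, 1]; raw components
  stay available on the results object (`raw_sigma2`).
- **Permutation tests rank on the raw, unfloored statistic.**  If the
  floored statistic were compared, every null permutation tying at zero
  would count as "as extreme", piling p-values at 1.0; ranking raw
  ratios keeps the null distribution of p-values uniform (verified by a
  KS check in the test suite).  Reported estimates remain floored.
- Schemes: Φ_PT permutes individuals among populations preserving
  sizes; Φ_PR permutes individuals among populations within their
  taxon; Φ_RT permutes whole populations among taxa.  The estimator is
  p = (hits + 1)/(B + 1); default B = 999, configurable.
- A zero-variance data set yields Phi = NaN ("undefined"), never 0;
  single-member populations are allowed (they contribute 0 within-df),
  an all-singleton layout is rejected.
- All randomness flows through one seeded `numpy` generator; a fixed
  seed fixes every p-value.  Pairwise Φ_PT derives one independent
  child stream per population pair from the seed, so results do not
  depend on evaluation order.
- Pairwise Φ_PT p-values are reported uncorrected for multiple testing.

## PCoA

Gower double-centering of −½D² followed by symmetric
eigendecomposition; for the mismatch-count metric the matrix entries
already are squared distances and are centred as-is (`treat_as_squared`
overrides).  Coordinates are eigenvectors scaled by √λ for λ > 0; axis
percentages use the positive-eigenvalue total as denominator; negative
eigenvalues are retained for inspection but excluded from percentages.
Eigenvalues below 1e−10·λ_max in magnitude are dropped as numerical
nulls.  Per-axis sign is fixed by forcing the first accession's
coordinate non-negative (falling back to the largest-|loading| element),
making output identical across LAPACK backends.

## UPGMA

Classical size-weighted (unweighted in the historical naming) pair-group
averaging: closest clusters merge at height d/2; the merged cluster's
distance to others is the member-count-weighted mean.  Ties at the
minimum — common on small integer distances from binary data — break on
the lexicographically smallest (cluster-id, cluster-id) pair, ids being
the smallest member label, so topology is deterministic.  Trees are
ultrametric by construction; cutting into k clusters undoes the last
k−1 merges.  Dendrograms default to p-distances (mismatch/n_loci), so
branch lengths read as per-site differences; mismatch counts are
selectable and scale all lengths by n_loci.  Population purity at a cut
reports, per population, the largest fraction of members in one cluster,
and overall the fraction of populations kept intact.

## Evanno ΔK

From replicate log-likelihoods per K: L′(K) = L̄(K) − L̄(K−1),
|L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)|/sd L(K).  ΔK is undefined at
the boundary K and wherever sd = 0; undefined entries are NaN and are
excluded from the argmax (ties resolve to the smaller K with a flag).
The module consumes (K, replicate, lnL) tables or harvester-style
(K, mean, sd) summaries; it does not run Bayesian clustering itself.

## Simulator

Genotypes are simulated, not band frequencies: each individual draws two
alleles Bernoulli(q) per locus and shows the band unless both are null,
so P(band) = 1 − q² and the √(1−f) estimator is the exact generative
inverse.  Bottlenecks sample founder allele counts binomially
(2·n_founders copies) from the source frequencies, then apply
Wright–Fisher binomial resampling for g generations at effective size
Ne; expected heterozygosity decays by (1 − 1/(4·n_founders)) ·
(1 − 1/(2Ne))^g in expectation.

The default scenario produces 17 populations × 8 individuals × 148
biallelic loci: a broad wild source (per-locus q ~ Beta(0.45, 0.45)),
a narrow wild isolate (3 founders, 10 generations, Ne = 8) and 15
cultivated lines (2 founders, 16 generations, Ne = 6) founded
independently from the source.  The Beta parameters were calibrated so
that the *measured* source He at N = 8 — through the same √ estimator
used in the analysis, whose nonlinearity and sampling variation shrink
measured He below the true value — averages ≈ 0.17, with cultivated
lines at He ≈ 0.02–0.05 and one-level Φ_PT ≈ 0.80, the regime of a
diverse wild species from which uniform commercial lines were drawn.
U-shaped Beta frequencies also reproduce the realistic preponderance of
fixed or nearly fixed bands within lines.

What the generator does *not* emulate: linkage between loci, mutation
(including new transposon insertions), selection beyond founder
truncation, scoring error and comigrating non-homologous bands, or
missing data.  Tests passing on these data therefore validate the
estimators' algebra and calibration under HWE with drift — not
robustness to gel-scoring artefacts or non-equilibrium genotype
proportions.

## Problem sizes in the tests and the acceptance script

The test suite uses hand-computable toys (4–8 individuals), random
matrices up to ~20 × 50 against brute-force oracles, 500 replicates at
199 permutations for permutation-calibration checks, N = 500 × 300 loci
for estimator recovery, and the full 136 × 148 default scenario for
end-to-end properties.  `scripts/acceptance.py` analyses one 136 × 148
simulated data set with 999 permutations.  These sizes keep every run in
seconds while leaving Monte-Carlo error well inside the asserted
margins.

## Known limitations

- The HWE square-root estimator is undefined-ly optimistic under
  inbreeding or selfing (common in cultivated lines); reported He for
  highly selfing material should be read as an upper bound on
  outcrossing-equivalent diversity.
- AMOVA percentages and Phi treat the mismatch metric as the squared
  distance; feeding pre-squared or root-transformed matrices is the
  caller's responsibility when bypassing `pairwise_distance`.
- The hierarchical decomposition assumes every population belongs to
  exactly one taxon; crossed designs are out of scope.
- PCoA applies no Lingoes/Cailliez correction; strongly non-Euclidean
  inputs simply report negative eigenvalues.
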