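# bandpop

Population-genetic analysis of **dominant-marker band matrices** — the
0/1 presence/absence scores produced by iPBS, ISSR, RAPD and similar PCR
fingerprinting systems.  It is written for plant-breeding and
conservation-genetics workflows in which a set of lines or populations is
genotyped with a handful of primers and the questions are: how much
diversity does each population hold, how strongly are populations
differentiated, and how do individuals group?

## What it computes

A dominant marker cannot distinguish a heterozygote from a band-allele
homozygote, so allele frequencies are estimated under Hardy–Weinberg
equilibrium from the band frequency *f* in each population:

    q̂ = √(1 − f)        (null-allele frequency)
    p̂ = 1 − q̂           (band-allele frequency)

From (p̂, q̂) the package derives, per locus and per population:
expected heterozygosity He = 2p̂q̂ and its small-sample correction
uHe = (2N/(2N−1))·He, the effective allele number Ne = 1/(p̂²+q̂²),
Shannon's information index I = −(p̂ ln p̂ + q̂ ln q̂), the band-presence
indicator Na, the percentage of polymorphic loci, and the polymorphic
information content PIC = 1 − [f² + (1−f)²] of each locus over the
pooled data set.

Differentiation is measured by **AMOVA** on squared pairwise distances
(for 0/1 data the mismatch count *is* the squared Euclidean distance):

    SS_total  = (1/N) Σ_{i<j} d²ᵢⱼ
    SS_within = Σ_pop (1/N_p) Σ_{i<j∈pop} d²ᵢⱼ
    Φ_PT      = σ²_among / (σ²_among + σ²_within)

with permutation p-values, a three-level decomposition
(Φ_RT, Φ_PR, Φ_PT) when populations are nested in taxa/series, and the
pairwise population Φ_PT matrix.  Ordination and clustering come as
principal coordinates analysis (Gower double-centering +
eigendecomposition) and UPGMA dendrograms with Newick output; the Evanno
ΔK = |L″(K)|/sd[L(K)] table selects the number of genetic clusters from
external Bayesian-clustering log-likelihoods.  A genotype-level
simulator (HWE with dominance masking, founder bottlenecks,
Wright–Fisher drift) generates data sets with known ground truth.

## Worked example

Simulate the default scenario — 15 cultivated lines founded through
narrow bottlenecks from a diverse wild source, plus two wild populations,
17 × 8 individuals at 148 loci — and analyse it:

```python
import bandpop as bp

sim = bp.paper_like_dataset(seed=1)
m = sim.matrix

bp.diversity_table(m)           # per-population He, uHe, I, %P ...
res = bp.Amova.from_band_matrix(m).fit(n_permutations=999, seed=1)
print(res.summary())
```

```
AMOVA (hierarchical)
================================================================
                                df        SS       MS  sigma2      pct
source
Among taxa                       3  295.7484  98.5828  0.0000   0.0000
Among populations within taxa   13 1586.1339 122.0103 14.8177  81.0322
Within populations             119  412.7500   3.4685  3.4685  18.9678
Total                          135 2294.6324      NaN 18.2862 100.0000
----------------------------------------------------------------
PhiRT = 0.0000   p(perm) = 0.981
PhiPR = 0.8103   p(perm) = 0.001
PhiPT = 0.8103   p(perm) = 0.001
permutations = 999, seed = 1
```

81% of the molecular variance lies among lines (Φ_PT = 0.81,
p = 0.001): each bottlenecked line is nearly uniform inside but fixed
for a different subset of bands.  The commercial-series level explains
nothing (Φ_RT ≈ 0) — lines were founded independently, not by series.
The diversity table shows the same story from the heterozygosity side
(wild source R: He 0.164, 45.3% polymorphic loci; cultivated lines:
He 0.02–0.05):

```
            he      uhe   shannon_i  pct_polymorphic
A       0.0315   0.0336      0.0484          10.1351
J       0.0361   0.0385      0.0521           8.7838
Q       0.0697   0.0744      0.1015          17.5676
R       0.1643   0.1752      0.2430          45.2703
Mean    0.0445   0.0475      0.0653          11.6455
```

A UPGMA tree on p-distances recovers the line structure almost
perfectly (total branch length 4.18; 16 of 17 populations form intact
clusters when the tree is cut into 17 groups, purity 0.941).

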