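# Methods

`pairscan` implements the analytical chain used to contrast resident
(Kokanee) and anadromous (Sockeye) *Oncorhynchus nerka* collections from two
lake systems with very different demographic histories: one strongly
differentiated pair and one pair that is genetically indistinguishable. The
chain is genotype QC → population-genomic statistics → F_ST-outlier scanning
→ kinship-corrected GWAS → random-forest backward purging, exercised
end-to-end on synthetic genotypes with known truth.

## Synthetic data: the Balding–Nichols F-model

Each locus draws an ancestral frequency p̄ ~ Uniform(0.05, 0.95). A
population at divergence c from the ancestral pool has allele frequency
p ~ Beta(p̄(1−c)/c, (1−p̄)(1−c)/c), whose variance is c·p̄(1−p̄) — i.e. c plays
the role of F_ST. Genotypes are Binomial(2, p) within population
(Hardy–Weinberg). Two scenarios are bundled:

- **strong pair** (`redfish_like`): c = 0.09, n = 103 anadromous + 45
  resident, 2,600 loci, 5% of loci planted at c = 0.4 (divergent selection).
  The binary life history equals the population label, as in a system where
  ecotype and population coincide.
- **panmictic pair** (`alturas_like`): c = 0, n = 14 + 49. Five causal loci
  (drawn among loci with ancestral frequency in [0.2, 0.8] so their MAF is
  useful) each shift a standard-normal liability by 0.8 per allele; the top
  n_anadromous liabilities are scored migratory, preserving the observed
  class imbalance (14/63). Five causal loci is a deliberate oligogenic
  choice, matching the size of the planted set used in the random-forest
  recovery benchmark.

The four-collection design (`simulate_two_lakes`) nests both pairs under a
common locus panel with a lake-level divergence of 0.05.

What the generator does **not** emulate: linkage (loci are exchangeable and
unlinked, so the pair scenarios carry no background LD and LD-based Ne on
them is correctly ~infinite), genotyping-error structure, allele dropout, or
selection acting over generations. Passing tests therefore demonstrate
estimator correctness under the F-model, not robustness to those artefacts.

A separate individual-based Wright–Fisher generator
(`simulate_wright_fisher`) tracks a finite diploid parent pool so that drift
LD of order 1/(3Ne) exists for the LD-based Ne estimator to measure. For
ne > 10⁵ parents the drift LD is negligible and the generator switches to the
exact no-LD limit (binomial genotypes at drifted frequencies), which avoids
materialising the parent pool.

## Genotype QC

Filters run in a fixed, logged order: individuals with < 75% of loci called;
then loci with global MAF < 0.05, observed heterozygosity > 80% (a paralog /
PSV screen), or missingness > 30%; finally loci out of Hardy–Weinberg
equilibrium in ≥ 3 collections. All inequalities are strict, matching the
filters' directional definitions. HWE uses Levene's conditional exact test
(probability method: the p-value sums all heterozygote counts whose
conditional probability does not exceed the observed one); the per-population
significance level is the Benjamini–Yekutieli threshold q / Σ_{i≤m} 1/i with
m = loci tested in that population. The same simplified BY threshold is used
for every significance call in the pipeline (at m = 2,593 and q = 0.05 it is
0.005926).

## Population-genomic statistics

- Ho, He (Nei's unbiased 2p̂q̂·2n/(2n−1)) and F = 1 − Ho/He per locus and
  group; F is undefined (and excluded from means) where He = 0.
- Weir–Cockerham (1984) variance components a, b, c per locus; multilocus
  theta is the ratio of sums Σa / Σ(a+b+c) over informative loci, negative
  per-locus values retained. Confidence intervals bootstrap loci (percentile,
  default 1,000 replicates); the bootstrap p-value is the fraction of
  replicates with theta ≤ 0.
- PCA mean-imputes missing dosages, centres columns, and eigen-decomposes via
  SVD; components with positive eigenvalues are returned.
- LD is the composite genotypic r² (squared Pearson correlation of dosages
  over pairwise-complete samples), appropriate for unphased data.
- Ne uses the bias-corrected LD method: mean r̂² over all pairs passing the
  MAF cutoff, minus the sampling expectation 1/S + 3.19/S² (S ≥ 30) or
  0.0018 + 0.907/S + 4.44/S² (S < 30, harmonic-mean sample size), mapped to
  Ne by the corresponding quadratic-root formula. Without a map, linked pairs
  cannot be excluded, so estimates on real linked data would be biased
  downward. The CI is parametric (chi-square on mean r̂² with df = number of
  pairs); a jackknife CI is not implemented. Non-positive drift r² reports
  infinite Ne.

## Outlier scan

The neutral null is the same F-model, conditioned on the data: the target
neutral mean theta is the trimmed ratio-of-sums (excluding the 5% most
extreme per-locus thetas at each tail, a one-pass stand-in for full iterative
outlier removal), the null is simulated at the observed group sample sizes,
and c is rescaled once so the simulated *trimmed* multilocus theta matches
the observed target — comparing trimmed to trimmed cancels the trim bias.
This replaces a coalescent island-model simulator with a desk-scale null that
targets the same conditioning (mean F_ST given heterozygosity). Simulated
loci fall into 20 equal-count bins of mean within-group expected
heterozygosity; an observed locus's empirical p is the add-one-smoothed,
mid-rank-tied fraction of its bin's simulated thetas at or below its theta.
A locus is divergent if 1 − p, or balancing if p, beats the BY threshold at
m = loci scanned. The neutral set is the loci with p in [0.1, 0.9] in all
three analyses.

Two calibration facts worth knowing. First, with a fixed per-test threshold
t = q/Σ(1/i) ≈ 0.0059, a perfectly uniform empirical p still flags ~0.6% of
truly neutral loci per tail — the fixed simplified BY threshold is not an
FDR-adaptive step-up procedure, so the neutral "divergent" rate cannot fall
below that floor. Second, planted outliers drawn from the Beta at c = 0.4
have hugely dispersed realized divergence (median per-locus theta ≈ 0.18);
even an oracle null caps recovery at the BY stringency near ~20%. Power rises
steeply with the planted divergence and with how extreme the tail criterion
is, and the scan's ranking (empirical p) is well calibrated — KS distance to
uniform < 0.05 under the null.

## GWAS mixed model

y = Xβ + g + e with g ~ N(0, σ²_g K), K the VanRaden genomic relationship
ZZᵀ / (2Σp̂(1−p̂)) on subpopulation-imputed dosages (missing cells drawn
Binomial(2, p̂_subpop) — a deliberate frequency-based substitution for
haplotype-cluster imputation). The binary phenotype is modelled as Gaussian
0/1, as the classical mixed-model GWAS frameworks for this design do.
Variance components are estimated once under the no-marker null by REML,
profiling the ratio λ = σ²_g/σ²_e on the spectral decomposition of K (grid
scan plus bounded refinement; reproducible to < 1e−6), then reused for every
marker test (P3D), giving deterministic O(n) Wald tests per marker with
t-distributed statistics. Fixed-effect candidates (sex, then PC1–PC3 in
order) enter by forward selection when they lower the ML BIC by more than 2.
Residualization returns y − Xβ̂ − ĝ (BLUP, computed in the rotated basis) for
the phenotype and for every marker column treated as the response of the same
model form (each with its own profiled λ).

Calibration: on structured null pairs (F_ST 0.09, phenotype confounded with
population) genomic inflation is ~1.0. Power at the study's panmictic-pair
size (n = 63, binary trait) is intrinsically limited: a marker reaches the
top 1% of p-values only when it explains roughly ≥ 20% of liability
variance, so with five causal loci of shift 0.8 about a quarter of causal
loci rank that high; a monogenic architecture would reach ~75%.

## Random-forest backward purge

Regression forests (candidate features per split = ⌈m/3⌉, minimum node size
5, out-of-bag error) run on the residualized data in triplicate with distinct
seed substreams. Importance is permutation importance — the mean increase in
MSE over eight shuffles per column, batched into single predict calls and
chunked to bound memory; several shuffles are averaged because the classical
per-tree OOB permutation importance is far more stable than a single shuffle,
and the 0.90 replicate-correlation convergence rule presumes that stability.
If the *minimum* pairwise Pearson correlation of the three importance vectors
is below 0.90, the triplicate reruns once at the escalated tree count and
then proceeds with a warning (near the end of a purge, correlations over 2–4
importance values are inherently unstable — warnings there are expected).
The union of each replicate's top ⌈2%·m⌉ markers seeds the backward purge:
each step refits the triplicate, records mean pseudo-R² (OOB proportion of
residual-phenotype variance explained — the residual is the forest's
response, so its variance is the denominator), and drops the marker with the
lowest mean importance (ties broken lexicographically by id) until two
remain. The best subset maximizes mean pseudo-R², earliest step on ties.

Problem sizes: configuration defaults keep the reference tree counts (10,000
initial, 100,000 escalated); the bundled benchmarks and analysis scripts use
100–300-tree forests, which the convergence rule accepts at these data sizes
and which keep a 50-marker purge under a minute. The purge recovery
benchmark plants 5 causal markers among 45 noise markers at n = 150 with the
five jointly explaining ~56% of response variance — the scale of variance the
method's best subsets are expected to explain.

## Numerical and design choices

- One master seed; every stochastic stage draws from a named SHA-256-derived
  substream, so stages are independently reproducible and tabular outputs are
  byte-identical across runs.
- Allele orientation: codes count the globally minor allele (ties keep the
  orientation of the counted allele written as allele 001). Genepop
  round-trips are exact for minor-oriented matrices; the format cannot record
  which allele was counted, so a majority-oriented matrix is re-oriented on
  read (`orient_minor` canonicalizes).
- Monomorphic loci are uninformative for theta and excluded from multilocus
  sums; all-missing loci are flagged and removed at QC.
- Non-positive-definite kinship gets a 1e−6 ridge (logged).
- Empty heterozygosity bins in the outlier null borrow the nearest populated
  bin (warned).

## Limitations

- The F-model null and generator share a family; real data violate both in
  the same directions (linked loci, non-equilibrium demography), so outlier
  false-positive rates on real data will exceed the simulated floor.
- The binary-as-Gaussian LMM is a fidelity choice, not the statistically
  optimal model for a rare binary trait at n = 63.
- LD-based Ne assumes unlinked loci and a closed, discrete-generation
  population; estimates on mixed-age samples are biased (documented, not
  corrected).
- The purge is greedy: a causal marker dropped early cannot return.
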