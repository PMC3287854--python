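# Methods

This note records the generative model, the numerical and design choices
behind it, and what the synthetic data do and do not emulate.

## Trait model

Each quantitative trait (Q1, Q2, Q4) and the latent liability L are sums of
additive SNP effects, fixed covariate effects, a residual polygenic
deviation and a residual environmental deviation, on a scale where the
residual (polygenic + environmental) variance of each trait is 1.  Effect
sizes in the packaged tables are therefore displacements in residual-SD
units per minor-allele copy.  This scale convention is what makes the
residual heritabilities directly recoverable: for a trait with residual
heritability h², the polygenic deviation has variance h² and the
environmental deviation 1 − h².

The polygenic deviations of (Q1, Q2, L) are drawn jointly: across
individuals their covariance is 2Φ (twice the kinship matrix; the identity
for unrelated individuals), and across traits a genetic covariance built
from the per-trait h² and a genetic correlation matrix.  The draw uses the
matrix-normal identity X = L_Φ Z C_gᵀ with L_Φ the Cholesky factor of 2Φ
and C_g a PSD factor of the cross-trait covariance (an eigenvalue factor is
used when a trait has h² = 0, which makes the matrix singular).  Q4's
genetic component (h² = 0.70) is drawn separately and independently of the
other three — Q4 owes none of its heritability to the genotyped SNPs, and
nothing ties its polygenic component to theirs.  Environmental deviations
are independent across individuals with a weak cross-trait correlation.

Defaults not fixed by the study description, chosen once and exposed in
`TraitModelConfig`:

| parameter | default | note |
| --- | --- | --- |
| genetic cross-trait correlation (off-diagonal) | 0.5 | "correlated" without a printed value |
| environmental cross-trait correlation | 0.2 | "weakly correlated" |
| latent-liability residual h² | 0.0 | liability variation beyond its SNPs is environmental by default |
| covariate effects | Q1: +0.01/yr age, +0.3 smoking; Q4: −0.01/yr, −0.5 female, −0.3 smoking; L: +0.01/yr, +0.3 smoking | directions are part of the model; magnitudes are package defaults |
| age distribution | normal(41.8, 12) truncated to [16, 91] by rejection | only mean and range are specified |
| smoking | Bernoulli(0.25), redrawn each replicate | only genotype/age/sex/pedigree are held fixed across replicates |

Age enters centered at the sample mean, so covariate defaults do not shift
trait means.

## Disease assignment

Liability = L + Q1 + Q2 − Q4, summed unweighted with the raw (not
re-standardized) trait values.  Affection is rank-based within each
replicate: the top round(prevalence·N) individuals by liability are
affected, ties broken by stable individual order.  This makes the affected
count exactly constant across replicates (209 of 697 at 30%) while the
affected identities vary; an equivalent fixed-threshold formulation would
let the count fluctuate.

## Founder genotypes

Target MAFs are drawn from a three-bin spectrum (probabilities over the
non-private mass: 0.578 below 0.01, 0.214 in [0.01, 0.05), 0.208 above)
with a separate private fraction of 0.384, which reproduces the summary
fractions 38.4% private / 74% ≤ 0.01 / 12.8% ≥ 0.05.  Within the rare bin,
MAFs are drawn as discrete allele counts k/(2N) with weights ∝ 1/k, which
places the median MAF at three copies (~0.002 for N = 697); other bins are
log-uniform.  Haplotypes are independent Bernoulli(MAF) draws per
chromosome copy, except that any marker whose target MAF rounds to a
single copy is placed as exactly one minor allele on a uniformly chosen
haplotype — private variants are private by construction, not in
expectation.

The default map has 24,487 markers in 3,205 genes across 22 autosomes.
Per-gene marker counts come from a negative binomial with mean 7.64 and
SD 14, truncated to [1, 231] and adjusted to the exact total; only these
moments are targeted, the true gene-size distribution is not published.
Markers the generator names itself are labeled `C<chrom>S<rank>` with the
S-index equal to the marker's rank on its chromosome.  Functional variants
from the effect tables are injected under their verbatim labels at their
reference MAFs; because those label indices imply far more markers per
chromosome than the default map contains, the generator's own ranks are
offset above the injected indices so labels stay unique, and the
rank-equals-index property holds only for fully synthetic maps.  What the
synthetic panel does **not** emulate: population structure (a single
panmictic pool is drawn), linkage disequilibrium between markers, and the
calling artifacts that shaped the original rare-variant excess — the
spectrum is emulated as reported, not the process that produced it.

## Pedigrees, gene dropping and IBD

The family design places 697 individuals into 8 four-generation pedigrees
with 202 founders in total: a founder couple, a handful of married
children, married grandchildren chosen round-robin across sibships (which
guarantees second cousins in generation four, kinship 1/64), and
great-grandchildren, with sibship sizes partitioned randomly to hit each
family's exact member and founder quota.  Only the aggregate counts
(8 families / 697 members / 202 founders / four generations / second
cousins) match the published design; the true family structures are not
printed.  Founder haplotypes are drawn from the unrelated panel without
replacement.

Each meiosis transmits a recombinant haplotype with exactly one obligate
crossover per chromosome at a uniform position over the chromosome's
marker extent — no interference, no sex-specific map, and the
whole-chromosome (rather than per-arm) reading of "one crossover" is
assumed.  Founder haplotypes carry unique labels, so IBD sharing is exact:
per gene, each individual's two labels are read at the gene's bp midpoint
(genes inherit atomically; if a crossover lands inside a gene span the
genotype drop still recombines marker by marker, and the one-gene-wide
discrepancy window is accepted), and π̂ᵢⱼ is the number of label matches
between the pairs' two labels divided by 2 — always 0, 0.5 or 1 for
non-inbred pedigrees, with E[π̂] = 2Φ.

Because IBD matrices are dense (697², one per gene), the pipeline writes
them for the functional genes by default; `ibd_genes="all"` covers every
gene at ~4 MB per gene.

## Estimators

Heritability recovery uses Haseman–Elston regression: standardize the
(residualized) trait, regress pairwise products zᵢzⱼ on 2Φᵢⱼ over pairs
with Φ > 0, clamp the slope to [0, 1].  Two refinements matter at this
sample configuration (697 people in 8 deep families):

* Pairs with Φ = 0 are excluded; they contribute no slope information and
  only dilute the regression.
* Centering at the grand mean couples every individual to the sample
  average; the induced attenuation of the slope is linear in the pair's
  summed kinship row sums, and with only 8 families it is not negligible
  (simulations at h² = 0.44 show plain HE averaging ≈ 0.436 with
  pedigree-to-pedigree wobble down to ≈ 0.41).  The regression therefore
  includes the pair's summed row relatedness as a nuisance covariate,
  which removes the attenuation (mean ≈ 0.442 under the same conditions).

The reported standard error treats pairs as independent, which overlapping
pairs violate mildly; across-replicate dispersion is the honest precision
measure and is what the validation suite reports.  REML would be more
efficient; HE regression was chosen for transparency and because it needs
nothing beyond ordinary least squares.

Q4's heritability is estimated after residualizing on its covariates
(age, sex, smoking); Q1's and Q2's residual heritabilities after
subtracting the simulator's own SNP genetic values (and, for Q1, covariate
effects) — the estimand is the residual h², so the known fixed effects are
removed first.

The genotype-by-smoking uplift is recovered by fitting
Q1 ~ dosage + smoker + dosage×smoker on simulated unrelated individuals
carrying the common KDR variant (MAF 0.165) and reporting the
interaction/main-effect ratio; its delta-method SE from a single fit of
50,000 individuals is ≈ 0.15, so recovery checks pool independent
phenotype replicates on the same genotypes — averaging the interaction and
main-effect coefficients separately and taking the ratio of the means,
which avoids the heavy tails a per-fit ratio inherits from its small,
noisy denominator.

## Problem sizes and determinism

The validation and acceptance computations run on the functional markers
only (160 unique variants) — SNP genetic values, and hence all phenotype
checks, are unchanged by the non-functional markers, and the full
24,487-marker map is exercised separately by the pipeline and its tests.
Heritability recovery uses 100 family replicates; the uplift regression
50,000 individuals with 40 replicate fits; smoking prevalence 200
replicates of 697.

Every stochastic stage draws from `default_rng` seeded by
SHA-256(master_seed, stage label, index) truncated below 2³¹.  Replicates
are therefore independently reproducible, streams never collide across
stages, and a full run is byte-reproducible from the manifest (master
seed + config digest + code version).

## Known limitations

* No linkage disequilibrium and no population structure in the founder
  panel; association tests on the synthetic data will not see the
  confounding or the same-carrier LD pairs present in real exome panels.
* The latent liability's residual heritability defaults to 0; analysts
  probing familial aggregation of disease beyond Q1/Q2/Q4 should raise it.
* HE standard errors from a single replicate are approximate (correlated
  pairs); use across-replicate dispersion.
* Pedigree structures are balanced constructions matching aggregate counts
  only; real extended pedigrees are less regular.
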