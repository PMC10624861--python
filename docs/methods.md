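# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `hlafinemap`, in the spirit of a statistical
software methods appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Nomenclature and genotype states

Allele names are parsed as `GENE*F1[:F2[:F3[:F4]]][X]` with fields kept as
zero-padded *strings* (IMGT field text is padded, and `"01"` must never
collapse onto `"1"`). Truncating to k fields drops the expression suffix
only when fields are actually removed; truncation is idempotent.

Genotypes carry one of three states. `called` (1–2 alleles), `no_call`
(QC failure: missing data) and `gene_absent` (a secondary DRB gene the
participant genuinely does not carry: zero dosage). The distinction
matters everywhere denominators appear: absent genes contribute zero
copies to dosage rows but are excluded from haplotype-frequency
denominators, while no-calls are missing in both.

## Coverage QC and DRB3/4/5 assignment

Calls are kept when mean reads at the diagnostic exon (exon 2; exon 3 for
HLA-DRB2/DRB8, which lack a second exon) are at least `min_reads` (default
20). The boundary is inclusive because "fewer than 20 reads" is what
defines poor coverage; 20 itself is acceptable.

Each DRB1 haplotype carries at most one of DRB3/4/5, so a participant has
0–2 secondary DRB copies and read depth at those genes, relative to DRB1,
tracks copy number. Per gene: coverage ≥ 60% of DRB1 *and* strictly more
than 20 reads ⇒ both candidate alleles; else ≥ 30% ⇒ the first candidate
allele (the first listed by the caller); else absent. The >20-read clause
attaches only to the 60% rule, as the rule is stated. Two collisions are
resolved explicitly because the rule alone can produce more than two
copies: when several genes qualify for the two-allele rule, the gene with
the higher coverage keeps both (ties broken DRB3 < DRB4 < DRB5) and the
rest are demoted to the single-allele rule; assignments past two total
copies are dropped in the same priority order.

Imputed dosages below the threshold (default 0.8; 0.66 liberal, 0.9
strict) are removed, as are `*99:01` sentinel alleles. Surviving dosages
round to copy counts at 1.5 (no rounding rule is standard; 1.5 is the
midpoint of the het/hom dosage means). More than two retained copies at a
gene is treated as inconsistent input, not silently truncated.

## Concordance

Per gene, concordance is the maximum multiset intersection of the
sequenced and imputed 2-field genotypes, summed over participants and
divided by 2N. Adjusted concordance removes sequenced alleles absent from
the imputation reference *allele-wise*: a participant contributes 0, 1 or
2 countable slots. Allele-wise (rather than participant-wise) exclusion
was chosen because the definition restricts "sequenced alleles", not
participants. The individual-specific frequency reported for mismatching
participants is the mean sequenced-allele frequency of their two alleles.

## Asymmetric LD

For haplotype frequencies h with margins p (gene A) and q (gene B),

W_{A/B} = sqrt( [Σ_ij (h_ij − p_i q_j)² / q_j] / (1 − Σ_i p_i²) ).

W_{A/B} is the fraction of gene A's allelic variation explained by
conditioning on gene B, normalized by A's heterozygosity; it is
direction-dependent (W_{A/B}=1 exactly when A is a deterministic function
of B) and reduces to |r| for two biallelic loci — the property the test
suite verifies against the closed form on random 2×2 tables. The two
directions are averaged for the gene×gene matrix. Alleles under 1%
frequency and unsequenced slots are pooled into one dummy allele first,
because sparse cells make the statistic unstable; pooling happens within
each analysis stratum.

Haplotype frequencies are estimated by a standard two-locus EM on
unphased genotypes: only double heterozygotes are phase-ambiguous (two
configurations, E-step weighted by products of current haplotype
frequencies). Initialization is the product of marginal allele
frequencies — deterministic, no random restarts — with tol 1e-8 on the
largest frequency update and at most 1,000 iterations; the observed-data
log-likelihood is asserted non-decreasing at every step. When phase is
unambiguous the EM reproduces direct counting exactly, which is the
test oracle.

## Firth association scans

Each marker is tested by logistic regression with the Jeffreys-prior
penalty l*(β) = l(β) + ½ log det I(β), which keeps estimates finite under
separation (routine for rare alleles) and removes leading-order
small-sample bias. Newton iterations use the modified score
U* = X'(y − π + h(½ − π)) with hat diagonals h, step-halving (up to 10) on
penalized-likelihood decreases, and converge when the free coefficients'
score max-norm drops below 1e-8 (≤100 iterations).

P-values are penalized likelihood-ratio tests. The null is *not* a
smaller design: the tested coefficient is constrained to zero inside the
full design so the Jeffreys penalties of null and alternative have the
same dimension — otherwise the ½ log det terms do not cancel and the test
is badly anti-conservative. The package's null-calibration experiment
(1,000 independent null markers, n=2,000, full covariates) measures the
realized rejection rate at α=0.05. Wald standard errors from the inverse
penalized information are reported alongside.

Scans run per ancestry with age, sex and PC1–PC10 as covariates, skipping
strata with fewer than 50 cases and markers below the minimum allele
count (default 1). Stratum results combine by fixed-effect
inverse-variance meta-analysis; the direction string follows the fixed
order AFR, AMR, EAS, EUR, SAS; Cochran's Q gets a χ²(k−1) p-value. The
genome-wide threshold is 5×10⁻⁸ divided by the number of phenotypes
(default 11); the heterogeneity flag uses 0.05 divided by the realized
number of meta-analyzed tests.

The study this package operationalizes ran its scans inside a
whole-genome-ridge/LOCO mixed-model framework to absorb kinship and
polygenic background. That machinery is deliberately replaced by plain
covariate-adjusted Firth regression: the synthetic cohorts are generated
unrelated, so kinship control would be untestable scaffolding here. This
is the package's one stated deviation from the analysis it mirrors.

Amino-acid expansion codes each (alignment column, residue) pair as a
one-vs-rest dosage marker, excluding columns containing a gap in any
allele (indels) and columns monomorphic among called alleles.
Participants carrying an allele missing from the alignment are missing
for that gene's residue markers. Conditional analyses append the
conditioning markers' dosages to the covariates and report
Benjamini–Hochberg q-values; tested markers collinear with a conditioning
marker are flagged undefined.

## Synonymous-variant heterogeneity

3-field alleles sharing a 2-field name encode identical proteins. For
each 2-field haplotype with at least one genome-wide-significant 3-field
allele, the lead (lowest p; ties by larger |β|, then marker id) is
compared to: every other significant allele, every non-significant
partner directly, and — when two or more partners are non-significant —
to their collapsed dummy burden allele, which is re-associated per
ancestry with the same covariates and meta-analyzed before the
comparison. Burden modes `sum` and `comphet` (capped at 2) coincide for
same-gene pooling because a participant carries at most two alleles of
one gene.

With only (β, SE) per side, Welch's degrees of freedom are not
computable; the comparison uses the normal reference (df→∞), which at
biobank sample sizes is indistinguishable from the t reference. The final
threshold is 0.05 / (number of pair tests performed). Categories follow
the convention that a pair is "opposite direction" or "same direction,
different magnitude" only when both sides are themselves significantly
associated; a heterogeneous pair whose partner association is not
significant is categorized as such rather than as a directional finding.

## Diversity and redundancy

Richness comparisons across cohorts of different sizes are biased by
discovery saturation, so expected unique-allele counts are computed by
repeatedly down-sampling participants without replacement (default
10,000 draws; 500 in tests and cross-checks, where the Monte-Carlo error
is measured against the exact hypergeometric expectation
E[unique] = Σ_a (1 − C(N−c_a, n)/C(N, n)) over carrier counts c_a).

The redundancy of sequenced dosages Y given imputed dosages X is the
Stewart–Love index: canonical correlations are computed by QR+SVD on the
standardized matrices, and the index sums ρ_k² weighted by the fraction
of Y's standardized variance carried by each Y-side variate. With all
variates retained this equals the mean over Y columns of the R² from
regressing each column on all of X — the independent oracle used in the
tests (agreement to 1e-8). Zero-variance and linearly dependent columns
are dropped (QR with column pivoting) with a log entry and the result
flagged. Redundancy is evaluated on an allele-frequency threshold grid
(>0.01%, 0.1%, 1%, 5%, 10%, 20% in the CLI default).

## Synthetic cohorts

The generator's defaults are fixed study conditions, not tuning knobs:

* five ancestries (AFR/AMR/EAS/EUR/SAS) with sizes 700/300/250/3,100/650 —
  a 5,000-participant toy cohort whose size ordering mirrors a
  European-dominated biobank;
* genes HLA-A, -B, -DRB1, -DQB1 (+ DRB3/4/5 via carriage), 5–10 3-field
  alleles per gene;
* haplotype pools are *explicit enumerated mixtures*: 25% extended
  all-gene core haplotypes, 35% a DR–DQ coupled block with other genes
  independent, 40% full independence. Enumerated pools (rather than
  copula-coupled marginals) give exact control of the LD targets the
  asymmetric-LD tests recover: strong DRB1–DQB1 coupling, weaker
  class-I/class-II background. Per-ancestry marginals are the baseline
  frequency vector rotated by the ancestry index, so ancestries share an
  allele universe but differ in ranking;
* DRB3/4/5 carriage follows a DRB1-protein map (03:01/13:01→DRB3,
  04:01/07:01→DRB4, 15:01→DRB5); exon coverage is drawn lognormal around
  gene means (DRB1 100×, others 80×, participant dispersion σ=0.15) with
  secondary-DRB coverage equal to (copies/2)·DRB1 times multiplicative
  noise σ=0.06, and a 5% background ratio at uncarried genes — inside the
  ≤10% noise band under which the copy-assignment heuristic is expected
  to recover ≥99% of participants, which the test suite measures;
* imputation miscalls each true allele copy with probability 0.25 below
  1% frequency and 0.05 otherwise, replaces it by a frequency-weighted
  allele from the reference universe (or the `99:01` sentinel at rate
  1%), always miscalls alleles outside the universe, and draws dosages
  around 0.95 (het) / 1.90 (hom) with σ=0.08 so that realized dosages
  straddle the 0.66/0.8/0.9 QC thresholds;
* phenotypes are Bernoulli with logit intercept −2.6 (≈7% prevalence) and
  default allele effects 0.8 on HLA-B*27:05:02 and 0.5 on
  HLA-DQB1*02:01:08, plus small age/sex/PC1 effects;
* the *synonymous-flip* scenario pins HLA-A*01:01:01 at +β and
  HLA-A*01:01:02 at −β (default β=0.3, allele frequency 5% each,
  n=20,000, single ancestry) with a balanced phenotype (prevalence 0.5),
  the standard design for power evaluation. An a-priori power calculation
  for these conditions: each allele's association z against the
  genome-wide gate is ≈6.5, so at least one allele passes the gate and
  the (always overwhelming) Welch pair test fires in ≈93% of replicates,
  whereas requiring *both* alleles to pass the gate caps near 56% — the
  detection event is therefore a significant pair test with
  opposite-signed estimates, regardless of the partner-significance
  category label.

The residue alignment is keyed by 2-field name (length 40, 1–3 mutations
per allele, one gap column per gene), which makes synonymous-consistency
(3-field siblings share one protein sequence) structural.

What the generator does **not** emulate: relatedness/kinship, genotyping
batch effects, reference-panel growth over time, read-level errors,
4-field (non-coding) variation, and realistic allele counts per gene
(real class I genes carry hundreds of alleles). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative assumptions, not performance on real biobank data.

## Problem sizes and determinism

The test suite uses the 5,000-participant cohort for integration
properties, n=200–20,000 for statistical recoveries, 500 draws for
Monte-Carlo cross-checks, and five replicates of the flip scenario;
`scripts/acceptance.py` uses 10,000 biallelic tables, a 1,000-marker null
calibration at n=2,000, and 30 flip replicates. All randomness flows
through `numpy.random.default_rng` seeded from a single configuration (or
CLI) seed; reruns are bit-for-bit identical, which the pipeline test
verifies by hashing stage outputs.

## Known limitations

* Exact Firth regression is used; the "approximate Firth" fast variant
  used by large-scale GWAS tools (null-model anchoring) is not
  implemented, so very large marker panels pay two Newton fits per
  marker.
* The EM treats the dummy (pooled/unsequenced) category as an ordinary
  allele; with heavy pooling the dummy haplotype mass can blur W toward
  its unpooled value.
* Welch comparisons ignore the (unknown) correlation between the lead and
  partner estimates from shared controls; with one-vs-rest coding at a
  single gene the estimates are nearly independent, but the statistic is
  mildly anti-conservative in principle.
* `comphet` burden mode is only meaningful for cross-gene pooling, which
  the collapse guard currently forbids (same 2-field haplotype required).
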