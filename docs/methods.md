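# Methods

## The model

A genome-wide polygenic risk score (PRS) aggregates GWAS effect sizes
over all of an individual's risk alleles. `pathprs` instead computes one
score per biological pathway: for individual *i* and pathway *k*,

    PRS_ik = Σ_{j=1..m_k} β_j · G_ij

where the sum runs over the *m_k* clumped ("independent") SNPs annotated
to pathway *k* that pass the P-value threshold, β_j is the GWAS effect of
SNP *j* expressed for the target panel's counted allele, and G_ij is the
dosage. Scores are standardized to mean 0, sd 1 (sample sd, ddof = 1)
per pathway.

### Pathway-aware clumping

Clumping is greedy index selection by ascending GWAS P: the index SNP is
retained and every member SNP on the same chromosome within the window
whose r² with the index reaches the threshold is discarded; repeat until
the set is exhausted. Run naively this must be repeated once per
pathway, because a SNP removed in one pathway may be the index of
another. The implementation instead does a single pass over all SNPs in
ascending-P order in which every SNP carries one membership bit per
pathway and an index clears the bits of linked SNPs *only in the
pathways the index itself belongs to*. Because a SNP's final bits equal
its bits at its own processing time, this is provably identical to
per-pathway greedy clumping; the greedy routine is kept in the code base
as an oracle and equality is asserted over randomized instances in the
test suite. Ties in P are broken by genomic position, then SNP id, so
results are reproducible. r² is the squared Pearson correlation of
mean-imputed dosages computed from the target panel itself. Defaults
follow common C+T practice: r² = 0.1, window = 250 kb, P ceiling = 1.

### Competitive enrichment P-values

The association of each pathway PRS (threshold 1) with the residualized
phenotype is an OLS fit of phenotype on score; its two-sided slope
P-value is P0. A background "pathway" of all genic SNPs is clumped the
same way, and N null sets of the matched size m are drawn uniformly
without replacement from it. Each null set is scored with the GWAS β of
its SNPs and regressed identically, giving P_1..P_N, and

    P_competitive = ( #{n : P_n < P0} + 1 ) / (N + 1)

with strict inequality (ties do not count) and a pseudo-count of one in
both numerator and denominator, so the smallest achievable value is
1/(N+1). The default N is 10,000; simulation-scale analyses here use
1,000.

Null associations are evaluated through an algebraic shortcut: with
centered β-weighted dosage columns, a null PRS is a column-sum, so its
correlation with the phenotype requires only per-SNP phenotype
covariances and the background Gram matrix. This is exactly — not
approximately — the same P-value as scoring each null set and fitting
the regression, which the tests verify, and it is what makes
1,000 permutations × hundreds of pathways feasible on one CPU. Null
draws use a per-pathway substream derived from (seed, CRC32 of the
pathway name), so results do not depend on pathway iteration order.

### Annotation

SNPs map to genes by closed-interval overlap on 1-based coordinates
after extending each gene 35 kb upstream and 10 kb downstream
(strand-aware: upstream means 5'). Pathways keep only genes present in
the gene table and are filtered to 10–2000 mappable genes by default.
Excluded regions (e.g. the MHC, chr6:25–34 Mb, constant
`MHC_GRCH37`; the APOE region chr19:44–46 Mb, `APOE_GRCH37`) blank SNPs
from background and pathways alike. The negative control shifts every
gene 5 Mb, wrapping modulo the chromosome length so pathway SNP counts
stay comparable; windows that would straddle a chromosome end are moved
whole to the start and logged rather than split.

### Subtype stratification

Pathways with competitive P < 0.05 on the training split are re-scored
at their best P-value threshold (grid {5e-8, 1e-5, 1e-3, 0.01, 0.05,
0.1, 0.2, 0.3, 0.4, 0.5, 1}; ties favour the larger threshold) and fed
to a Gaussian lasso on the 0/1 subtype label. The penalty minimizes
5-fold cross-validated MSE (a one-SE rule and an L1 logistic variant are
available). The split is stratified 80/20; enrichment, threshold
optimization, standardization parameters and the lasso all see training
data only. Performance is the squared Pearson correlation between
predictions and labels in the test split; constant predictions score 0.

Under pure noise the min-MSE rule returns a strictly empty model only
part of the time (the CV curve is nearly flat near the largest penalty),
which is why the one-SE option exists; the null behaviour of both rules
is characterized in the tests.

### Expression specificity and relevance scores

Specificity is each gene's expression divided by its total across
tissues; genes expressed nowhere must be removed first. Per tissue,
quantile 1 collects zero-expression genes and the remaining genes are
split into 10 equal-count bins by increasing specificity (ties and
remainders resolved by sorting on (specificity, gene id)), giving the
11-quantile gene sets. The top-quantile test reports the competitive P
of the q11 set; the linear test regresses −log10 competitive P on
quantile rank and reports the one-sided P for a positive slope.

Gene relevance scores are rank-normalized as (r+1)/(n+1) over the n
scored genes, with the largest raw score receiving r = n (normalized 1)
under the default ascending convention — the opposite convention is a
flag, since the source description of the "inverse ranking" is
ambiguous. Unscored genes get 0, and a pathway's relevance is the mean
over its member genes. Rank agreement uses Kendall's tau-b
(tie-corrected, appropriate for score vectors with many zeros), and
P-values are combined across tests with Fisher's method.

## Synthetic data

The genotype generator produces LD-blocked diploid dosages from a
haplotype copy model: SNPs within a block share one MAF drawn uniformly
from the configured range, and each haplotype allele copies its left
neighbour with probability q = sqrt(r²_target), making the expected
adjacent-genotype r² exactly r²_target inside blocks (decaying
geometrically with distance) and 0 across blocks. This emulates
block-wise LD and frequency spectra but not recombination hotspots,
population structure, relatedness or realistic human LD maps — so
passing benchmarks demonstrate correctness of the machinery, not
performance on any particular cohort.

Traits follow Y = Xβ + ε with X column-standardized, causal effects
β ~ N(0, h²) i.i.d. and noise variance var(Xβ)(1−h²)/h², the unique
scaling for which the genetic variance fraction equals h². (A commonly
printed shorthand for this noise term, sd = var(Xβ)(1−h²), is
dimensionally inconsistent; the variance form here is what any target
heritability requires.) The effect-size scale is arbitrary because the
noise is scaled to the realized genetic variance.

Causal architectures draw k causal pathways without replacement, assign
each an enrichment fraction uniform on {1%, …, 30%}, and mark
round(fraction × members) member SNPs causal (minimum 1). Every
pathway's true enrichment is its causal-member fraction — including
spillover through SNPs shared with causal pathways — and the true
ranking derives from it with average ranks on ties.

Subtype labels are Bernoulli draws from a logistic model whose linear
predictor is the standardized true-effect genetic score of the driver
pathways, with the logistic scale calibrated numerically (root-finding
on the empirical score distribution) so the score separates the two
labels by the requested number of standard deviations.

## Benchmark problem sizes

The packaged benchmark uses 5,000 SNPs in blocks of 10 (within-block
r² = 0.8, MAF 0.05–0.5), 1,000 tiled genes, 300 random 15-gene
pathways of which 50 are causal, a 10,000-sample base GWAS and a
disjoint 5,000-sample target, N = 1,000 permutations, h² ∈ {0.1, 0.5}
and 6 seeded repetitions per h². These sizes keep a complete run on a
single CPU in a few minutes while preserving the qualitative behaviour
of the full-scale design (tens of thousands of samples, ~4,000
pathways, N = 10,000); the rank agreement achieved at this scale is
computed, not assumed, by `scripts/acceptance.py` and the test suite.

## Numerical choices and edge cases

- Missing dosages are mean-imputed per SNP at scoring and LD time only;
  QC statistics always see the raw missingness. QC defaults: drop SNPs
  with missingness > 0.02, MAF < 0.01, or HWE exact P < 1e-8 (mid-P
  exact test on hard calls; the conservative non-mid variant is a flag).
- Odds ratios convert to β by natural log. Strand-ambiguous (A/T, G/C)
  SNPs are always dropped; allele complement is attempted before
  declaring a mismatch; β is negated when the effect allele matches the
  panel's uncounted allele.
- Association P-values come from the correlation form of the OLS slope
  t-test, floored at the smallest positive double; constant PRS columns
  are zeroed with a warning and refuse association.
- Monomorphic SNPs get r² = 0 against everything (they cannot clump),
  and GWAS reports β = 0, P = 1 for them.
- Logistic covariate residualization defaults to deviance residuals
  ("pseudo residuals"); response residuals — which are exactly
  orthogonal to fitted covariates — are a flag.
- All randomness flows from integer seeds through numpy Generators;
  per-pathway substreams make enrichment independent of iteration
  order, and the workflow manifest records every parameter, input hash
  and warning of a run.

## Known limitations

- LD is estimated from the target panel; very small target samples make
  clumping noisy.
- The null-set construction matches pathway size (m) only, not MAF or
  LD-score spectra.
- The shift control wraps rather than truncates genes at chromosome
  ends; a shifted gene can still overlap causal SNPs by chance, so an
  occasional seed shows no shift penalty.
- The generator's block-exchangeable LD understates long-range LD;
  absolute tau values from the benchmark are therefore comparable only
  across configurations of this generator, not to cohort studies.
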