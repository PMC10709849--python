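# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generators, and the numerical and design choices behind
`asbkit`.

## Allelic-imbalance model

The unit of inference is a biallelic heterozygous SNV with reference and
alternative read counts (ref, alt), n = ref + alt. Under the null of no
allele-specific binding the reference count is beta-binomial with success
probability fixed at 0.5 and overdispersion ρ:

    X ~ BetaBin(n, a, b),  a = b = ½(1/ρ − 1),  ρ ∈ [0, 1)
    Var X = (n/4)(1 + (n − 1)ρ)

The symmetric shapes follow from requiring mean ½ and the standard
intra-class correlation parameterization ρ = 1/(a + b + 1). ρ = 0 is the
binomial limit (the beta shapes diverge, so the implementation branches to
`binom` there). ρ = 1 would put all mass on 0 and n and has undefined
shapes; the fitting grid therefore stops at 0.9.

Tail probabilities are computed with `scipy.stats.betabinom`, which works
in log-gamma space; the test suite verifies it against an independent
direct log-gamma summation of the pmf to ≤1e−10 for n ≤ 500 across the
whole ρ grid.

**Two-sided p-value.** p = min(1, 2·P(X ≤ min(ref, alt))). Doubling the
lower tail of the minority allele count is well defined because the null is
symmetric; perfectly balanced counts give p = 1 by the cap. The p-value is
monotone non-increasing in |ref/n − ½| at fixed n and symmetric in
(ref, alt).

**Overdispersion fit (LSSE).** The empirical distribution is the histogram
of reference-allele ratios over B = 21 equal-width bins on [0, 1]
(configurable). The expected distribution for a candidate ρ is the
beta-binomial pmf at each observed depth mapped onto the same ratio bins
and averaged with the observed depth frequencies. The selected ρ minimizes
the sum of squared bin differences; ties break toward smaller ρ (the
argmin takes the first minimum on the ascending grid). Comparing on the
ratio scale rather than pooled counts is a documented choice: it puts
depths on a common axis and makes the expected histogram a proper average
over the depth distribution.

**Count filter.** Only SNPs with total reads strictly greater than 6 are
tested; shallower SNPs carry almost no information under either null. A
SNP with counts (0, 34) passes (total 34): the filter is on total depth,
not per-allele.

**Simulation FDR.** For each of S = 10 rounds (default, configurable),
null reference counts are redrawn at the observed depths under the fitted
ρ, and null p-values computed identically to the observed ones. For each
candidate threshold t (the unique observed p-values),

    FDR(t) = (mean over rounds of #{null p ≤ t}) / #{observed p ≤ t}

clamped to [0, 1]; the chosen threshold is the largest t with
FDR(t) ≤ 0.10 (default target). If none qualifies, no SNP is called. With
zero observed positives FDR is defined as 0 (vacuous). This estimator is
noisy at the extreme left tail when few SNPs are callable: with S rounds
the mean null count at the smallest observed p is estimated from S small
Poisson-like draws, so single spurious calls can occur at the nominal
rate. The per-seed realized-FDR ratio is therefore 0 or occasionally 1
when only one SNP is flagged; calibration claims in the tests are about
the mean over ≥20 seeded replicates with Monte-Carlo standard-error slack.

A single seeded `numpy` generator drives all rounds; the seed is recorded
in the detection sidecar.

## Motif scanning

PWMs are accepted as HOCOMOCO-style plain-text count matrices or MEME
minimal files. Count matrices become probabilities with a
background-distributed pseudocount (default 0.1, FIMO's convention):

    p[b, j] = (c[b, j] + 0.1·bg[b]) / (total[j] + 0.1)

Background defaults to uniform. Log-odds are log2(p/bg) in bits;
per-position information content is IC[j] = 2 + Σ_b p log2 p, in [0, 2]
bits under the uniform background.

**Exact score null.** Scores are discretized at 1/1000 bit (configurable)
and the distribution of the integer score sum of a background-drawn
width-w word is built by positionwise convolution; tail(s) = P(score ≥ s)
is exact under that discretization and verified against exhaustive 4^w
enumeration for w ≤ 8. Scanning uses the same integer matrix, so scan
scores and the null share one discretization.

**Pair scanning.** Both strands of both 41-bp windows are scanned at every
offset. A hit is significant iff its score p-value is strictly below 1e−4
and the motif span covers the center (the SNP). The anchor is the
maximal-scoring significant hit across both windows (ties: smaller offset,
then "+" strand, then the reference window); both windows are rescored at
the anchor so the score change compares aligned coordinates. Offsets
touching non-ACGT characters score −∞ and can never be hits. Strand
handling: the reverse strand is scored with the reverse-complemented
matrix, which makes scanning a window and its reverse complement produce
mirror-image hits with identical scores — a property test in the suite.

**Enrichment.** With n ASB and m ≥ n non-ASB scan results, each of 10,000
iterations draws n controls from the non-ASB pool without replacement and
counts in-motif members. z = (observed − control mean)/control SD
(SD with ddof = 1); p is the two-sided normal tail, with p = 1 at z = 0.
A degenerate control SD of 0 with a discrepant observation is flagged
(`degenerate_sd`) and the p-value reported at the double floor rather than
fabricating an infinite z. The control moments converge to the exact
hypergeometric moments, which the tests check at 3 Monte-Carlo standard
errors.

**Profiles and correlations.** The motif coordinate of a disrupted SNP is
center − offset on "+" hits and width − 1 − (center − offset) on "−" hits.
Disruption frequencies are kept as raw counts; the Pearson correlation
with IC and the high/low consistency ratio (fraction of positions on the
same side of their respective means, ties counted as high) are invariant
to positive affine rescaling. Groups with fewer than 3 records or zero
variance yield a flagged undefined correlation instead of a number.

## Annotation

cCRE intervals carry SCREEN-style labels; the class token is one of PLS,
pELS, dELS, DNase-H3K4me3, CTCF-only, DNase-only, with "CTCF-bound" kept
as a separate boolean modifier. A SNP overlapping several cCREs takes the
highest class by the order above (promoter-like before enhancer-like —
a conventional choice; the assignment must be unique). No overlap →
"unclassified"; unknown tokens are kept verbatim with a warning.

Region labels come from a native interval labeler over minimal transcript
models (GTF): UTR5/UTR3 (checked first, as refinements of exonic
sequence), then exon, intron, upstream_gene / downstream_gene within a
strand-aware 5 kb flank (configurable), else intergenic. Across multiple
overlapping genes the highest-precedence label wins. eQTL/GWAS tables
join by exact rsID; duplicates are dropped preserving first-seen order,
and SNPs without an rsID get empty lists.

## Synthetic data

`simulate_counts_dataset` emulates a ChIP-seq allelic-count table on a toy
genome (2 chromosomes × 100 kb, uniform composition): depths uniform in
[10, 60] (straddling the >6 filter), null SNPs beta-binomial at the
generating ρ, and a planted 10% of truly imbalanced SNPs drawn binomially
with odds uniform in [1.5, 5] and a random direction — the regime used
throughout the tests. `simulate_motif_windows` embeds the PWM consensus
across the window center and flips the center base to the column's weakest
base in the alternative window; background pairs are uniform random.
Everything is deterministic given the seed, and the writers emit the same
dialects the parsers read.

What the generators do **not** emulate: mapping bias (assumed removed
upstream), read-level error, non-uniform genomic background, linkage
between SNPs, peak structure, or overdispersion in the *planted* effects.
Passing tests therefore demonstrate correctness of the statistics under
the stated model, not robustness to alignment artifacts.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| count filter | total > 6 | strict inequality |
| ρ grid | 0.0 … 0.9 step 0.1 | 1.0 degenerate, excluded |
| LSSE bins | 21 | ratio histogram on [0, 1] |
| FDR target | 0.10 | largest threshold with FDR ≤ target |
| simulation rounds | 10 | null redraws at observed depths |
| window | ±20 bp (41 bp) | SNP at center index 20 |
| score p cutoff | 1e−4, strict | center-covering hits only |
| score granularity | 1e−3 bit | shared by scan and null |
| enrichment iterations | 10,000 | without replacement per draw |
| pseudocount | 0.1 × background | uniform background default |
| min MAPQ / base quality | 10 / 10 | pileup counting |
| region flank | 5,000 bp | upstream/downstream calls |

Test and acceptance runs use 2,000–20,000 simulated SNPs and 20 seeded
replicates, sizes at which the grid fit and FDR sweep are exact enough to
check recovery and calibration while the whole suite stays under a minute.

## Known limitations

- The simulation FDR is coarse when very few SNPs are callable (see
  above); increasing `n_sim_rounds` sharpens it at linear cost.
- Overdispersion is fitted on a 0.1-step grid, not by maximum likelihood;
  samples whose true ρ sits between grid points take the nearest SSE
  minimizer.
- The region labeler is transcript-naive (no consequence ranking) and the
  cCRE assignment ignores interval scores.
- Read counting assumes bias-filtered, deduplicated, indexed alignments;
  no remapping or duplicate marking is performed.
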