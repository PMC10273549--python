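# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Map-to-pan construction

Per-accession assembled contigs are compared to the reference with an
internal seed-and-extend aligner: exact k-mer anchors (k = 21 by default,
k ≥ 11 required) are grouped per (reference sequence, diagonal), chained when
overlapping or adjacent, and extended without gaps under an x-drop rule
(match +1, mismatch −2, drop 20); trailing mismatches are trimmed back to the
score maximum. Identity is matches / aligned columns. Both strands are
searched; coordinates are always reported on the forward contig. The aligner
is deliberately ungapped — adequate for high-identity contig-to-reference
comparison on data without structural rearrangement inside a contig — and a
7-column alignment TSV from an external aligner can be substituted (both
0-based half-open and 1-based inclusive `show-coords` dialects are read).

Classification thresholds read as strict "exceeding": a block is *reliable*
iff identity > 0.90 **and** aligned length > 300 bp. A contig with at least
one reliable block is aligned; the complement of the union of its reliable
blocks (unreliable blocks are ignored) yields candidate non-reference
segments, kept when longer than 500 bp. Contigs with no reliable block are
emitted whole. Contigs shorter than 500 bp are removed before any of this.

Redundancy removal is a single greedy longest-first pass (length descending,
id ascending on ties): a segment is discarded iff ≥ 90% of its length aligns
at ≥ 90% identity to an already-retained segment. The pass is idempotent, so
the "multiple rounds until convergence" formulation collapses to one
deterministic sweep. Identity for this rule is computed over the aligned
region, with the 90%-of-length condition carrying the coverage requirement —
the alternative (identity over the whole sequence) would double-count the
coverage criterion. A label-based contamination filter (keep/drop per segment
id, unlabelled segments kept) stands in for taxonomic screening, which needs
external databases.

## PAV calling and occupancy

The loss rule follows SGSGeneLoss semantics: with per-position depth from a
3-column TSV (positions absent from the table count as depth 0), the covered
fraction of a gene's region — exon union when exons are annotated, else the
gene span — is the fraction of positions with depth ≥ `minCov` (2 reads);
the gene is *lost* iff that fraction is < `lostCutoff` (0.2). A covered
fraction of exactly 0.2 is therefore *present*. The looser published phrasing
("lost when 20% of its region has less than 2 reads") reads instead as lost
iff the uncovered fraction ≥ 0.2; the two differ only at the boundary and the
alternative is available via `PAVParams(strict_uncovered=True)`.

Occupancy classes partition genes by presence frequency *f* with half-open
boundaries: core *f* = 1; softcore 0.99 ≤ *f* < 1; shell 0.01 ≤ *f* < 0.99;
cloud *f* < 0.01. A gene exactly at 0.99 is softcore and exactly at 0.01 is
shell. With 400 accessions, 399/400 = 0.9975 is softcore and 3/400 = 0.0075
is cloud, matching the published class structure; whether a study counts
softcore from 1 − 1/n or from a rounded 99% only moves genes at the boundary
and is configurable through `softcore_min`. Genes absent in every accession
are classified cloud and additionally reported by
`PAVMatrix.all_absent_genes()` rather than silently dropped. Raising `minCov`
can only shrink covered fractions, so it never converts an absent call to
present (tested).

## Selection scan

For each gene, presence counts in two groups form a 2×2 table tested with
the two-sided Fisher exact test under the probability-mass criterion (the sum
of hypergeometric probabilities of tables, at fixed margins, no more probable
than the observed one); `scipy.stats.fisher_exact` provides this and is
checked exhaustively against a brute-force enumeration oracle for all tables
with group sizes ≤ 15. Benjamini–Hochberg step-up FDR is applied across
tested genes. Genes absent in both groups carry no information and are
excluded from testing (returned flagged, with NaN statistics).

A gene is *selected* iff |log₂(freq_A/freq_B)| > 2 and FDR < 0.001; a raw-p
threshold is available as a config alternative (`use_raw_p`), since both
appear in the literature this workflow follows. For the fold change only, a
zero frequency is replaced by 1/(2n) of its group — keeping the statistic
finite and monotone in the observed gap — while the test always uses raw
counts. Selected genes are *favorable* when the higher frequency is in the
more-derived group of the comparison (cultivar over landrace over wild
relative), *unfavorable* otherwise; favorable and unfavorable partition the
selected set, and swapping group labels swaps the directions without touching
p-values.

## PAV-GWAS

Shell genes are the genotypes (present = 1). Genes whose presence-frequency
spread (min of f, 1−f) is below 0.01 — including constant genes — are flagged
untestable and excluded from the test count, mirroring MAF filtering.
Population structure is adjusted with principal components of the genotype
matrix (10 by default, following common practice; an external covariate table
can be supplied instead — the original study used SNP-based components,
which require data outside this package's scope).

Each gene is evaluated with a 1-df score test of adding its genotype to the
covariate-only null model. This single-locus GLM is a documented stand-in for
multi-locus programs such as FarmCPU: the contribution being exercised is the
PAV-as-genotype encoding and the Bonferroni threshold (alpha / n_tested,
0.05/6161 ≈ 8.1e-6 at the published scale), not the iterative locus-selection
machinery. Two phenotype treatments are implemented:

- **linear** (default, also for 0/1 phenotypes): Gaussian score test with the
  residual variance estimated from the null fit. Treating coded phenotypes
  numerically is what single-locus GWAS tools conventionally do, and at desk
  scale (tens of accessions, 10 covariates) it keeps the family-wise error of
  the Bonferroni scan controlled — measured at 0.005–0.02 under permuted
  phenotypes — while a fully penetrant causal gene at n = 40 reaches
  p ≈ 7e-8.
- **logistic** (`GwasParams(binary_model="logistic")`): binomial null fitted
  by Firth's penalised likelihood (which keeps fitted probabilities away from
  0/1 under quasi-separation, frequent at these sample sizes), tail
  probabilities by a saddlepoint approximation of the score distribution
  (calibrated for unbalanced case/control splits where the χ² tail is not).
  Because the penalised null is not the exact MLE, the score numerator uses
  covariate-adjusted genotypes; without that adjustment genes correlated with
  the covariates acquire grossly inflated statistics. Even with both
  corrections this path remains mildly anti-conservative below roughly 100
  accessions (family-wise error ~0.08–0.16 at n = 40 with 10 PCs), which is
  why it is not the default.

The reported effect is the one-step estimate U/V; significance is
p < alpha / n_tested with n_tested recalculated from the genes actually
tested.

## RGA and QTL summaries

Occupancy collapses to two groups: *variable* (cloud + shell) and *core-group*
(core + softcore). The crosstab is subfamily × location (reference vs
additional pan-genome contigs) with totals, and is additive by construction:
subfamily rows sum to the totals row, reference + additional = pangenome, and
variable + core-group = total in every cell. `annotations_from_counts`
expands a published count summary into synthetic per-gene rows so the
crosstab logic can be exercised against printed totals. The NBS-LRR pool is
taken as every subfamily that is not RLK, RLP or TM-CC
(CN, CNL, NBS, NL, TN, TNL, TX, OTHER): with the shipped watermelon counts
this reproduces the published variable-gene percentages exactly
(106/661 = 16.0% overall, 12/44 = 27.3% RLP, 37/417 = 8.9% RLK,
35/80 = 43.8% NBS-LRR).

Gene–QTL intersection uses half-open 0-based arithmetic (an overlap requires
≥ 1 shared bp, so [500,600) does not touch [50,500)) via a sorted sweep per
chromosome, verified against a brute-force all-pairs oracle on random
fixtures. Densities are genes per Mb per chromosome per subfamily, with
unplaced genes reported separately. Variant-consequence tallies compute, per
gene, the fraction of accessions with at least one consequence record and the
composition by consequence type, ranked by frequency with gene-id tie-break.
The QTL BED shipped with the package is a synthetic stand-in: the published
coordinates of the three gummy-stem-blight QTLs are not available here, so
three intervals on chr3/chr5/chr7 were chosen to reproduce the reported
totals (18.5 Mb across three chromosomes, mean 6.2 Mb).

## NG86 Ka/Ks

Population SNPs (substitutions only; indels are rejected, and a SNP whose
stated reference base disagrees with the CDS is an error naming the gene and
position) are collapsed into one alternate haplotype per gene; per-accession
haplotypes are a deliberate non-goal since the source workflow does not state
its construction. For each codon, each position contributes the fraction of
its three possible changes that preserve the amino acid; changes creating a
stop codon count as nonsynonymous, so synonymous + nonsynonymous sites equal
the coding length. Site counts are averaged over the two sequences (the
classical Nei–Gojobori treatment, which makes results symmetric under
swapping reference and alternate); counting on the reference alone — the
convention of some simple population scripts, asymmetric but occasionally
expected — is available via `sites="reference"`. For a single G→A change in
a glycine run the two conventions give dN ≈ 0.1827 and ≈ 0.1885 respectively;
dS for the synonymous example (≈ 0.4408) is identical under both.

Observed differences in multi-hit codons are averaged over all minimal
mutational pathways, excluding pathways through stop codons (all pathways are
used if every one is blocked); codons containing a stop in either sequence
are excluded from counting and reported. Proportions pS = Sd/S and pN = Nd/N
are corrected with Jukes–Cantor, d = −¾ ln(1 − 4p/3), undefined at p ≥ ¾
(flagged as saturated). The ratio dN/dS is flagged undefined when dS = 0 or
either rate is saturated. Site and difference counting are verified against
an independent pathway-enumeration oracle over all 61 × 61 sense-codon pairs.

## Synthetic data

The generator emulates, at desk scale, a resequencing cohort of a
domestication series. Defaults: 40 reference genes of 600 bp evenly spaced on
one chromosome (400 bp spacers), 10 novel genes of 800 bp, and three groups —
CM 15, CL-landrace 20, CL-cultivar 25 accessions (60 total; the source cohort
had 400, which is not tractable or necessary for correctness testing). The
default presence design assigns 60% of reference genes as core, 15% shell
(absence frequency 0.5 everywhere), 15% selection-like (absence 0.9 in the
wild group, 0.5 intermediate, 0.05 in the cultivar group — an ~8-fold
presence-frequency gap), 10% cloud-like (absence 0.97); novel genes are
shell-like at 0.5. Per-position depth is Poisson with mean 10 for present and
0 for absent genes (`depth_noise="constant"` switches noise off), stressing
the minCov = 2 boundary from both sides; contigs for present reference genes
are exact reference substrings ± 200 bp flanks with 1% substitution noise
(exercising the 90% identity rule without violating it), and novel-gene
carriers receive the novel sequence as its own contig. Novel sequences are
random at GC ≈ 0.35 and post-processed to share no 21-mer with the reference,
which guarantees the internal aligner classifies them fully unaligned. The
phenotype is binary: the first shell gene's presence, XOR a configurable flip
probability (0 by default). CDS inputs for Ka/Ks are random sense-codon
sequences with substitution SNPs at rate 0.01/bp.

The generator is byte-deterministic under a fixed config (verified by file
hashing) and does **not** emulate: read-level sequencing (FASTQ), assembly
errors or fragmentation, repeats and segmental duplication, heterozygosity or
copy-number states, mapping bias, or linkage disequilibrium between gene
PAVs. Passing tests therefore demonstrate the correctness of the decision
rules and statistics under clean, well-separated signals — not robustness to
assembly artefacts or repeat-induced mismapping on real data.

For scan-scale studies where sequence simulation is unnecessary,
`simulate_pav_matrix` draws a PAV matrix directly from per-gene per-group
presence frequencies. The recovery studies use it at 1,000 genes with 40
accessions per group (50 planted 8-fold gaps), and the GWAS study uses 200
genotypes × 40 accessions with 150 phenotype permutations — sizes chosen so
the whole reproduction script runs in well under a minute while leaving
binomial sampling error small relative to the tested margins.

## Known limitations

- The internal aligner is ungapped; indel-containing homology is reported as
  separate blocks and may split reliable alignments. Real-data use should
  supply external alignment TSVs.
- PAV calling assumes depth tables are complete where coverage exists;
  positions missing from the table are depth 0 by contract.
- The GWAS stand-in is single-locus; it does not re-implement FarmCPU's
  multi-locus model selection, and the logistic path is mildly
  anti-conservative at small n (see above).
- Ka/Ks collapses population SNPs to one alternate haplotype; segregating
  sites within the population are treated as fixed differences, which
  overstates divergence at low allele frequencies.
- The shipped QTL BED is a synthetic stand-in reproducing published totals,
  not the true QTL coordinates.
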