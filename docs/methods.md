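# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `asbscan`.

## Allele-specific binding model

At a biallelic heterozygous SNV covered by CUT&RUN reads, the alternate
read count is modelled as `n_alt ~ Binomial(n, θ)` with `n = n_ref +
n_alt`. The null of equal binding is `θ = 0.5`; the two-sided p-value is
the doubled smaller exact tail, `min(1, 2·min(P(X ≤ k), P(X ≥ k)))`. This
construction is symmetric in the alleles and matches exhaustive tail
enumeration exactly (tested to n = 12, and by construction for all n since
the tails come from the exact binomial CDF). Counts from samples sharing
the same anti-TF antibody are summed before testing; per-site provenance
is retained.

Multiple testing uses Benjamini–Hochberg step-up within each TF's tested
site set. ASB resources of this kind are reported as per-TF catalogs, so
per-TF adjustment is the default; a pooled mode (`per_tf_bh=False`) is one
flag away. Sites need ≥ 20 summed reads to be tested (configurable).

Tier definitions, applied after all filters:

| tier            | rule                                         |
|-----------------|----------------------------------------------|
| putative        | p < 0.1 and max/min count ratio ≥ 1.2        |
| likely          | putative and motif-concordant                |
| high_confidence | BH q < 0.2 and motif-concordant              |

"Fold change ≥ 1.2" is interpreted as the larger/smaller count ratio; a
zero count gives an infinite ratio and passes the gate. A site with
unclassifiable concordance can reach at most the putative tier.

### IgG artifact filter

A site is removed when the same two-sided binomial rejects at α = 0.01 in
any single IgG control sample **or** in the sum over all IgG samples.
Antibody-free controls should show no allelic preference; imbalance there
indicates copy-number variation or other technical artifacts. No minimum
depth guard is needed: below 8 total reads the doubled-tail p cannot fall
under 0.01.

### Mapping-bias filter

For each candidate site, 100 reads of length 70 are drawn per allele with
start offsets uniform over the 71 legal positions in the 140-bp window
centered on the SNV. Offsets are shared between alleles (common random
numbers), so the allele base is the only difference — this removes
sampling noise from the comparison; with 100 reads the distinction from
independent draws is immaterial. A site is dropped when
`|mapped_ref − mapped_alt| / max(mapped_ref, mapped_alt) ≥ 0.2` (the
denominator choice is configurable; the larger count is the default), or
when nothing maps for either allele.

The built-in mapper indexes all genome k-mers at the read length (both
strands) and counts a read as mapped iff it has exactly one match.
Matching is *allele-aware*: a read overlapping the SNV also matches
genome locations carrying the other allele at that single position. This
mirrors what a mismatch-tolerant aligner does when alternate-allele reads
are mapped to a reference-backed genome — without it, alternate reads
from perfectly unique loci would count as unmapped and every site would
be dropped. The mapper is adequate for error-free synthetic reads against
synthetic genomes; for real genomes, `mapping_bias_screen` accepts a
callable that wraps any aligner (reads in, mapped count out).

### Motif scoring and concordance

PFM counts become probabilities via `(count + pseudocount·background) /
(colsum + pseudocount)` with pseudocount 0.1 and uniform background by
default; scores are log2 odds against the background. Match p-values —
`P(score ≥ s)` for a random background sequence of motif length — are
exact: scores are discretized at 1e-3 log2-units per step and the total
score distribution is built by convolving per-position distributions
(verified against brute-force enumeration for motif lengths ≤ 6). At a
het site, every placement overlapping the SNV (`[pos−L+1, pos+L−1]`, both
strands) is scored for each allele; the per-allele summary is the best
match's −log10 p. A site is motif-overlapping when at least one allele
reaches p ≤ 1e-3 (FIMO-style threshold); the raw best score is used for
the delta even when below threshold. Concordance compares
`sign(Δ(−log10 p))` with `sign(n_ref − n_alt)`: equal signs (both
nonzero) are concordant, opposite discordant, anything else unclassified.
One cognate motif is assigned per TF via a small mapping table (the same
motif may serve two related TFs).

## Genomic-context statistics

Context labels use precedence promoter > exon > intron > intergenic, with
the promoter window spanning 2000 bp upstream to 500 bp downstream of any
TSS in transcription orientation (the window is a package default — no
standard definition exists — and is configurable).

Promoter buffering is tested three ways on the called table: (i)
two-sided Mann–Whitney on |log2fc|, promoter vs intergenic; (ii)
Mann–Whitney on the putative-ASB indicator among sites with ≥ 20 reads;
(iii) the F-test for the context term in OLS
`|log2fc| ~ context + log10(depth) + tf`. Infinite |log2fc| (a zero
count) is capped at `log2(depth)+1`; the cap only matters for the OLS —
rank tests are unaffected because capped values stay extreme.

Occupancy analysis counts distinct TFs with a peak overlapping a
2.5-kbp window centered on the site (10 kbp for the HOT-region mode,
which compares |log2fc| in top-decile-occupancy windows vs the rest).
Empirical gene-set enrichment counts ASB sites within 50 kbp of target
gene bodies and compares against draws of equally many random expressed
genes, with the +1 pseudo-draw correction so p ∈ [1/(n+1), 1]. Overlap
tests are exact Fisher (point-probability two-sided rule, or upper tail).
The SNV-class binding test counts class SNVs in peaks per replicate
against a seeded equal-size downsample of the comparison class and runs a
paired one-sided t-test across replicates (pairing is the package's
choice; the procedure compares two counts within each replicate).

## Screen statistics

Directional gene-level p-values from an upstream rank-aggregation tool
are combined by Fisher's method, `ψP = exp(−x/2)(1 + x/2)` at
`x = −2(ln p1 + ln p2)` — the closed-form df-4 χ² survival. Because the
two directions are computed on overlapping cell populations, ψP is a
*pseudo* p-value and is calibrated by simulation rather than interpreted
directly: assuming unexpressed genes are true negatives and T expressed
genes are true positives, false positives are drawn Bernoulli(f) over the
non-true genes for each f on a grid, the f matching the observed
unexpressed fraction among hits is selected (mean |simulated − observed|
over `n_sims` draws), and FDR = simulated FP / observed hits, reported as
a range over the T grid. This estimator is a reconstruction: the
published description gives the idea (match the unexpressed fraction; a
range of assumed true positives) but not the estimator's exact form.

Cross-platform combination uses weighted Stouffer
(`Z = Σ w z / sqrt(Σ w²)`, weights = total cells / number of guides per
dataset; one-sided p's combined separately, two-sided = doubled smaller),
Hedges g with equal-variance pooling and small-sample factor
`J = 1 − 3/(4(n1+n2)−9)`, and effect averaging after per-platform
Z-normalization.

Pseudotime tests: per dataset, one-sided Mann–Whitney of target-cell
pseudotimes against all other single-guide cells, Stouffer-combined. The
window-enrichment scan fits Gaussian KDEs (Scott bandwidth) to all cells
and to target cells, evaluates both at 40 evenly spaced positions over
the pooled range, rolls a 10-position window, tests target > all
densities one-sided per window, combines across datasets by Stouffer
weighted by target-cell count, and reports −log10 p clipped at 4, with a
20-cell floor per dataset. The LOWESS residual test (frac 0.3) subtracts
the pseudotime-expected marker expression and t-tests residuals per
target against all other cells, with BH across targets.

**Known limitation — window-enrichment null.** The rolling
Mann–Whitney-on-KDE scan is descriptive, not a calibrated test. Within
windows where the density is locally flat (modes, the valley between
progenitor and differentiated populations), both KDE curves vary less
across the window than the sampling error of the target-cell KDE, so a
chance excess produces complete rank separation and a per-window p as
small as 1/C(20,10) ≈ 5×10⁻⁶. Measured on null targets, the maximum
per-window −log10 combined p reaches 2 in roughly half of seeds. The
clipped enrichment profile is therefore useful for *localizing* where a
real shift acts (the shift tests above establish that it acts), and the
acceptance script reports the measured null exceedance rate rather than
assuming calibration.

## Synthetic-data generator

The generator emulates the pipeline's inputs on a single ~100–400 kbp
contig: random A/C/G/T sequence; gene models with TSS, strand, exons,
expression flags and set labels; strong-consensus PFMs (85:5:5:5 columns)
per TF written in JASPAR format; and evenly spaced het sites (≥ 120 bp
apart so 140-bp windows stay disjoint) assigned to categories:

* **motif sites** — the TF's consensus is written into the genome with
  the SNV at the central position; ref is the consensus base, alt the
  worst base. The allelic ratio follows a logistic link
  `θ = 1/(1 + exp(−β·Δ))` with Δ the alt−ref score difference in bits and
  β = 0.5/bit, so motif disruption drives binding loss and concordance
  tests have signal. The link and slope are generator constructs (no
  published model ties motif bits to allelic ratios).
* **plain ASBs** — θ = planted_ratio (alternating direction), applied to
  all TF samples.
* **CNV artifacts** — the same imbalance in TF *and* IgG samples.
* **mapping traps** — two extra copies of the alt-substituted 140-bp
  window are planted elsewhere, which makes every alt-carrying read
  multimap while SNV-covering ref reads stay unique. Two copies, not one:
  with a single copy, alt reads overlapping the SNV would map uniquely
  *at the copy* and the filter would see no asymmetry.
* **null sites** — θ = 0.5.

Depths are uniform over `depth_range` per (sample, site); DP4 counts draw
`n_alt ~ Binomial(depth, θ)` with each allele's forward-strand count
Binomial(n, 0.5) — strand balance is not used by any downstream test.
Per-sample VCFs include decoy homozygous and indel records to exercise
the intake filters. All randomness flows from numpy Generators seeded
with `[seed, stage]`; identical configurations give byte-identical files
(sample sheets store VCF paths relative to their own directory for this
reason).

The screen/cell generator draws directional p-values Uniform(0,1) for
null genes and deflates the favoured direction pair (U(0, 5e-4)) for true
hits, which are always expressed; positive controls are a mix of true
hits and expressed non-hits. Pseudotimes come from a two-component Beta
mixture (Beta(2,5) progenitor / Beta(5,2) differentiated, equal weights);
a knockout "shift" moves the mixture weight, preserving stochastic
ordering. The marker follows a late-differentiation bump
(`2·exp(−((t−0.7)/0.25)²)`) plus Gaussian noise, with additive planted
effects per target.

The ASB-statistics fixture (`simulate_asb_table`) draws latent allelic
effects `|log2 odds| = 0.4 + Exp(0.8)` for imbalanced sites (30% of
sites are exactly balanced) and materializes counts at uniform depths
20–500. The 0.4 floor encodes that a bona fide ASB carries at least a
fold-change-gate-sized effect (the putative tier requires ratio ≥ 1.2,
i.e. |log2fc| ≥ 0.26); promoter attenuation multiplies the latent effect
before counts are drawn.

### What the generator does not emulate

Read-level sequencing error, fragment-length and GC structure, linkage
between nearby sites, overdispersion beyond binomial counts (real ASB
data show extra-binomial variance), donor genotype structure, and peak
calling. Passing tests therefore demonstrate correctness of the
statistics and filters under their stated models, not robustness to those
real-data features.

## Problem sizes used in validation

Parameter recovery runs 2200 sites (200 planted ASBs at θ = 0.7, depth
100) per seed, pooled over six fixed seeds — the exact discrete null
rejection rate at depth 100 is 0.0886, and pooling brings the
measurement's standard error to ~0.003 so the check is decisive. The
mapping-bias check uses 100-site genomes over three seeds; concordance
240 sites with 30% motif sites across three TFs; buffering 500 sites;
the screen FDR check 4000 genes with 150 true hits at ψP cutoff 0.1.
These sizes keep the full validation under a minute while leaving
comfortable statistical margins.
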