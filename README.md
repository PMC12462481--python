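# asbscan

Allele-specific transcription-factor binding (ASB) analysis for
population-sampling CUT&RUN, together with the companion statistics used to
call and calibrate regulator screens: pseudo-P combination of sorted-screen
enrichments, simulation-based FDR, and pseudotime-based knockout tests.

## The problem

When CUT&RUN libraries are collected from many unrelated donors, every
heterozygous SNV inside a binding site becomes a tiny internal experiment:
if a transcription factor binds the two alleles equally, reads should cover
them 1:1. At a het site with summed allele depths (n_ref, n_alt), the
package tests

  n_alt ~ Binomial(n_ref + n_alt, 0.5)

with a two-sided exact binomial p (doubled smaller tail, capped at 1) and
Benjamini–Hochberg FDR within each TF. Apparent imbalance has several
non-biological causes, which the pipeline removes in order:

1. **Exclusion regions & mitochondria** — structural-variation and
   blacklist BED intervals, chrM.
2. **IgG artifacts** — sites with binomial p < 0.01 in any antibody-free
   IgG control, or in the sum of all IgG controls, are discarded
   (copy-number imbalance masquerading as ASB).
3. **Mapping bias** — 100 reads of length 70 are drawn per allele from the
   140-bp window centered on the SNV and mapped back to the genome; sites
   whose mapped-read counts differ by ≥20% between alleles are dropped.
4. **Motif concordance** — each allele is scored against the TF's cognate
   position-weight matrix (exact p-values by dynamic programming over the
   discretized score distribution); a site is *concordant* when the allele
   with the stronger predicted motif also carries more reads.

Calls are tiered: **putative** (p < 0.1 and allelic fold change ≥ 1.2),
**likely** (putative + concordant), **high-confidence** (q < 0.2 +
concordant).

Because the real donor data are access-controlled, the package ships a
first-class synthetic-data generator (`asbscan.synthetic_data`) that
produces genomes, per-sample VCFs with DP4 depths, JASPAR motifs, gene
models, screen tables and cell tables — with planted ground truth — so
every statistical property of the pipeline is testable end to end.

## Worked example

Generate a synthetic dataset (3 TFs × 2 replicates + 4 IgG controls over 80
het sites) and call ASBs:

```bash
asbscan simulate --out demo --seed 3 --n-sites 80 --genome-length 70000
asbscan call --samples demo/samples.tsv --genome demo/genome.fa \
    --motifs demo/motifs.jaspar --motif-map demo/motif_map.tsv \
    --genes demo/genes.tsv --exclude demo/exclude.bed --seed 3 --out demo/
```

The run summary prints per-stage record counts:

```json
{
  "intake":       {"tf_records": 480, "igg_records": 320},
  "igg_filter":   {"excluded_sites": 7, "tf_records": 438},
  "aggregate":    {"pairs": 219},
  "mapping_bias": {"sites_tested": 73, "sites_dropped": 2, "pairs": 213},
  "tiers":        {"putative": 24, "likely": 0, "high_confidence": 12}
}
```

Reading: 80 sites × 6 TF samples minus decoy records gives 480 het-SNV
intake records; 7 sites are imbalanced in IgG (the planted copy-number
artifacts plus chance hits) and leave 438 records; summing replicates per
antibody gives 219 (TF, site) pairs; the read-simulation filter drops the 2
planted duplication traps; tier counts follow the p/q/fold-change/
concordance rules. `demo/asb_calls.tsv` holds one row per (TF, site):

```
tf   contig  pos   ref alt rsid    n_ref n_alt p_binom q      log2fc ratio ...
JUN  chr1    312   T   G   rs1000  327   347   0.464   0.847  -0.086 1.061
```

The same statistics are available as library calls
(`asbscan.call_asb`, `asbscan.binom_two_sided`,
`asbscan.screen_stats.fisher_combine_pseudo_p`, ...); `asbscan screen` and
`asbscan cells` expose the screen and pseudotime layers.

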