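"""Allele-specific binding (ASB) statistics and the calling pipeline.

The core test asks whether reads at a heterozygous SNV are drawn equally
from the two alleles: under the null, the alternate-allele read count is
Binomial(n, 0.5) and the two-sided p-value is the doubled smaller exact
tail, capped at 1.  Candidate sites pass through, in order: exclusion-region
and mitochondrial filters, removal of sites imbalanced in IgG controls
(copy-number and other technical artifacts), per-antibody aggregation, a
minimum-depth floor, the binomial test with Benjamini-Hochberg FDR within
each TF, a simulated-read mapping-bias filter, allele-specific motif-delta
scoring, and finally tier classification:

* putative        — uncorrected p < 0.1 and allelic fold change >= 1.2
* likely          — putative and motif-concordant
* high_confidence — BH q < 0.2 and motif-concordant
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from . import mapping_bias as mb
from . import motif_scan as ms
from . import variant_io as vio

logger = logging.getLogger("asbscan")

TIER_NONE = "none"
TIER_PUTATIVE = "putative"
TIER_LIKELY = "likely"
TIER_HIGH = "high_confidence"

ASB_TABLE_COLUMNS = [
    "tf", "contig", "pos", "ref", "alt", "rsid", "n_ref", "n_alt",
    "p_binom", "q", "log2fc", "ratio", "motif_delta", "concordance",
    "tier", "context", "n_samples",
]


# ------------------------------------------------------------- primitives

def binom_two_sided(n_ref: int, n_alt: int) -> float:
    """Two-sided exact binomial p for counts against a fair 0.5 null.

    Defined as ``min(1, 2*min(P(X<=k), P(X>=k)))`` with ``k = n_alt`` and
    ``n = n_ref + n_alt``; symmetric in its arguments.
    """
    n = n_ref + n_alt
    if n < 1:
        raise ValueError("binom_two_sided requires at least one read")
    k = n_alt
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def binom_two_sided_vec(n_ref, n_alt) -> np.ndarray:
    """Vectorised :func:`binom_two_sided`."""
    n_ref = np.asarray(n_ref, dtype=np.int64)
    n_alt = np.asarray(n_alt, dtype=np.int64)
    n = n_ref + n_alt
    if np.any(n < 1):
        raise ValueError("binom_two_sided requires at least one read")
    lower = binom.cdf(n_alt, n, 0.5)
    upper = binom.sf(n_alt - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def fold_change(n_ref: int, n_alt: int) -> tuple[float, float, bool]:
    """(ratio, log2fc, passes_fc) for an allelic count pair.

    ``ratio`` is larger/smaller count (+inf when the smaller is 0);
    ``log2fc`` is log2(n_ref/n_alt), signed toward the reference allele;
    ``passes_fc`` is the >=1.2 ("fold change > 20%") gate.
    """
    if n_ref + n_alt < 1:
        raise ValueError("fold_change requires at least one read")
    lo, hi = min(n_ref, n_alt), max(n_ref, n_alt)
    ratio = math.inf if lo == 0 else hi / lo
    if n_alt == 0:
        log2fc = math.inf
    elif n_ref == 0:
        log2fc = -math.inf
    else:
        log2fc = math.log2(n_ref / n_alt)
    return ratio, log2fc, ratio >= 1.2


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, aligned to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- IgG filter

def igg_artifact_sites(
    igg_records: Iterable[vio.AlleleDepth], alpha: float = 0.01
) -> set[tuple]:
    """Sites allelically imbalanced in any IgG sample or in their sum.

    Such imbalances in antibody-free controls reflect copy-number variation
    or other technical artifacts rather than TF binding, so the returned
    site keys are excluded from ASB calling.
    """
    per_sample: dict[tuple, dict[str, list[int]]] = {}
    for rec in igg_records:
        pair = per_sample.setdefault(rec.site.key, {}).setdefault(rec.sample_id, [0, 0])
        pair[0] += rec.n_ref
        pair[1] += rec.n_alt
    if not per_sample:
        logger.warning("no IgG samples supplied; IgG artifact filter is empty")
        return set()
    excluded: set[tuple] = set()
    for key, samples in per_sample.items():
        tot_ref = tot_alt = 0
        for n_ref, n_alt in samples.values():
            tot_ref += n_ref
            tot_alt += n_alt
            if n_ref + n_alt >= 1 and binom_two_sided(n_ref, n_alt) < alpha:
                excluded.add(key)
        if key not in excluded and tot_ref + tot_alt >= 1:
            if binom_two_sided(tot_ref, tot_alt) < alpha:
                excluded.add(key)
    return excluded


# ------------------------------------------------------------------ tiers

def classify_tier(p_binom: float, q: float, passes_fc: bool, concordance: str) -> str:
    putative = p_binom < 0.1 and passes_fc
    concordant = concordance == ms.CONCORDANT
    if q < 0.2 and concordant:
        return TIER_HIGH
    if putative and concordant:
        return TIER_LIKELY
    if putative:
        return TIER_PUTATIVE
    return TIER_NONE


def classify_tiers(df: pd.DataFrame) -> pd.DataFrame:
    """Add the ``tier`` column; missing concordance caps a site at putative."""
    df = df.copy()
    conc = df["concordance"].fillna(ms.UNCLASSIFIED)
    df["tier"] = [
        classify_tier(p, q, fc, c)
        for p, q, fc, c in zip(df["p_binom"], df["q"], df["passes_fc"], conc)
    ]
    return df


# --------------------------------------------------------------- pipeline

@dataclass
class ASBConfig:
    min_depth: int = 20
    alpha_igg: float = 0.01
    fdr: float = 0.2
    per_tf_bh: bool = True          # BH within each TF's tested set
    drop_mito: bool = True
    seed: int = 0
    bias_params: mb.BiasSimParams = field(default_factory=mb.BiasSimParams)
    run_bias_filter: bool = True
    motif_threshold: float = ms.MOTIF_P_THRESHOLD


def call_asb(
    samples: pd.DataFrame | str,
    genome,
    motifs: Mapping[str, ms.MotifModel] | str | None,
    motif_map: Mapping[str, str] | None = None,
    exclusions: Sequence[str | dict] = (),
    config: ASBConfig | None = None,
    gene_models: Sequence | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full ASB pipeline; returns (ASB table, per-stage summary).

    ``samples`` is a sample sheet (frame or TSV path) with sample_id,
    tf_label, vcf_path, is_igg.  ``motifs`` maps motif names to models (or
    is a directory of JASPAR files); ``motif_map`` assigns each TF its
    cognate motif.  ``gene_models`` (optional) adds a genomic-context label
    per site.
    """
    from . import context_stats as cs

    cfg = config or ASBConfig()
    if isinstance(samples, str):
        samples = vio.read_sample_sheet(samples)
    if isinstance(motifs, str):
        motifs = ms.read_motif_dir(motifs)
    motif_map = dict(motif_map or {})
    summary: dict = {"stages": {}}

    # intake
    tf_records: list[vio.AlleleDepth] = []
    igg_records: list[vio.AlleleDepth] = []
    for row in samples.itertuples(index=False):
        recs = vio.read_vcf_allele_depths(row.vcf_path, row.sample_id, row.tf_label)
        (igg_records if row.is_igg else tf_records).extend(recs)
    summary["stages"]["intake"] = {"tf_records": len(tf_records),
                                   "igg_records": len(igg_records)}

    # exclusion regions + mitochondrial contig
    tf_records = vio.apply_site_filters(tf_records, exclusions, cfg.drop_mito)
    igg_records = vio.apply_site_filters(igg_records, exclusions, cfg.drop_mito)
    summary["stages"]["site_filters"] = {"tf_records": len(tf_records)}

    # IgG artifact removal
    artifact = igg_artifact_sites(igg_records, cfg.alpha_igg)
    tf_records = [r for r in tf_records if r.site.key not in artifact]
    summary["stages"]["igg_filter"] = {"excluded_sites": len(artifact),
                                       "tf_records": len(tf_records)}

    # per-antibody aggregation and depth floor
    table = vio.aggregate_by_antibody(tf_records)
    summary["stages"]["aggregate"] = {"pairs": len(table)}
    table = table[table["n_ref"] + table["n_alt"] >= cfg.min_depth].reset_index(drop=True)
    summary["stages"]["min_depth"] = {"pairs": len(table)}
    if table.empty:
        logger.warning("no (TF, site) pairs survive filtering")
        table = table.rename(columns={"tf_label": "tf"})
        for col in ASB_TABLE_COLUMNS:
            if col not in table.columns:
                table[col] = pd.Series(dtype=float)
        return table[ASB_TABLE_COLUMNS], summary

    # binomial test + fold change
    table["p_binom"] = binom_two_sided_vec(table["n_ref"], table["n_alt"])
    fc = [fold_change(r, a) for r, a in zip(table["n_ref"], table["n_alt"])]
    table["ratio"] = [f[0] for f in fc]
    table["log2fc"] = [f[1] for f in fc]
    table["passes_fc"] = [f[2] for f in fc]

    # BH within each TF (or pooled)
    if cfg.per_tf_bh:
        table["q"] = np.nan
        for tf, idx in table.groupby("tf_label").groups.items():
            table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p_binom"])
    else:
        table["q"] = bh_adjust(table["p_binom"])

    # mapping-bias filter on distinct sites
    if cfg.run_bias_filter:
        sites = table[["contig", "pos", "ref", "alt"]].drop_duplicates().reset_index(drop=True)
        report = mb.mapping_bias_screen(genome, sites, cfg.bias_params, cfg.seed)
        keep_keys = {
            (c, p) for c, p, k in zip(report["contig"], report["pos"], report["keep"]) if k
        }
        before = len(table)
        table = table[[(c, p) in keep_keys
                       for c, p in zip(table["contig"], table["pos"])]].reset_index(drop=True)
        summary["stages"]["mapping_bias"] = {
            "sites_tested": len(sites),
            "sites_dropped": int((~report["keep"]).sum()),
            "pairs": len(table), "pairs_before": before,
        }

    # allele-specific motif delta and concordance
    deltas, conc = [], []
    for row in table.itertuples(index=False):
        motif_name = motif_map.get(row.tf_label)
        model = motifs.get(motif_name) if (motifs and motif_name) else None
        if model is None:
            deltas.append(np.nan)
            conc.append(ms.UNCLASSIFIED)
            continue
        d = ms.allele_motif_delta(genome, row.contig, int(row.pos), row.ref,
                                  row.alt, model, threshold=cfg.motif_threshold)
        deltas.append(d.delta)
        conc.append(ms.classify_concordance(d.delta, row.n_ref, row.n_alt,
                                            d.motif_overlapping and not d.edge))
    table["motif_delta"] = deltas
    table["concordance"] = conc

    # genomic context
    if gene_models is not None:
        table["context"] = [
            cs.annotate_context(c, int(p), gene_models)
            for c, p in zip(table["contig"], table["pos"])
        ]
    else:
        table["context"] = ""

    table = classify_tiers(table).rename(columns={"tf_label": "tf"})
    summary["stages"]["tiers"] = {
        tier: int((table["tier"] == tier).sum())
        for tier in (TIER_PUTATIVE, TIER_LIKELY, TIER_HIGH)
    }
    summary["stages"]["final"] = {"pairs": len(table)}
    return table[ASB_TABLE_COLUMNS + ["passes_fc"]], summary


def write_asb_outputs(table: pd.DataFrame, summary: dict, out_prefix: str) -> None:
    table[ASB_TABLE_COLUMNS].to_csv(out_prefix + "asb_calls.tsv", sep="\t", index=False)
    with open(out_prefix + "asb_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
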