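"""Genomic-context annotation and downstream ASB statistics.

Covers the comparisons run on a called ASB table: promoter "buffering"
(attenuated allelic fold changes at promoters relative to distal sites),
correlation of allelic imbalance with TF occupancy and HOT (high-occupancy
target) regions, empirical gene-set enrichment against random draws of
expressed genes, Fisher overlap tests, binding enrichment at a disease SNV
class versus downsampled control SNVs, and the correlation of allelic
binding with population allele frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("asbscan")

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"


@dataclass
class GeneModel:
    """A gene with TSS/strand, exon structure, expression and set labels.

    ``tss`` is 1-based; exon intervals are 0-based half-open on the gene's
    contig; ``start``/``end`` bound the gene body (0-based half-open).
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    expressed: bool = True
    sets: tuple[str, ...] = ()


def read_gene_table(path: str) -> list[GeneModel]:
    """Gene models from a TSV (gene_id, contig, strand, tss, start, end,
    exons as ``a-b;c-d``, expressed {0,1}, sets comma-separated)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        exons = []
        if row.exons:
            for span in str(row.exons).split(";"):
                a, b = span.split("-")
                exons.append((int(a), int(b)))
        sets = tuple(s for s in str(row.sets).split(",") if s)
        genes.append(GeneModel(row.gene_id, row.contig, row.strand, int(row.tss),
                               int(row.start), int(row.end), exons,
                               bool(int(row.expressed)), sets))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str) -> None:
    rows = [{
        "gene_id": g.gene_id, "contig": g.contig, "strand": g.strand,
        "tss": g.tss, "start": g.start, "end": g.end,
        "exons": ";".join(f"{a}-{b}" for a, b in g.exons),
        "expressed": int(g.expressed), "sets": ",".join(g.sets),
    } for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotate_context(
    contig: str,
    pos: int,
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> str:
    """Label a 1-based site as promoter/exon/intron/intergenic.

    The promoter window spans ``promoter_up`` bp upstream to
    ``promoter_down`` bp downstream of any gene's TSS in transcription
    orientation; precedence is promoter > exon > intron > intergenic.
    """
    pos0 = pos - 1
    in_exon = in_body = False
    seen_contig = False
    for g in genes:
        if g.contig != contig:
            continue
        seen_contig = True
        if g.strand == "+":
            promo_lo, promo_hi = g.tss - promoter_up, g.tss + promoter_down
        else:
            promo_lo, promo_hi = g.tss - promoter_down, g.tss + promoter_up
        if promo_lo <= pos <= promo_hi:
            return PROMOTER
        if g.start <= pos0 < g.end:
            in_body = True
            if any(a <= pos0 < b for a, b in g.exons):
                in_exon = True
    if not seen_contig:
        logger.warning("contig %s absent from gene annotation; labelling intergenic",
                       contig)
        return INTERGENIC
    if in_exon:
        return EXON
    if in_body:
        return INTRON
    return INTERGENIC


def clip_log2fc(log2fc, depth) -> np.ndarray:
    """|log2fc| with infinite values (a zero count) capped at log2(depth)+1.

    The cap only matters for mean-based statistics; rank tests are
    unaffected because the capped values remain the most extreme.
    """
    a = np.abs(np.asarray(log2fc, dtype=float))
    depth = np.asarray(depth, dtype=float)
    cap = np.log2(np.maximum(depth, 2)) + 1
    return np.where(np.isfinite(a), a, cap)


# ---------------------------------------------------------------- buffering

def buffering_tests(asb_table: pd.DataFrame, min_depth: int = 20) -> dict:
    """Promoter-buffering statistics on an ASB table.

    Requires columns log2fc, p_binom, passes_fc, context, n_ref, n_alt, tf.
    Returns Mann-Whitney p for |log2fc| promoter vs intergenic, Mann-Whitney
    p for the putative-ASB indicator promoter vs intergenic (depth floor
    applied), and the OLS F-test p for the context term controlling for
    log10 depth and TF.
    """
    df = asb_table.copy()
    df["depth"] = df["n_ref"] + df["n_alt"]
    df["abs_l2fc"] = clip_log2fc(df["log2fc"], df["depth"])
    counts = df["context"].value_counts()
    keep_levels = counts[counts >= 2].index
    dropped = set(counts.index) - set(keep_levels)
    if dropped:
        logger.warning("dropping context levels with <2 observations: %s", dropped)
    df = df[df["context"].isin(keep_levels)]
    if df["context"].nunique() < 2:
        raise ValueError("buffering_tests needs at least two context groups")

    promo = df.loc[df["context"] == PROMOTER, "abs_l2fc"]
    inter = df.loc[df["context"] == INTERGENIC, "abs_l2fc"]
    if len(promo) and len(inter):
        mw_p_magnitude = stats.mannwhitneyu(promo, inter, alternative="two-sided").pvalue
    else:
        mw_p_magnitude = math.nan

    deep = df[df["depth"] >= min_depth]
    deep_put = ((deep["p_binom"] < 0.1) & deep["passes_fc"]).astype(int)
    p_flag = deep_put[deep["context"] == PROMOTER]
    i_flag = deep_put[deep["context"] == INTERGENIC]
    if len(p_flag) and len(i_flag):
        mw_p_frequency = stats.mannwhitneyu(p_flag, i_flag, alternative="two-sided").pvalue
    else:
        mw_p_frequency = math.nan

    model_df = df.assign(log10_depth=np.log10(df["depth"]))
    formula = "abs_l2fc ~ C(context) + log10_depth"
    if model_df["tf"].nunique() > 1:
        formula += " + C(tf)"
    fit = smf.ols(formula, data=model_df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    anova_p = float(anova.loc["C(context)", "PR(>F)"])
    return {"mw_p_magnitude": float(mw_p_magnitude),
            "mw_p_frequency": float(mw_p_frequency),
            "anova_p": anova_p}


# ---------------------------------------------------------------- occupancy

def _count_tfs_overlapping(peaks_by_tf: Mapping[str, Sequence[tuple]],
                           contig: str, lo: int, hi: int) -> int:
    n = 0
    for tf, peaks in peaks_by_tf.items():
        for (c, a, b) in peaks:
            if c == contig and a < hi and b > lo:
                n += 1
                break
    return n


def occupancy_correlation(
    asb_table: pd.DataFrame,
    peaks_by_tf: Mapping[str, Sequence[tuple]],
    window: int = 2500,
    hot_window: int = 10_000,
) -> dict:
    """Relate local TF occupancy to the magnitude of allelic imbalance.

    Occupancy of a site is the number of distinct TFs with a peak
    overlapping a ``window``-bp window centered on it (``hot_window`` for
    the HOT-region comparison).  Peaks are (contig, start, end) 0-based
    half-open.  Returns Pearson r/p and a Mann-Whitney comparison of
    |log2fc| in top-decile-occupancy windows vs the rest.
    """
    if not peaks_by_tf or all(len(v) == 0 for v in peaks_by_tf.values()):
        raise ValueError("empty peak sets")
    df = asb_table.copy()
    df["depth"] = df["n_ref"] + df["n_alt"]
    df["abs_l2fc"] = clip_log2fc(df["log2fc"], df["depth"])
    occ, occ_hot = [], []
    for row in df.itertuples(index=False):
        pos0 = int(row.pos) - 1
        occ.append(_count_tfs_overlapping(
            peaks_by_tf, row.contig, pos0 - window // 2, pos0 + window // 2))
        occ_hot.append(_count_tfs_overlapping(
            peaks_by_tf, row.contig, pos0 - hot_window // 2, pos0 + hot_window // 2))
    df["occupancy"] = occ
    df["occupancy_hot"] = occ_hot
    out: dict = {}
    if df["occupancy"].nunique() < 2:
        logger.warning("occupancy has zero variance; correlation undefined")
        out["r"], out["p"] = math.nan, math.nan
    else:
        r, p = stats.pearsonr(df["occupancy"], df["abs_l2fc"])
        out["r"], out["p"] = float(r), float(p)
    thresh = np.quantile(df["occupancy_hot"], 0.9)
    hot = df[df["occupancy_hot"] >= thresh]["abs_l2fc"]
    rest = df[df["occupancy_hot"] < thresh]["abs_l2fc"]
    if len(hot) and len(rest):
        out["hot_mw_p"] = float(
            stats.mannwhitneyu(hot, rest, alternative="two-sided").pvalue)
        out["hot_median"] = float(hot.median())
        out["rest_median"] = float(rest.median())
    else:
        out["hot_mw_p"] = math.nan
    return out


# ------------------------------------------------------- gene-set enrichment

def empirical_geneset_enrichment(
    asb_sites: pd.DataFrame,
    target_genes: Sequence[str],
    expressed_genes: Sequence[str],
    gene_models: Sequence[GeneModel],
    window: int = 50_000,
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Are ASB sites enriched near a gene set, vs random expressed genes?

    The observed statistic is the number of ASB sites within ``window`` bp
    of any target gene body; each null draw replaces the targets with an
    equally sized random subset of expressed genes.  The empirical p uses
    the +1 pseudo-draw correction, so it is never 0.
    """
    target_genes = list(target_genes)
    expressed_genes = list(expressed_genes)
    if not set(target_genes) <= set(expressed_genes):
        raise ValueError("all target genes must be expressed")
    if n_draws < 100:
        logger.warning("n_draws=%d is small; empirical p resolution is coarse", n_draws)
    by_id = {g.gene_id: g for g in gene_models}

    def count_near(gene_ids: Sequence[str]) -> int:
        n = 0
        spans = [(by_id[g].contig, by_id[g].start - window, by_id[g].end + window)
                 for g in gene_ids if g in by_id]
        for row in asb_sites.itertuples(index=False):
            pos0 = int(row.pos) - 1
            if any(c == row.contig and lo <= pos0 < hi for c, lo, hi in spans):
                n += 1
        return n

    observed = count_near(target_genes)
    rng = np.random.default_rng(seed)
    draws = np.array([
        count_near(rng.choice(expressed_genes, size=len(target_genes), replace=False))
        for _ in range(n_draws)
    ])
    p = (1 + int((draws >= observed).sum())) / (1 + n_draws)
    mean_draw = float(draws.mean())
    fold = observed / mean_draw if mean_draw > 0 else math.inf if observed else math.nan
    return {"observed": observed, "expected": mean_draw, "fold": fold, "p": p}


# ------------------------------------------------------------- Fisher overlap

def overlap_fisher(
    flags_a=None, flags_b=None, table=None, sided: str = "two"
) -> tuple[float, float]:
    """Fisher's exact test from two indicator vectors or a 2x2 table.

    ``sided="greater"`` is the upper (enrichment) tail; ``"two"`` uses the
    point-probability (minimum-likelihood) two-sided rule.
    """
    if table is None:
        a = np.asarray(flags_a).astype(bool)
        b = np.asarray(flags_b).astype(bool)
        if a.shape != b.shape:
            raise ValueError("indicator vectors must have equal length")
        table = [[int((a & b).sum()), int((a & ~b).sum())],
                 [int((~a & b).sum()), int((~a & ~b).sum())]]
    table = np.asarray(table)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    alternative = "greater" if sided == "greater" else "two-sided"
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


# --------------------------------------------------- SNV-class binding test

def snv_class_binding_enrichment(
    peak_replicates: Sequence[Sequence[tuple]],
    class_snvs: pd.DataFrame,
    other_snvs: pd.DataFrame,
    downsample_to: int | None = None,
    seed: int = 0,
) -> float | None:
    """Is a TF's binding enriched at one SNV class over another?

    For each peak replicate, counts class SNVs in peaks and a seeded
    downsample of other-class SNVs (matched to ``downsample_to``, default
    the class size) in peaks; a paired one-sided t-test across replicates
    asks whether class counts exceed the downsampled other counts.  SNV
    frames need contig/pos (1-based); peaks are (contig, start, end).
    Returns None (with a warning) when fewer than 2 replicates or the test
    is degenerate.
    """
    if len(peak_replicates) < 2:
        logger.warning("snv_class_binding_enrichment needs >=2 replicates")
        return None
    downsample_to = downsample_to or len(class_snvs)
    rng = np.random.default_rng(seed)

    def count_in_peaks(snvs: pd.DataFrame, peaks) -> int:
        n = 0
        for row in snvs.itertuples(index=False):
            pos0 = int(row.pos) - 1
            if any(c == row.contig and a <= pos0 < b for c, a, b in peaks):
                n += 1
        return n

    class_counts, other_counts = [], []
    for peaks in peak_replicates:
        class_counts.append(count_in_peaks(class_snvs, peaks))
        idx = rng.choice(len(other_snvs), size=min(downsample_to, len(other_snvs)),
                         replace=False)
        other_counts.append(count_in_peaks(other_snvs.iloc[idx], peaks))
    diffs = np.array(class_counts) - np.array(other_counts)
    if np.all(diffs == diffs[0]) and np.std(diffs) == 0 and diffs[0] == 0:
        logger.warning("degenerate SNV-class test (all differences zero)")
        return None
    res = stats.ttest_rel(class_counts, other_counts, alternative="greater")
    p = float(res.pvalue)
    if math.isnan(p):
        logger.warning("SNV-class t-test undefined (zero variance)")
        return None
    return p


# ------------------------------------------- allele frequency vs binding

def allele_freq_binding_correlation(
    asb_table: pd.DataFrame, allele_freqs: pd.DataFrame
) -> dict:
    """Correlate the more-bound allele's population frequency with binding.

    ``allele_freqs`` has columns rsid and freq (alternate-allele frequency
    in [0, 1]), joined by rsid.  The binding measure is the more-bound
    allele's read fraction (max(n_ref, n_alt)/depth); the linear-model p
    controls for log10 depth and TF.
    """
    freqs = allele_freqs.copy()
    if np.any((freqs["freq"] < 0) | (freqs["freq"] > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    df = asb_table.merge(freqs, on="rsid", how="inner")
    if df.empty:
        raise ValueError("no rsids join between the ASB table and frequency table")
    depth = df["n_ref"] + df["n_alt"]
    bound_frac = np.maximum(df["n_ref"], df["n_alt"]) / depth
    freq_more_bound = np.where(df["n_ref"] >= df["n_alt"], 1 - df["freq"], df["freq"])
    if np.std(freq_more_bound) == 0 or np.std(bound_frac) == 0:
        logger.warning("zero variance; allele-frequency correlation undefined")
        return {"r": math.nan, "p": math.nan, "anova_p": math.nan}
    r, p = stats.pearsonr(freq_more_bound, bound_frac)
    model_df = pd.DataFrame({
        "bound_frac": bound_frac, "freq_mb": freq_more_bound,
        "log10_depth": np.log10(depth), "tf": df["tf"],
    })
    formula = "bound_frac ~ freq_mb + log10_depth"
    if model_df["tf"].nunique() > 1:
        formula += " + C(tf)"
    fit = smf.ols(formula, data=model_df).fit()
    return {"r": float(r), "p": float(p),
            "anova_p": float(fit.pvalues["freq_mb"])}
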