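"""Seeded generator of every input the ASB pipeline consumes.

The generator emulates the inputs of a population-sampling CUT&RUN study
on a small synthetic genome: heterozygous SNVs with DP4 allele depths
drawn Binomial(depth, theta), IgG control samples carrying copy-number-like
imbalances, duplicated-sequence loci that defeat unique read mapping,
TF motifs planted in the genome with allelic ratios tied to motif
disruption through a logistic link, gene models for promoter/exon/intron/
intergenic context, and CRISPR-screen / pseudotime cell fixtures with
planted hits.  Ground truth for every planted feature is returned alongside
the artifacts so parameter-recovery tests can score the pipeline.

All randomness flows from a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import context_stats as cs
from . import motif_scan as ms
from .motif_scan import BASES

# default TF panel names (cycled when n_tfs exceeds the list)
TF_PANEL = ["JUN", "SP3", "TFAP2A", "KLF4", "RUNX1", "ATF4", "SNAI2", "IRF6"]

SITE_SPACING = 160        # bp between het sites: keeps 140-bp windows disjoint
EDGE_MARGIN = 300
TRAP_COPY_GAP = 20


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_length: int = 150_000
    n_genes: int = 20
    n_het_sites: int = 300
    n_tfs: int = 3
    depth_range: tuple[int, int] = (20, 500)
    planted_asb_fraction: float = 0.10
    planted_ratio: float = 0.7
    n_igg_samples: int = 4
    cnv_site_fraction: float = 0.03
    duplication_site_fraction: float = 0.03
    motif_length: int = 8
    motif_site_fraction: float = 0.15
    beta_per_bit: float = 0.5      # logistic slope: theta vs motif log-odds delta
    n_samples_per_tf: int = 2
    n_decoy_hom: int = 5
    n_decoy_indel: int = 3
    contig: str = "chr1"

    def __post_init__(self):
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        if not (0 < self.planted_ratio < 1):
            raise ValueError("planted_ratio must lie in (0, 1)")
        if self.planted_ratio == 0.5 and self.planted_asb_fraction > 0:
            raise ValueError("planted_ratio of exactly 0.5 cannot mark true ASBs")
        for name in ("planted_asb_fraction", "cnv_site_fraction",
                     "duplication_site_fraction", "motif_site_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GenomeArtifacts:
    genome: dict[str, str]
    genes: list
    motifs: dict[str, ms.MotifModel]
    motif_map: dict[str, str]
    pfms: dict[str, np.ndarray]
    sites: pd.DataFrame                  # contig, pos (1-based), ref, alt, rsid
    decoys: pd.DataFrame
    exclusion_intervals: list[tuple[str, int, int]]
    placements: pd.DataFrame             # motif placements: tf, contig, start, site_pos


@dataclass
class SyntheticTruth:
    sites: pd.DataFrame
    genes: pd.DataFrame | None = None
    cells: dict = field(default_factory=dict)


class SizingError(ValueError):
    pass


# -------------------------------------------------------------- genome build

def build_synthetic_genome(
    cfg: SyntheticConfig, out_dir: str | None = None
) -> tuple[GenomeArtifacts, SyntheticTruth]:
    """Generate the genome, gene models, motifs, het sites and truth table."""
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_het_sites
    n_motif = round(cfg.motif_site_fraction * n)
    n_asb = round(cfg.planted_asb_fraction * n)
    n_cnv = round(cfg.cnv_site_fraction * n)
    n_trap = round(cfg.duplication_site_fraction * n)
    if n_motif + n_asb + n_cnv + n_trap > n:
        raise ValueError("site-category fractions sum above 1")

    trap_zone = n_trap * 2 * (140 + TRAP_COPY_GAP) + EDGE_MARGIN
    zone_start = EDGE_MARGIN
    zone_end = cfg.genome_length - EDGE_MARGIN - trap_zone
    if zone_end - zone_start < n * SITE_SPACING:
        raise SizingError(
            f"genome_length {cfg.genome_length} too small for {n} het sites "
            f"(needs >= {n * SITE_SPACING + 2 * EDGE_MARGIN + trap_zone})")

    seq = rng.integers(0, 4, size=cfg.genome_length)

    # gene models over the left part of the genome (sites fall in and around them)
    genes = []
    gene_zone_end = min(int(cfg.genome_length * 0.55), zone_end)
    gene_spacing = max((gene_zone_end - zone_start) // max(cfg.n_genes, 1), 1)
    gene_len = min(2400, gene_spacing - 600)
    if cfg.n_genes > 0 and gene_len < 600:
        raise SizingError("genome_length too small to place requested genes")
    set_labels = ("homeostasis", "monogenic")
    for i in range(cfg.n_genes):
        start = zone_start + i * gene_spacing + 200
        end = start + gene_len
        strand = "+" if i % 2 == 0 else "-"
        tss = start + 1 if strand == "+" else end
        third = gene_len // 3
        exons = [(start, start + third // 2), (end - third // 2, end)]
        expressed = bool(rng.random() < 0.8)
        sets = tuple(s for j, s in enumerate(set_labels) if rng.random() < 0.2)
        genes.append(cs.GeneModel(f"G{i + 1:04d}", cfg.contig, strand, tss,
                                  start, end, exons, expressed, sets))

    # motif models: strong consensus PFMs, one per TF
    tf_names = [TF_PANEL[i % len(TF_PANEL)] + ("" if i < len(TF_PANEL) else str(i))
                for i in range(cfg.n_tfs)]
    pfms: dict[str, np.ndarray] = {}
    motifs: dict[str, ms.MotifModel] = {}
    motif_map: dict[str, str] = {}
    for tf in tf_names:
        consensus = rng.integers(0, 4, size=cfg.motif_length)
        pfm = np.full((4, cfg.motif_length), 5.0)
        pfm[consensus, np.arange(cfg.motif_length)] = 85.0
        name = f"{tf}_M1"
        pfms[name] = pfm
        motifs[name] = ms.build_motif_model(pfm, name=name, tf=tf)
        motif_map[tf] = name

    # het-site positions (0-based), evenly spaced with jitter
    spacing = (zone_end - zone_start) // n
    jitter_max = max(min(spacing - 150, 40), 1)
    positions0 = zone_start + np.arange(n) * spacing + rng.integers(0, jitter_max, size=n)

    # category assignment
    order = rng.permutation(n)
    category = np.array(["null"] * n, dtype=object)
    category[order[:n_motif]] = "motif"
    category[order[n_motif : n_motif + n_asb]] = "asb"
    category[order[n_motif + n_asb : n_motif + n_asb + n_cnv]] = "cnv"
    category[order[n_motif + n_asb + n_cnv : n_motif + n_asb + n_cnv + n_trap]] = "trap"

    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    theta = np.full(n, 0.5)
    motif_tf = np.array([""] * n, dtype=object)
    placements_rows = []
    flip = rng.integers(0, 2, size=n)          # direction of planted imbalance
    mid = cfg.motif_length // 2

    for i in range(n):
        pos0 = int(positions0[i])
        cat = category[i]
        if cat == "motif":
            tf = tf_names[i % cfg.n_tfs]
            model = motifs[motif_map[tf]]
            consensus_idx = np.argmax(model.probs, axis=1)
            start = pos0 - mid
            seq[start : start + cfg.motif_length] = consensus_idx
            ref_i = int(consensus_idx[mid])
            alt_i = int(np.argmin(model.probs[mid]))
            delta_bits = float(model.logodds[mid, alt_i] - model.logodds[mid, ref_i])
            theta[i] = 1.0 / (1.0 + np.exp(-cfg.beta_per_bit * delta_bits))
            motif_tf[i] = tf
            placements_rows.append({"tf": tf, "contig": cfg.contig,
                                    "start": start, "site_pos": pos0 + 1})
            refs[i], alts[i] = BASES[ref_i], BASES[alt_i]
        else:
            ref_i = int(seq[pos0])
            alt_i = int((ref_i + 1 + rng.integers(0, 3)) % 4)
            refs[i], alts[i] = BASES[ref_i], BASES[alt_i]
            if cat == "asb" or cat == "trap":
                theta[i] = cfg.planted_ratio if flip[i] else 1 - cfg.planted_ratio
            elif cat == "cnv":
                theta[i] = cfg.planted_ratio

    genome_str = "".join(BASES[b] for b in seq)

    # duplication traps: two extra copies of the alt-substituted 140-bp window,
    # so every alt-carrying read multimaps while SNV-covering ref reads stay unique
    trap_cursor = zone_end + EDGE_MARGIN // 2
    genome_list = list(genome_str)
    for i in np.where(category == "trap")[0]:
        pos0 = int(positions0[i])
        window = genome_list[pos0 - 70 : pos0 + 70]
        window[70] = alts[i]
        for _ in range(2):
            genome_list[trap_cursor : trap_cursor + 140] = window
            trap_cursor += 140 + TRAP_COPY_GAP
    genome_str = "".join(genome_list)

    # exclusion BED: intervals in site-free gaps (they exercise the filter
    # plumbing without removing planted sites)
    excl = []
    if n >= 2:
        g1 = (int(positions0[0]) + 90, int(positions0[1]) - 90)
        if g1[1] > g1[0]:
            excl.append((cfg.contig, g1[0], g1[1]))

    sites = pd.DataFrame({
        "contig": cfg.contig,
        "pos": positions0 + 1,
        "ref": refs,
        "alt": alts,
        "rsid": [f"rs{1000 + i}" for i in range(n)],
    })

    # decoy records exercise the genotype/indel filters at intake
    decoy_rows = []
    decoy_base = zone_end + 40
    for j in range(cfg.n_decoy_hom + cfg.n_decoy_indel):
        p0 = decoy_base + j * 5
        b = genome_str[p0]
        alt_b = BASES[(BASE_IDX[b] + 1) % 4]
        kind = "hom" if j < cfg.n_decoy_hom else "indel"
        decoy_rows.append({"contig": cfg.contig, "pos": p0 + 1, "ref": b,
                           "alt": alt_b if kind == "hom" else b + "T",
                           "kind": kind})
    decoys = pd.DataFrame(decoy_rows)

    genome = {cfg.contig: genome_str}
    context = [cs.annotate_context(cfg.contig, int(p), genes) for p in sites["pos"]]
    truth_sites = sites.copy()
    truth_sites["true_theta"] = theta
    truth_sites["is_asb"] = (theta != 0.5) & (category != "cnv") & (category != "trap")
    truth_sites["is_cnv_artifact"] = category == "cnv"
    truth_sites["is_mapping_trap"] = category == "trap"
    truth_sites["motif_disrupted_tf"] = motif_tf
    truth_sites["context"] = context
    truth_sites["category"] = category

    art = GenomeArtifacts(
        genome=genome, genes=genes, motifs=motifs, motif_map=motif_map,
        pfms=pfms, sites=sites, decoys=decoys, exclusion_intervals=excl,
        placements=pd.DataFrame(placements_rows,
                                columns=["tf", "contig", "start", "site_pos"]),
    )
    truth = SyntheticTruth(sites=truth_sites)
    if out_dir is not None:
        write_genome_artifacts(art, truth, out_dir)
    return art, truth


BASE_IDX = {b: i for i, b in enumerate(BASES)}


# ------------------------------------------------------------------ writers

def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig}\n")
            s = genome[contig]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_jaspar(pfms: dict[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for name, pfm in pfms.items():
            fh.write(f">{name} {name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{int(v):d}" for v in pfm[bi])
                fh.write(f"{base} [ {row} ]\n")


def _vcf_header(genome: dict[str, str], sample: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for contig, s in genome.items():
        lines.append(f"##contig=<ID={contig},length={len(s)}>")
    lines.append('##INFO=<ID=DP4,Number=4,Type=Integer,'
                 'Description="Ref-forward, ref-reverse, alt-forward, alt-reverse depths">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    return "\n".join(lines) + "\n"


def write_sites_vcf(art: GenomeArtifacts, path: str) -> None:
    """Het-site skeleton VCF (genotypes, no depths)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(art.genome, "donor"))
        for row in art.sites.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t0/1\n")


def write_genome_artifacts(art: GenomeArtifacts, truth: SyntheticTruth,
                           out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(art.genome, os.path.join(out_dir, "genome.fa"))
    write_jaspar(art.pfms, os.path.join(out_dir, "motifs.jaspar"))
    write_sites_vcf(art, os.path.join(out_dir, "sites.vcf"))
    cs.write_gene_table(art.genes, os.path.join(out_dir, "genes.tsv"))
    with open(os.path.join(out_dir, "exclude.bed"), "w") as fh:
        for contig, a, b in art.exclusion_intervals:
            fh.write(f"{contig}\t{a}\t{b}\texcluded\t0\t.\n")
    truth.sites.to_csv(os.path.join(out_dir, "truth_sites.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"tf": tf, "motif": m} for tf, m in art.motif_map.items()]
    ).to_csv(os.path.join(out_dir, "motif_map.tsv"), sep="\t", index=False)


# ------------------------------------------------------------- CUT&RUN counts

def draw_dp4(rng: np.random.Generator, depth: int, theta: float) -> tuple[int, int, int, int]:
    """Draw DP4 counts: alt ~ Binomial(depth, theta), each strand ~fair."""
    n_alt = int(rng.binomial(depth, theta))
    n_ref = depth - n_alt
    ref_fwd = int(rng.binomial(n_ref, 0.5))
    alt_fwd = int(rng.binomial(n_alt, 0.5))
    return ref_fwd, n_ref - ref_fwd, alt_fwd, n_alt - alt_fwd


def simulate_cutrun_counts(
    art: GenomeArtifacts,
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    out_dir: str,
) -> pd.DataFrame:
    """Write per-sample VCFs with DP4 depths; returns the sample sheet.

    TF samples draw alt counts at theta = true_theta for sites planted
    against that sample's antibody (motif-linked imbalances apply only to
    the cognate TF); IgG samples are balanced everywhere except CNV-artifact
    sites, which carry the same imbalance as in the TF samples.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 1])
    ts = truth.sites
    tf_names = list(art.motif_map.keys())
    sheet_rows = []

    def site_theta(row, tf_label: str) -> float:
        if tf_label == "IgG":
            return row.true_theta if row.is_cnv_artifact else 0.5
        if row.motif_disrupted_tf:
            return row.true_theta if row.motif_disrupted_tf == tf_label else 0.5
        return row.true_theta

    samples = [(f"{tf}_rep{r + 1}", tf, False)
               for tf in tf_names for r in range(cfg.n_samples_per_tf)]
    samples += [(f"IgG_{r + 1}", "IgG", True) for r in range(cfg.n_igg_samples)]

    dmin, dmax = cfg.depth_range
    for sample_id, tf_label, is_igg in samples:
        path = os.path.join(out_dir, f"{sample_id}.vcf")
        with open(path, "w") as fh:
            fh.write(_vcf_header(art.genome, sample_id))
            for row in ts.itertuples(index=False):
                depth = int(rng.integers(dmin, dmax + 1))
                dp4 = draw_dp4(rng, depth, site_theta(row, tf_label))
                fh.write(f"{row.contig}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}"
                         f"\t.\t.\tDP4={dp4[0]},{dp4[1]},{dp4[2]},{dp4[3]}\tGT\t0/1\n")
            for d in art.decoys.itertuples(index=False):
                depth = int(rng.integers(dmin, dmax + 1))
                if d.kind == "hom":
                    dp4 = (0, 0, depth // 2, depth - depth // 2)
                    gt = "1/1"
                else:
                    dp4 = draw_dp4(rng, depth, 0.5)
                    gt = "0/1"
                fh.write(f"{d.contig}\t{d.pos}\t.\t{d.ref}\t{d.alt}"
                         f"\t.\t.\tDP4={dp4[0]},{dp4[1]},{dp4[2]},{dp4[3]}\tGT\t{gt}\n")
        sheet_rows.append({"sample_id": sample_id, "tf_label": tf_label,
                           "vcf_path": path, "is_igg": int(is_igg)})
    sheet = pd.DataFrame(sheet_rows)
    # the written sheet carries paths relative to its own directory so that
    # same-seed runs are byte-identical wherever they land
    on_disk = sheet.assign(vcf_path=[os.path.basename(p) for p in sheet["vcf_path"]])
    on_disk.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
    return sheet


# -------------------------------------------------------- screen and cells

@dataclass
class ScreenCellConfig:
    seed: int = 0
    n_genes: int = 1772
    unexpressed_fraction: float = 0.4
    n_true_hits: int = 150
    true_p_scale: float = 5e-4     # favoured-direction p ~ U(0, scale) for hits
    n_positive_controls: int = 33
    pc_hit_fraction: float = 0.45
    n_datasets: int = 2
    n_targets: int = 12
    cells_per_target: int = 80
    control_cells: int = 400
    guides_per_target: int = 3
    shift_magnitude: float = 0.6   # mixture-weight shift for perturbed targets
    marker_effect: float = 1.0

    def __post_init__(self):
        if self.n_true_hits > self.n_genes:
            raise ValueError("more true hits than genes")
        if self.n_positive_controls > self.n_genes:
            raise ValueError("more positive controls than genes")


def _mixture_pseudotime(rng: np.random.Generator, n: int, shift: float) -> np.ndarray:
    """Beta-mixture pseudotime: progenitor (low) and differentiated (high)
    modes; ``shift`` in [-1, 1] moves weight toward the high mode."""
    w_high = float(np.clip(0.5 + 0.45 * shift, 0.02, 0.98))
    high = rng.random(n) < w_high
    pt = np.where(high, rng.beta(5, 2, size=n), rng.beta(2, 5, size=n))
    return pt


def simulate_screen_and_cells(
    cfg: ScreenCellConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate screen gene-level p-value tables and a perturbation cell table.

    Non-hit genes draw all four directional p-values Uniform(0,1); true hits
    deflate the favoured direction pair.  Unexpressed genes are never true
    hits.  Cells get Beta-mixture pseudotimes with target-specific mixture
    shifts for perturbed targets and a late-differentiation marker with
    optional planted expression effects.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n = cfg.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    expressed = np.ones(n, dtype=bool)
    unexp_idx = rng.choice(n, size=round(cfg.unexpressed_fraction * n), replace=False)
    expressed[unexp_idx] = False
    exp_idx = np.where(expressed)[0]
    hit_idx = rng.choice(exp_idx, size=min(cfg.n_true_hits, len(exp_idx)), replace=False)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hit_idx] = True

    p = {col: rng.random(n) for col in
         ("p_high_enrich", "p_low_deplete", "p_high_deplete", "p_low_enrich")}
    direction_up = rng.random(n) < 0.5
    for i in hit_idx:
        cols = (("p_high_enrich", "p_low_deplete") if direction_up[i]
                else ("p_high_deplete", "p_low_enrich"))
        for c in cols:
            p[c][i] = rng.random() * cfg.true_p_scale

    n_pc_hits = round(cfg.pc_hit_fraction * cfg.n_positive_controls)
    pc_from_hits = rng.choice(hit_idx, size=min(n_pc_hits, len(hit_idx)), replace=False)
    non_hit_exp = np.setdiff1d(exp_idx, hit_idx)
    pc_rest = rng.choice(non_hit_exp, size=cfg.n_positive_controls - len(pc_from_hits),
                         replace=False)
    is_pc = np.zeros(n, dtype=bool)
    is_pc[np.concatenate([pc_from_hits, pc_rest])] = True

    screen = pd.DataFrame({"gene": gene_ids, **p,
                           "expressed": expressed, "positive_control": is_pc})
    gene_truth = pd.DataFrame({"gene": gene_ids, "is_true_screen_hit": is_hit,
                               "is_expressed": expressed,
                               "is_positive_control": is_pc})

    # cell table: "control" plus perturbation targets, half with planted shifts
    target_genes = [gene_ids[i] for i in hit_idx[: cfg.n_targets]]
    shifts = {}
    marker_effects = {}
    for j, t in enumerate(target_genes):
        if j % 2 == 0:
            sign = 1 if j % 4 == 0 else -1
            shifts[t] = sign * cfg.shift_magnitude
        else:
            shifts[t] = 0.0
        marker_effects[t] = cfg.marker_effect if j % 3 == 0 else 0.0
    shifts["control"] = 0.0
    marker_effects["control"] = 0.0

    rows = []
    for ds in range(cfg.n_datasets):
        ds_name = f"dataset{ds + 1}"
        for target in ["control"] + target_genes:
            n_cells = cfg.control_cells if target == "control" else cfg.cells_per_target
            pt = _mixture_pseudotime(rng, n_cells, shifts[target])
            marker = (2.0 * np.exp(-(((pt - 0.7) / 0.25) ** 2))
                      + rng.normal(0, 0.3, size=n_cells) + marker_effects[target])
            guide_idx = rng.integers(0, cfg.guides_per_target, size=n_cells)
            for k in range(n_cells):
                rows.append({
                    "cell_id": f"{ds_name}_{target}_{k}",
                    "guide": f"{target}_g{guide_idx[k] + 1}",
                    "target": target,
                    "pseudotime": float(pt[k]),
                    "marker": float(marker[k]),
                    "dataset": ds_name,
                })
    cells = pd.DataFrame(rows)
    truth = SyntheticTruth(
        sites=pd.DataFrame(), genes=gene_truth,
        cells={"pseudotime_shift": shifts, "marker_effect": marker_effects},
    )
    return screen, cells, truth


# ----------------------------------------------- lightweight stats fixtures

def simulate_asb_table(
    n_sites: int = 500,
    seed: int = 0,
    promoter_attenuation: float = 1.0,
    n_tfs: int = 3,
    depth_range: tuple[int, int] = (20, 500),
    effect_floor: float = 0.4,
    effect_scale: float = 0.8,
    null_fraction: float = 0.3,
) -> pd.DataFrame:
    """A called-ASB-style table with controllable context-specific effects.

    Per-site latent allelic effects (|log2 allelic odds|) are
    ``effect_floor + Exponential(effect_scale)`` for imbalanced sites and
    exactly 0 for a ``null_fraction`` of balanced sites; the floor reflects
    that a bona fide ASB carries at least a fold-change-gate-sized effect.
    Promoter-site effects are multiplied by ``promoter_attenuation`` before
    counts are drawn.  Used by the buffering/occupancy/gene-set statistics
    and their tests.
    """
    from .asb_core import binom_two_sided_vec, bh_adjust, fold_change

    rng = np.random.default_rng([seed, 3])
    contexts = rng.choice(
        [cs.PROMOTER, cs.EXON, cs.INTRON, cs.INTERGENIC],
        p=[0.3, 0.1, 0.2, 0.4], size=n_sites)
    tfs = rng.choice([TF_PANEL[i % len(TF_PANEL)] for i in range(n_tfs)], size=n_sites)
    depth = rng.integers(depth_range[0], depth_range[1] + 1, size=n_sites)
    effect = effect_floor + rng.exponential(effect_scale, size=n_sites)
    effect[rng.random(n_sites) < null_fraction] = 0.0
    effect[contexts == cs.PROMOTER] *= promoter_attenuation
    sign = np.where(rng.random(n_sites) < 0.5, 1.0, -1.0)
    theta = 1.0 / (1.0 + 2.0 ** (-(sign * effect)))     # alt-allele probability
    n_alt = rng.binomial(depth, theta)
    n_ref = depth - n_alt
    ok = (n_ref + n_alt) >= 1
    df = pd.DataFrame({
        "tf": tfs[ok], "contig": "chr1",
        "pos": np.arange(1, n_sites + 1)[ok] * 200,
        "rsid": [f"rs{i}" for i in np.arange(n_sites)[ok]],
        "n_ref": n_ref[ok], "n_alt": n_alt[ok], "context": contexts[ok],
    })
    df["p_binom"] = binom_two_sided_vec(df["n_ref"], df["n_alt"])
    fcs = [fold_change(r, a) for r, a in zip(df["n_ref"], df["n_alt"])]
    df["ratio"] = [f[0] for f in fcs]
    df["log2fc"] = [f[1] for f in fcs]
    df["passes_fc"] = [f[2] for f in fcs]
    df["q"] = bh_adjust(df["p_binom"])
    return df.reset_index(drop=True)


def simulate_occupancy_data(
    n_sites: int = 300,
    seed: int = 0,
    occupancy_effect: float = 0.25,
    n_tfs: int = 8,
) -> tuple[pd.DataFrame, dict[str, list[tuple[str, int, int]]]]:
    """ASB table plus per-TF peak sets with an occupancy-linked attenuation.

    Each site gets an occupancy count ~Binomial(n_tfs, 0.4); its allelic
    effect is scaled by ``exp(-occupancy_effect * occupancy)``, and peaks
    for exactly that many TFs are placed over the site.
    """
    rng = np.random.default_rng([seed, 4])
    occupancy = rng.binomial(n_tfs, 0.4, size=n_sites)
    depth = rng.integers(50, 300, size=n_sites)
    effect = rng.exponential(1.0, size=n_sites) * np.exp(-occupancy_effect * occupancy)
    sign = np.where(rng.random(n_sites) < 0.5, 1.0, -1.0)
    theta = 1.0 / (1.0 + 2.0 ** (-(sign * effect)))
    n_alt = rng.binomial(depth, theta)
    from .asb_core import binom_two_sided_vec

    positions = (np.arange(n_sites) + 1) * 20_000    # one site per HOT-scale window
    df = pd.DataFrame({
        "tf": "JUN", "contig": "chr1", "pos": positions,
        "n_ref": depth - n_alt, "n_alt": n_alt,
        "context": cs.INTERGENIC,
    })
    df["p_binom"] = binom_two_sided_vec(df["n_ref"].clip(lower=0) + 0, df["n_alt"])
    df["log2fc"] = np.log2(np.maximum(df["n_ref"], 0.5) / np.maximum(df["n_alt"], 0.5))
    tf_names = [f"TF{i}" for i in range(n_tfs)]
    peaks: dict[str, list[tuple[str, int, int]]] = {t: [] for t in tf_names}
    for i in range(n_sites):
        pos0 = int(positions[i]) - 1
        for t in range(int(occupancy[i])):
            peaks[tf_names[t]].append(("chr1", pos0 - 100, pos0 + 100))
    return df, peaks
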