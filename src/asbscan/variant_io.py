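"""VCF allele-depth intake and site filtering for allele-specific analysis.

Per-sample VCFs (one per CUT&RUN library) are reduced to strictly biallelic
SNVs with heterozygous 0/1 genotypes, carrying the strand-split DP4 read
depths.  Sites are then filtered against exclusion intervals (structural
variation, blacklists) and the mitochondrial contig, and counts from
samples sharing the same anti-TF antibody are summed before testing.

Coordinate conventions: VCF positions are 1-based; BED intervals are
0-based half-open.  A 1-based position ``pos`` falls in BED interval
``[start, end)`` iff ``start <= pos-1 < end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("asbscan")

MITO_NAMES = {"chrM", "chrMT", "MT", "M"}


class VCFFormatError(ValueError):
    pass


class BEDParseError(ValueError):
    pass


@dataclass(frozen=True)
class HetSite:
    """A biallelic heterozygous SNV (1-based VCF coordinates)."""

    contig: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base SNVs are supported")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class AlleleDepth:
    """Strand-split ref/alt read depths at a het site in one sample."""

    site: HetSite
    sample_id: str
    tf_label: str
    n_ref_fwd: int
    n_ref_rev: int
    n_alt_fwd: int
    n_alt_rev: int

    @property
    def n_ref(self) -> int:
        return self.n_ref_fwd + self.n_ref_rev

    @property
    def n_alt(self) -> int:
        return self.n_alt_fwd + self.n_alt_rev


def read_vcf_allele_depths(
    vcf_path: str, sample_id: str, tf_label: str
) -> list[AlleleDepth]:
    """Read DP4 depths for biallelic SNVs with 0/1 genotypes from a VCF.

    Multiallelic records, indels and non-heterozygous genotypes are skipped
    (counts logged).  A record without a DP4 field raises
    :class:`VCFFormatError` naming the record.
    """
    from cyvcf2 import VCF

    records: list[AlleleDepth] = []
    skipped = {"multiallelic": 0, "indel": 0, "genotype": 0}
    vcf = VCF(vcf_path)
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            skipped["indel"] += 1
            continue
        gt = v.genotypes[0][:2]
        if sorted(gt) != [0, 1]:
            skipped["genotype"] += 1
            continue
        dp4 = v.INFO.get("DP4")
        if dp4 is None:
            raise VCFFormatError(
                f"{vcf_path}: record {v.CHROM}:{v.POS} {v.REF}>{v.ALT[0]} has no DP4")
        site = HetSite(contig=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
                       rsid=v.ID if v.ID not in (None, ".") else None)
        records.append(AlleleDepth(site, sample_id, tf_label, *map(int, dp4)))
    logger.info("%s: kept %d het SNVs, skipped %s", vcf_path, len(records), skipped)
    return records


# --------------------------------------------------------------- filtering

def read_bed_intervals(path: str) -> dict[str, IntervalTree]:
    """BED3+ into per-contig interval trees (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BEDParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BEDParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end > start:
                trees.setdefault(parts[0], IntervalTree()).addi(start, end)
    return trees


def apply_site_filters(
    records: Iterable[AlleleDepth],
    exclusion_beds: Sequence[str | dict] = (),
    drop_mito: bool = True,
) -> list[AlleleDepth]:
    """Remove records on the mitochondrial contig or inside exclusion BEDs."""
    trees: dict[str, IntervalTree] = {}
    for bed in exclusion_beds:
        parsed = read_bed_intervals(bed) if isinstance(bed, str) else bed
        for contig, tree in parsed.items():
            if contig in trees:
                trees[contig] |= tree
            else:
                trees[contig] = IntervalTree(tree)
    kept = []
    n_mito = n_excl = 0
    for rec in records:
        contig = rec.site.contig
        if drop_mito and contig in MITO_NAMES:
            n_mito += 1
            continue
        tree = trees.get(contig)
        if tree is not None and tree.overlaps_point(rec.site.pos - 1):
            n_excl += 1
            continue
        kept.append(rec)
    logger.info("site filters: dropped %d mitochondrial, %d excluded-region records",
                n_mito, n_excl)
    return kept


# ------------------------------------------------------------- aggregation

def records_to_frame(records: Iterable[AlleleDepth]) -> pd.DataFrame:
    rows = [
        {"contig": r.site.contig, "pos": r.site.pos, "ref": r.site.ref,
         "alt": r.site.alt, "rsid": r.site.rsid or "", "sample_id": r.sample_id,
         "tf_label": r.tf_label, "n_ref_fwd": r.n_ref_fwd, "n_ref_rev": r.n_ref_rev,
         "n_alt_fwd": r.n_alt_fwd, "n_alt_rev": r.n_alt_rev,
         "n_ref": r.n_ref, "n_alt": r.n_alt}
        for r in records
    ]
    return pd.DataFrame(rows)


def aggregate_by_antibody(records: Iterable[AlleleDepth]) -> pd.DataFrame:
    """Sum counts across samples sharing the same anti-TF antibody, per site.

    Returns one row per (tf_label, site) with summed n_ref / n_alt, the
    number of contributing samples, and their ids.  The same (sample, site)
    pair seen twice is a duplicate-input error.
    """
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["tf_label", "contig", "pos", "ref", "alt",
                                     "rsid", "n_ref", "n_alt", "n_samples",
                                     "sample_ids"])
    key = ["tf_label", "sample_id", "contig", "pos", "ref", "alt"]
    dups = df.duplicated(subset=key)
    if dups.any():
        first = df[dups].iloc[0]
        raise ValueError(
            f"duplicate input: sample {first['sample_id']} site "
            f"{first['contig']}:{first['pos']} seen twice")
    grouped = (
        df.groupby(["tf_label", "contig", "pos", "ref", "alt"], sort=True)
        .agg(
            rsid=("rsid", "first"),
            n_ref=("n_ref", "sum"),
            n_alt=("n_alt", "sum"),
            n_samples=("sample_id", "nunique"),
            sample_ids=("sample_id", lambda s: ",".join(sorted(s))),
        )
        .reset_index()
    )
    return grouped


def read_sample_sheet(path: str) -> pd.DataFrame:
    """TSV with columns sample_id, tf_label, vcf_path, is_igg.

    Relative ``vcf_path`` entries are resolved against the sheet's directory.
    """
    import os

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tf_label": str})
    required = {"sample_id", "tf_label", "vcf_path", "is_igg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df["is_igg"] = df["is_igg"].astype(int).astype(bool)
    base = os.path.dirname(os.path.abspath(path))
    df["vcf_path"] = [p if os.path.isabs(p) else os.path.join(base, p)
                      for p in df["vcf_path"]]
    return df
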