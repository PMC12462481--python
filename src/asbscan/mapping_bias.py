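"""Simulated-read mapping-bias filter for candidate allele-specific sites.

A heterozygous site can show apparent allelic imbalance simply because
short reads carrying one allele map less reliably than reads carrying the
other (typically near duplicated sequence).  The filter reconstructs both
allelic sequences of the window around the SNV, draws short reads from
each, maps them back to the genome, and drops sites where the mapped read
counts differ substantially between alleles.

Defaults: 100 reads of length 70 drawn uniformly from the 140-bp window
centered on the SNV per allele, with a site dropped when mapped counts
differ by 20% or more of the larger count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .motif_scan import fetch_seq, revcomp

DNA = set("ACGT")


@dataclass
class BiasSimParams:
    n_reads: int = 100
    read_length: int = 70
    window: int = 140
    diff_threshold: float = 0.2

    def __post_init__(self):
        if self.read_length > self.window:
            raise ValueError("read_length must not exceed window")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def simulate_allele_reads(
    genome,
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    params: BiasSimParams = BiasSimParams(),
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]] | None:
    """Draw paired allele-specific reads from the window around a SNV.

    ``pos`` is 1-based.  Read start offsets are drawn uniformly over all
    positions where a full read fits inside the window and are shared
    between the two alleles (common random numbers), so the read sets
    differ only at reads overlapping the SNV.  Returns ``None`` when the
    window does not fit on the contig (site flagged "edge" by callers).
    """
    rng = rng or np.random.default_rng()
    half = params.window // 2
    pos0 = pos - 1
    start = pos0 - half
    rec = genome[contig]
    contig_len = len(rec)
    if start < 0 or start + params.window > contig_len:
        return None
    window = fetch_seq(genome, contig, start, start + params.window).upper()
    mid = pos0 - start
    if window[mid] != ref.upper():
        raise ValueError(
            f"reference mismatch at {contig}:{pos}: genome {window[mid]} vs {ref}")
    alt_window = window[:mid] + alt.upper() + window[mid + 1 :]
    n_offsets = params.window - params.read_length + 1
    offsets = rng.integers(0, n_offsets, size=params.n_reads)
    L = params.read_length
    ref_reads = [window[o : o + L] for o in offsets]
    alt_reads = [alt_window[o : o + L] for o in offsets]
    snv_idx = [mid - int(o) if 0 <= mid - int(o) < L else None for o in offsets]
    return ref_reads, alt_reads, snv_idx


class ExactUniqueMapper:
    """Counts exact full-length matches of reads in a genome, both strands.

    This is the built-in stand-in for a short-read aligner, adequate for
    error-free reads against small synthetic genomes: a read "maps" iff it
    has exactly one exact occurrence genome-wide (forward occurrences of the
    read plus forward occurrences of its reverse complement).  An index of
    all k-mers at the read length is built lazily per read length.
    """

    def __init__(self, genome):
        if hasattr(genome, "keys"):
            self.contigs = {c: str(genome[c]).upper() for c in genome.keys()}
        else:
            self.contigs = {c: str(genome[c]).upper() for c in genome}
        self._index: dict[int, dict[str, int]] = {}

    def _build(self, k: int) -> dict[str, int]:
        idx: dict[str, int] = {}
        for seq in self.contigs.values():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                c = idx.get(kmer, 0)
                if c < 2:                       # only unique-vs-multi matters
                    idx[kmer] = c + 1
        return idx

    def hit_count(self, read: str) -> int:
        read = read.upper()
        if not set(read) <= DNA:
            return 0
        k = len(read)
        idx = self._index.get(k)
        if idx is None:
            idx = self._index[k] = self._build(k)
        n = idx.get(read, 0)
        rc = revcomp(read)
        if rc != read:
            n += idx.get(rc, 0)
        return n


def map_reads_unique(
    reads: Sequence[str],
    mapper: ExactUniqueMapper,
    snv_idx: Sequence[int | None] | None = None,
    other_base: str | None = None,
) -> int:
    """Number of reads with exactly one match in the genome.

    When ``snv_idx``/``other_base`` are given, matching is allele-aware: a
    read overlapping the SNV also matches locations carrying the other
    allele at that one position (a real aligner tolerates the single known
    mismatch, so a genome carrying the reference base still anchors an
    alternate-allele read).  Without them, matching is strictly exact.
    """
    if snv_idx is None:
        return sum(1 for r in reads if mapper.hit_count(r) == 1)
    n_mapped = 0
    for r, idx in zip(reads, snv_idx):
        hits = mapper.hit_count(r)
        if idx is not None and other_base is not None:
            swapped = r[:idx] + other_base.upper() + r[idx + 1 :]
            if swapped != r:
                hits += mapper.hit_count(swapped)
        if hits == 1:
            n_mapped += 1
    return n_mapped


def mapping_bias_filter(
    mapped_ref: int, mapped_alt: int, diff_threshold: float = 0.2
) -> bool:
    """True to keep the site; drop on >= ``diff_threshold`` relative difference.

    The difference is normalised by the larger allele's mapped count; a site
    where nothing maps for either allele is dropped.
    """
    big = max(mapped_ref, mapped_alt)
    if big == 0:
        return False
    return abs(mapped_ref - mapped_alt) / big < diff_threshold


def mapping_bias_screen(
    genome,
    sites: pd.DataFrame,
    params: BiasSimParams = BiasSimParams(),
    seed: int = 0,
    mapper: Callable[[Sequence[str]], int] | None = None,
) -> pd.DataFrame:
    """Run the full filter over a site table.

    ``sites`` needs columns contig, pos (1-based), ref, alt.  Returns a
    per-site report (mapped_ref, mapped_alt, keep, edge).  ``mapper`` may be
    a callable ``reads -> mapped count`` to substitute a real aligner; the
    default is the exact-unique built-in.
    """
    internal = ExactUniqueMapper(genome) if mapper is None else None
    rows = []
    for i, row in enumerate(sites.itertuples(index=False)):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, i])
        drawn = simulate_allele_reads(
            genome, row.contig, int(row.pos), row.ref, row.alt, params, rng)
        if drawn is None:
            rows.append({"contig": row.contig, "pos": int(row.pos),
                         "mapped_ref": math.nan, "mapped_alt": math.nan,
                         "keep": True, "edge": True})
            continue
        ref_reads, alt_reads, snv_idx = drawn
        if mapper is None:
            m_ref = map_reads_unique(ref_reads, internal, snv_idx, row.alt)
            m_alt = map_reads_unique(alt_reads, internal, snv_idx, row.ref)
        else:
            m_ref = mapper(ref_reads)
            m_alt = mapper(alt_reads)
        rows.append({"contig": row.contig, "pos": int(row.pos),
                     "mapped_ref": m_ref, "mapped_alt": m_alt,
                     "keep": mapping_bias_filter(m_ref, m_alt, params.diff_threshold),
                     "edge": False})
    return pd.DataFrame(rows)
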