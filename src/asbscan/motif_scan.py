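"""Position-weight-matrix scoring with exact p-values, and motif concordance.

A transcription-factor motif is modelled as a position frequency matrix
(PFM) converted to a log-odds matrix against a background base composition.
Match significance is the probability, under the background model, that a
random sequence of the motif's length scores at least as high as the
observed window; that distribution is computed exactly by dynamic
programming over the discretized per-position score distributions, so
p-values do not depend on any sampling step.

At a heterozygous SNV the two alleles are scored over every motif placement
that overlaps the variant, on both strands; the best match per allele is
summarised as -log10 p.  The difference between alleles (ref minus alt) is
the predicted change in motif strength, and its agreement with the observed
direction of allelic binding defines concordance.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: FIMO-style match threshold: an allele "has a motif" if its best placement
#: reaches p <= this value.
MOTIF_P_THRESHOLD = 1e-3

#: Score discretization used by the exact p-value dynamic programme
#: (log2 units per integer step).
DEFAULT_GRANULARITY = 1e-3


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A PFM-derived log-odds scoring model with an exact p-value table.

    ``pvalue_table`` maps an integer (discretized) score ``s`` to
    ``P(score >= s)`` for a random background sequence of the motif length.
    """

    name: str
    tf: str
    probs: np.ndarray            # (L, 4) base probabilities
    background: np.ndarray       # (4,) background probabilities
    logodds: np.ndarray          # (L, 4) log2(prob / background)
    granularity: float = DEFAULT_GRANULARITY
    score_int: np.ndarray = field(default=None, repr=False)   # (L, 4) ints
    _sf: np.ndarray = field(default=None, repr=False)         # survival probs
    _sf_offset: int = field(default=0, repr=False)            # score of _sf[0]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def score_sequence_int(self, seq: str) -> int:
        """Discretized log-odds score of a sequence of exactly the motif length."""
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != motif length {self.length}")
        return int(sum(self.score_int[i, BASE_INDEX[b]] for i, b in enumerate(seq.upper())))

    def pvalue_of_score(self, score: int) -> float:
        """Exact ``P(score >= s)`` under the background model."""
        idx = score - self._sf_offset
        if idx <= 0:
            return 1.0
        if idx >= len(self._sf):
            # above the best attainable score; only reachable for queries,
            # never for a scored sequence
            return 0.0
        return float(self._sf[idx])

    def best_match(self, seq: str) -> "MotifHit":
        """Best-scoring placement of the motif in ``seq``, both strands.

        Placements must fit entirely within ``seq``.
        """
        L = self.length
        if len(seq) < L:
            raise ValueError("sequence shorter than motif")
        best = None
        for strand, s in (("+", seq.upper()), ("-", revcomp(seq).upper())):
            for off in range(len(s) - L + 1):
                window = s[off : off + L]
                if any(b not in BASE_INDEX for b in window):
                    continue
                sc = self.score_sequence_int(window)
                if best is None or sc > best[0]:
                    # report offsets on the forward coordinate system
                    fwd_off = off if strand == "+" else len(seq) - L - off
                    best = (sc, strand, fwd_off)
        if best is None:
            raise ValueError("no scannable placement (non-ACGT sequence)")
        sc, strand, off = best
        p = self.pvalue_of_score(sc)
        return MotifHit(offset=off, strand=strand, score=sc * self.granularity,
                        p_motif=p, neglog10p=-math.log10(p))


@dataclass
class MotifHit:
    offset: int
    strand: str
    score: float
    p_motif: float
    neglog10p: float


def build_motif_model(
    pfm: np.ndarray,
    *,
    name: str = "motif",
    tf: str = "",
    background: Sequence[float] | None = None,
    pseudocount: float = 0.1,
    granularity: float = DEFAULT_GRANULARITY,
) -> MotifModel:
    """Turn a 4xL (or Lx4) count matrix into a scoring model.

    Column probabilities are ``(count + pseudocount*background) /
    (colsum + pseudocount)``; the exact score distribution under the
    background is then built by convolving the per-position discretized
    score distributions.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or 4 not in pfm.shape:
        raise ValueError("PFM must be 4xL or Lx4")
    if pfm.shape[0] == 4 and pfm.shape[1] != 4:
        pfm = pfm.T                      # -> (L, 4)
    if np.any(pfm < 0):
        raise ValueError("PFM counts must be non-negative")
    colsums = pfm.sum(axis=1)
    if np.any(colsums == 0):
        raise ValueError("PFM has a zero column sum")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    probs = (pfm + pseudocount * bg) / (colsums[:, None] + pseudocount)
    logodds = np.log2(probs / bg)
    score_int = np.rint(logodds / granularity).astype(np.int64)

    # exact distribution of the total discretized score for background draws
    dist = np.array([1.0])
    offset = 0
    for i in range(probs.shape[0]):
        vals = score_int[i]
        lo, hi = int(vals.min()), int(vals.max())
        new = np.zeros(len(dist) + hi - lo)
        for b in range(4):
            shift = int(vals[b]) - lo
            new[shift : shift + len(dist)] += bg[b] * dist
        dist = new
        offset += lo
    # sf[j] = P(score >= offset + j)
    sf = np.cumsum(dist[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    return MotifModel(name=name, tf=tf, probs=probs, background=bg,
                      logodds=logodds, granularity=granularity,
                      score_int=score_int, _sf=sf, _sf_offset=offset)


# ---------------------------------------------------------------- JASPAR IO

def read_jaspar(path: str, **kwargs) -> dict[str, MotifModel]:
    """Read JASPAR-format PFMs into MotifModels, keyed by motif name.

    Parsing is delegated to :mod:`Bio.motifs`; the model ``tf`` defaults to
    the motif name.
    """
    from Bio import motifs as bio_motifs

    models: dict[str, MotifModel] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            name = m.name or m.matrix_id
            counts = np.array([m.counts[b] for b in BASES])  # (4, L)
            models[name] = build_motif_model(counts, name=name, tf=name, **kwargs)
    return models


def read_motif_dir(path: str, **kwargs) -> dict[str, MotifModel]:
    models: dict[str, MotifModel] = {}
    for fn in sorted(os.listdir(path)):
        if fn.endswith((".jaspar", ".pfm", ".txt")):
            models.update(read_jaspar(os.path.join(path, fn), **kwargs))
    return models


# ---------------------------------------------------- allele-specific delta

def fetch_seq(genome, contig: str, start: int, end: int) -> str:
    """0-based half-open fetch from a dict of strings or a pyfaidx.Fasta."""
    rec = genome[contig]
    if isinstance(rec, str):
        return rec[max(start, 0) : end]
    return str(rec[max(start, 0) : end])


@dataclass
class AlleleMotifDelta:
    neglog10p_ref: float
    neglog10p_alt: float
    delta: float
    motif_overlapping: bool
    edge: bool = False


def allele_motif_delta(
    genome,
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    model: MotifModel,
    *,
    threshold: float = MOTIF_P_THRESHOLD,
) -> AlleleMotifDelta:
    """Best motif match for each allele over placements covering the SNV.

    ``pos`` is the 1-based variant position.  The scanned window is
    ``[pos-L+1, pos+L-1]`` (1-based, inclusive): exactly the placements whose
    score can differ between alleles.  ``delta > 0`` means the alternate
    allele is predicted to weaken the motif.
    """
    L = model.length
    pos0 = pos - 1
    start, end = pos0 - L + 1, pos0 + L
    contig_len = len(genome[contig]) if isinstance(genome[contig], str) else len(genome[contig])
    if start < 0 or end > contig_len:
        return AlleleMotifDelta(math.nan, math.nan, math.nan, False, edge=True)
    window = fetch_seq(genome, contig, start, end).upper()
    mid = pos0 - start
    if window[mid] != ref.upper():
        raise ValueError(
            f"reference mismatch at {contig}:{pos}: genome has {window[mid]}, VCF ref {ref}")
    ref_seq = window
    alt_seq = window[:mid] + alt.upper() + window[mid + 1 :]
    hit_ref = model.best_match(ref_seq)
    hit_alt = model.best_match(alt_seq)
    overlapping = min(hit_ref.p_motif, hit_alt.p_motif) <= threshold
    return AlleleMotifDelta(
        neglog10p_ref=hit_ref.neglog10p,
        neglog10p_alt=hit_alt.neglog10p,
        delta=hit_ref.neglog10p - hit_alt.neglog10p,
        motif_overlapping=overlapping,
    )


# -------------------------------------------------------------- concordance

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNCLASSIFIED = "unclassified"


def classify_concordance(
    delta: float, n_ref: int, n_alt: int, motif_overlapping: bool = True
) -> str:
    """Agreement between predicted motif-strength change and binding change.

    Concordant when the allele with the stronger predicted motif also has
    more reads; discordant when the directions oppose; unclassified when the
    site is not motif-overlapping or either quantity is zero.
    """
    if not motif_overlapping or delta is None or not np.isfinite(delta):
        return UNCLASSIFIED
    d_binding = n_ref - n_alt
    if delta == 0 or d_binding == 0:
        return UNCLASSIFIED
    return CONCORDANT if (delta > 0) == (d_binding > 0) else DISCORDANT


def concordance_summary(df) -> "pandas.DataFrame":  # noqa: F821
    """Per-TF concordant/discordant counts and their ratio."""
    import pandas as pd

    rows = []
    for tf, grp in df.groupby("tf"):
        n_con = int((grp["concordance"] == CONCORDANT).sum())
        n_dis = int((grp["concordance"] == DISCORDANT).sum())
        ratio = n_con / n_dis if n_dis else math.inf if n_con else math.nan
        rows.append({"tf": tf, "n_concordant": n_con, "n_discordant": n_dis,
                     "ratio": ratio})
    return pd.DataFrame(rows)
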