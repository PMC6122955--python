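"""Promoter-window motif scanning and over-representation scoring.

Motifs are IUPAC degenerate consensus strings (e.g. the stringent HNF1A
site ``DGTTAATNATTAAC``) or position weight matrices scored at a relative
threshold. Over-representation of a motif in a foreground gene set against
a background set is scored with a binomial per-nucleotide z:

    p_bg  = x_b / L_b            background per-position hit rate
    mu    = L_t * p_bg           expected foreground hits
    sigma = sqrt(L_t * p_bg * (1 - p_bg))
    z     = (x_t - mu) / sigma

where x is a hit count and L a scanned-position count (both strands). An
exact two-sided binomial p-value is reported alongside the z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GeneModel

logger = logging.getLogger(__name__)

#: The stringent consensus binding site of HNF1A (D = A/G/T, N = any base).
HNF1A_CONSENSUS = "DGTTAATNATTAAC"
#: Its 7-base half-site; dense enough to yield measurable background rates
#: in desk-scale promoter sets.
HNF1A_HALF_SITE = "GTTAATG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """An IUPAC consensus or weight-matrix motif.

    ``matrix`` has shape (length, 4) in A/C/G/T column order; a matrix hit
    requires relative score (S - S_min)/(S_max - S_min) >= ``rel_threshold``.
    """

    name: str
    consensus: Optional[str] = None
    matrix: Optional[np.ndarray] = None
    rel_threshold: float = 0.85
    window_bp: int = 5_000

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.matrix is None):
            raise ValueError("provide exactly one of consensus or matrix")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes in consensus: {sorted(bad)}")
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
                raise ValueError("matrix must have shape (length, 4)")
        if not (0 < self.rel_threshold <= 1):
            raise ValueError("rel_threshold must be in (0, 1]")

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.matrix.shape[0]


@dataclass
class MotifHit:
    position: int  # forward-strand coordinate of the match start
    strand: str
    score: Optional[float] = None


@dataclass
class MotifEnrichmentResult:
    name: str
    x_t: int
    L_t: int
    x_b: int
    L_b: int
    p_bg: float
    mu: Optional[float]
    sigma: Optional[float]
    zscore: Optional[float]
    binom_p: Optional[float]
    gene_hits: int = 0
    degenerate_background: bool = False


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to 0..3 for A/C/G/T and 4 for N or anything else."""
    codes = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[ord(base)] = idx
        codes[ord(base.lower())] = idx
    return codes[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_forward(codes: np.ndarray, motif: MotifModel) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Match start positions (and matrix scores) on the given strand."""
    m = motif.length
    n = codes.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=int), None
    if motif.consensus is not None:
        # allowed[i, code]: column 4 (N in the sequence) never matches
        allowed = np.zeros((m, 5), dtype=bool)
        for i, sym in enumerate(motif.consensus):
            for base in IUPAC[sym]:
                allowed[i, _BASE_INDEX[base]] = True
        ok = np.ones(n, dtype=bool)
        for i in range(m):
            ok &= allowed[i, codes[i : i + n]]
        return np.nonzero(ok)[0], None
    # matrix mode: N positions contribute -inf so masked bases never hit
    col_min = motif.matrix.min(axis=1)
    padded = np.concatenate([motif.matrix, np.full((m, 1), -np.inf)], axis=1)
    score = np.zeros(n, dtype=float)
    for i in range(m):
        score += padded[i, codes[i : i + n]]
    s_min = float(col_min.sum())
    s_max = float(motif.matrix.max(axis=1).sum())
    if s_max == s_min:
        rel = np.where(score >= s_max, 1.0, 0.0)
    else:
        rel = (score - s_min) / (s_max - s_min)
    hits = np.nonzero(rel >= motif.rel_threshold)[0]
    return hits, rel[hits]


def scan_sequence(seq: str, motif: MotifModel, strands: str = "both") -> list[MotifHit]:
    """All motif match positions in ``seq``; overlapping hits are all reported.

    Reverse-strand hits are found by scanning the reverse complement and
    reported in forward coordinates (position of the match's leftmost base).
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    if len(seq) < motif.length:
        return []
    codes = _encode(seq)
    fwd, fwd_scores = _scan_forward(codes, motif)
    hits = [
        MotifHit(int(p), "+", float(fwd_scores[i]) if fwd_scores is not None else None)
        for i, p in enumerate(fwd)
    ]
    if strands == "both":
        rc_codes = _encode(reverse_complement(seq))
        rev, rev_scores = _scan_forward(rc_codes, motif)
        L, m = len(seq), motif.length
        for i, p in enumerate(rev):
            hits.append(
                MotifHit(L - m - int(p), "-",
                         float(rev_scores[i]) if rev_scores is not None else None)
            )
    return sorted(hits, key=lambda h: (h.position, h.strand))


def extract_windows(
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    window_bp: int = 5_000,
) -> dict[str, str]:
    """Per-gene +/-``window_bp`` TSS windows.

    ``sequences`` may be keyed by chromosome (windows are cut out, clipped
    to the sequence bounds, and reverse-complemented for -strand genes so
    upstream reads 5'->3') or directly by gene id (pre-extracted windows
    are passed through). Genes without a sequence are skipped with a log
    message.
    """
    out: dict[str, str] = {}
    for g in genes:
        if g.gene_id in sequences:
            out[g.gene_id] = sequences[g.gene_id]
            continue
        chrom_seq = sequences.get(g.chrom)
        if chrom_seq is None:
            logger.warning("extract_windows: no sequence for gene %s (%s)", g.gene_id, g.chrom)
            continue
        lo = max(0, g.tss - window_bp)
        hi = min(len(chrom_seq), g.tss + window_bp)
        window = chrom_seq[lo:hi]
        out[g.gene_id] = reverse_complement(window) if g.strand == "-" else window
    return out


def count_hits(
    windows: Mapping[str, str], motif: MotifModel, strands: str = "both"
) -> tuple[int, int, int]:
    """Total hit count, scanned-position count, and #genes with >=1 hit."""
    per_strand = 2 if strands == "both" else 1
    total_hits = 0
    total_positions = 0
    genes_hit = 0
    for seq in windows.values():
        n = max(0, len(seq) - motif.length + 1)
        total_positions += per_strand * n
        k = len(scan_sequence(seq, motif, strands)) if n else 0
        total_hits += k
        genes_hit += bool(k)
    return total_hits, total_positions, genes_hit


def enrichment_zscore(
    fg_hits: int, fg_len: int, bg_hits: int, bg_len: int,
    name: str = "", gene_hits: int = 0,
) -> MotifEnrichmentResult:
    """Binomial per-nucleotide over-representation z (no continuity correction)."""
    if fg_len <= 0 or bg_len <= 0:
        raise ValueError("scanned-position counts must be positive")
    if bg_hits > bg_len or fg_hits > fg_len:
        raise ValueError("hit count exceeds scanned positions")
    p_bg = bg_hits / bg_len
    if p_bg <= 0.0 or p_bg >= 1.0:
        return MotifEnrichmentResult(
            name=name, x_t=fg_hits, L_t=fg_len, x_b=bg_hits, L_b=bg_len,
            p_bg=p_bg, mu=None, sigma=None, zscore=None, binom_p=None,
            gene_hits=gene_hits, degenerate_background=True,
        )
    mu = fg_len * p_bg
    sigma = float(np.sqrt(fg_len * p_bg * (1.0 - p_bg)))
    z = (fg_hits - mu) / sigma
    binom_p = float(stats.binomtest(fg_hits, fg_len, p_bg).pvalue)
    return MotifEnrichmentResult(
        name=name, x_t=fg_hits, L_t=fg_len, x_b=bg_hits, L_b=bg_len,
        p_bg=p_bg, mu=mu, sigma=sigma, zscore=z, binom_p=binom_p,
        gene_hits=gene_hits,
    )


def motif_enrichment(
    fg_genes: Iterable[str],
    bg_genes: Iterable[str],
    windows: Mapping[str, str],
    motif: MotifModel,
    strands: str = "both",
) -> MotifEnrichmentResult:
    """Score one motif's over-representation in foreground vs background windows."""
    fg = {g: windows[g] for g in fg_genes if g in windows}
    bg = {g: windows[g] for g in bg_genes if g in windows}
    x_t, L_t, genes_hit = count_hits(fg, motif, strands)
    x_b, L_b, _ = count_hits(bg, motif, strands)
    return enrichment_zscore(x_t, L_t, x_b, L_b, name=motif.name, gene_hits=genes_hit)


def read_motifs_tsv(path) -> list[MotifModel]:
    """Read motifs from a two-column TSV (name, IUPAC consensus), header optional."""
    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>consensus")
            if lineno == 1 and fields[0].lower() in ("name", "motif"):
                continue
            motifs.append(MotifModel(name=fields[0], consensus=fields[1]))
    return motifs


def rank_motifs(results: Sequence[MotifEnrichmentResult]) -> list[MotifEnrichmentResult]:
    """Descending by z; missing z last; ties by gene_hits (desc) then name."""
    def key(r: MotifEnrichmentResult):
        missing = r.zscore is None
        return (missing, -(r.zscore or 0.0), -r.gene_hits, r.name)

    return sorted(results, key=key)
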