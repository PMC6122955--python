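"""Peak-to-gene TSS annotation and proximal/distal binding classification.

Each peak is assigned to the closest *expressed* gene's TSS (reference
point: peak summit when called, else midpoint). Classification is
reciprocal: a gene's candidate peaks are exactly the peaks assigned to it,
so a peak that sits nearer another gene never classifies this one. Per
replicate, a gene is *proximal* if its nearest candidate peak lies within
``proximal_bp`` of the TSS, else *distal* within ``distal_bp``, else
*none*. Cross-cell-line consensus:

1. proximal  — >=1 replicate of every cell line proximal;
2. distal    — otherwise, every replicate of every cell line distal;
3. neither   — any other mix, or no peak at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntervalSet, Peak


@dataclass(frozen=True)
class PeakAnnotationConfig:
    proximal_bp: int = 5_000
    distal_bp: int = 100_000
    reference_point: str = "summit"  # "summit" (fall back to midpoint) or "midpoint"

    def __post_init__(self) -> None:
        if not (0 < self.proximal_bp < self.distal_bp):
            raise ValueError("require 0 < proximal_bp < distal_bp")
        if self.reference_point not in ("summit", "midpoint"):
            raise ValueError("reference_point must be 'summit' or 'midpoint'")


@dataclass
class PeakAssignment:
    """One peak's nearest-TSS assignment (``gene_id`` is None off-gene chromosomes)."""

    peak: Peak
    gene_id: Optional[str]
    distance: Optional[int]


@dataclass
class GeneBindingCall:
    gene_id: str
    per_replicate_class: dict[tuple[str, str], str] = field(default_factory=dict)
    consensus_class: str = "neither"
    nearest_distance: Optional[int] = None
    assigned_peaks: list[Peak] = field(default_factory=list)
    enhancer_flag: Optional[bool] = None


class _TssIndex:
    """Per-chromosome sorted TSS arrays with deterministic tie-breaking."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = (
                np.array([g.tss for g in gs], dtype=np.int64),
                [g.gene_id for g in gs],
            )

    def nearest(self, chrom: str, pos: int) -> tuple[Optional[str], Optional[int]]:
        """Closest gene by |TSS - pos|; equidistant ties go to the smaller gene_id."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None, None
        tss, ids = entry
        i = int(np.searchsorted(tss, pos))
        best_d: Optional[int] = None
        best_id: Optional[str] = None
        # check the flanking TSS values; equal TSSs are adjacent and sorted
        # by gene_id, so the first index of a group is its minimal id
        for j in (i - 1, i):
            if 0 <= j < len(ids):
                d = abs(int(tss[j]) - pos)
                # walk left to the first gene sharing this TSS (min gene_id)
                k = j
                while k > 0 and tss[k - 1] == tss[j]:
                    k -= 1
                cand = ids[k]
                if best_d is None or d < best_d or (d == best_d and cand < best_id):
                    best_d, best_id = d, cand
        return best_id, best_d


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    cfg: PeakAnnotationConfig | None = None,
) -> list[PeakAssignment]:
    """Assign each peak to the closest gene TSS on its chromosome."""
    cfg = cfg or PeakAnnotationConfig()
    index = _TssIndex(genes)
    out = []
    for peak in peaks:
        ref = peak.interval.midpoint if cfg.reference_point == "midpoint" else peak.reference_point()
        gene_id, dist = index.nearest(peak.chrom, ref)
        out.append(PeakAssignment(peak, gene_id, dist))
    return out


def classify_replicate(
    assignments: Sequence[PeakAssignment],
    genes: Sequence[GeneModel],
    cfg: PeakAnnotationConfig | None = None,
) -> dict[str, tuple[str, Optional[int]]]:
    """Per-gene class for one replicate from that replicate's assignments.

    Returns ``{gene_id: (class, nearest_candidate_distance)}`` with class in
    {"proximal", "distal", "none"}; genes without candidate peaks get
    ("none", None).
    """
    cfg = cfg or PeakAnnotationConfig()
    nearest: dict[str, int] = {}
    for a in assignments:
        if a.gene_id is None:
            continue
        if a.gene_id not in nearest or a.distance < nearest[a.gene_id]:
            nearest[a.gene_id] = a.distance
    result: dict[str, tuple[str, Optional[int]]] = {}
    for g in genes:
        d = nearest.get(g.gene_id)
        if d is None:
            result[g.gene_id] = ("none", None)
        elif d <= cfg.proximal_bp:
            result[g.gene_id] = ("proximal", d)
        elif d <= cfg.distal_bp:
            result[g.gene_id] = ("distal", d)
        else:
            result[g.gene_id] = ("none", d)
    return result


def consensus_classification(per_replicate: Mapping[tuple[str, str], str]) -> str:
    """Cross-cell-line consensus from per-replicate classes.

    ``per_replicate`` maps (cell_line, replicate) -> class. Requires >=1
    replicate per cell line.
    """
    by_line: dict[str, list[str]] = {}
    for (cell_line, _rep), cls in per_replicate.items():
        by_line.setdefault(cell_line, []).append(cls)
    if not by_line:
        raise ValueError("no replicate classes supplied")
    if all("proximal" in classes for classes in by_line.values()):
        return "proximal"
    all_classes = [c for classes in by_line.values() for c in classes]
    if all(c == "distal" for c in all_classes):
        return "distal"
    return "neither"


def classify_genes(
    peaks_by_replicate: Mapping[tuple[str, str], Sequence[Peak]],
    genes: Sequence[GeneModel],
    cfg: PeakAnnotationConfig | None = None,
) -> list[GeneBindingCall]:
    """Full per-gene binding classification across all replicates.

    ``peaks_by_replicate`` maps (cell_line, replicate) -> blacklist-filtered
    peaks; ``genes`` must already be restricted to the expressed set.
    """
    cfg = cfg or PeakAnnotationConfig()
    per_rep_classes: dict[str, dict[tuple[str, str], str]] = {
        g.gene_id: {} for g in genes
    }
    per_gene_peaks: dict[str, list[Peak]] = {g.gene_id: [] for g in genes}
    per_gene_nearest: dict[str, Optional[int]] = {g.gene_id: None for g in genes}

    for key, peaks in peaks_by_replicate.items():
        assignments = assign_peaks(peaks, genes, cfg)
        for a in assignments:
            if a.gene_id is not None:
                per_gene_peaks[a.gene_id].append(a.peak)
        classes = classify_replicate(assignments, genes, cfg)
        for gene_id, (cls, dist) in classes.items():
            per_rep_classes[gene_id][key] = cls
            if dist is not None:
                prev = per_gene_nearest[gene_id]
                per_gene_nearest[gene_id] = dist if prev is None else min(prev, dist)

    calls = []
    for g in genes:
        calls.append(
            GeneBindingCall(
                gene_id=g.gene_id,
                per_replicate_class=per_rep_classes[g.gene_id],
                consensus_class=consensus_classification(per_rep_classes[g.gene_id]),
                nearest_distance=per_gene_nearest[g.gene_id],
                assigned_peaks=per_gene_peaks[g.gene_id],
            )
        )
    return calls


def common_peaks(
    peaks_a: Mapping[str, Sequence[Peak]], peaks_b: Mapping[str, Sequence[Peak]]
) -> tuple[list[Peak], list[Peak]]:
    """Peaks reproducible across the two cell lines.

    A peak of line A is retained iff it overlaps >=1 peak from >=1 replicate
    of line B, and symmetrically. Inputs map replicate label -> peaks.
    """
    def _flatten(d: Mapping[str, Sequence[Peak]]) -> list[Peak]:
        return [p for peaks in d.values() for p in peaks]

    index_b = IntervalSet(p.interval for p in _flatten(peaks_b))
    index_a = IntervalSet(p.interval for p in _flatten(peaks_a))
    kept_a = [p for p in _flatten(peaks_a) if index_b.overlaps(p.interval)]
    kept_b = [p for p in _flatten(peaks_b) if index_a.overlaps(p.interval)]
    return kept_a, kept_b


def enhancer_overlap_report(
    calls: Sequence[GeneBindingCall], enhancers: Iterable[GenomicInterval]
) -> tuple[dict[str, bool], Optional[float]]:
    """Flag bound genes whose assigned peaks touch a merged enhancer region.

    Returns the per-gene flags (all genes) and the fraction of *bound*
    genes (consensus proximal or distal) flagged; None when no gene is
    bound. Flags are also written back onto the calls.
    """
    index = IntervalSet(enhancers)
    flags: dict[str, bool] = {}
    n_bound = 0
    n_flagged = 0
    for call in calls:
        flag = any(index.overlaps(p.interval) for p in call.assigned_peaks)
        flags[call.gene_id] = flag
        call.enhancer_flag = flag
        if call.consensus_class in ("proximal", "distal"):
            n_bound += 1
            if flag:
                n_flagged += 1
    fraction = n_flagged / n_bound if n_bound else None
    return flags, fraction


def calls_to_frame(calls: Sequence[GeneBindingCall]) -> pd.DataFrame:
    """Tabular view: gene_id, consensus_class, nearest_distance, enhancer_flag."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "consensus_class": [c.consensus_class for c in calls],
            "nearest_distance": [c.nearest_distance for c in calls],
            "enhancer_flag": [c.enhancer_flag for c in calls],
        }
    )
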