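"""Differential-transcription gene selection from nascent-RNA knockdown contrasts.

Per-gene statistics (log2 fold change, p, adjusted p, mean RPKM, gene
length) for each (cell line, shRNA) knockdown-vs-control contrast are
consumed as input; this module applies the selection thresholds, intersects
calls across cell lines into directional regulated sets, and defines the
expressed-gene backgrounds used by the peak-annotation and survival stages.

Direction convention: a *negative* knockdown log2 fold change (gene goes
down when the factor is depleted) marks a factor-*activated* gene; positive
marks a repressed gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Columns expected in a per-contrast statistics table.
CONTRAST_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "mean_rpkm", "gene_length"]


@dataclass(frozen=True)
class DESelectionConfig:
    """Thresholds for calling a gene differentially transcribed in a contrast.

    All comparisons are strict, exactly as the thresholds are printed:
    ``mean_rpkm > rpkm_min``, ``gene_length >= length_min``,
    ``|log2fc| > lfc_min`` (0.58 ~ 1.5-fold), ``padj < padj_max``.
    """

    rpkm_min: float = 0.25
    length_min: int = 300
    lfc_min: float = 0.58
    padj_max: float = 0.1

    def __post_init__(self) -> None:
        if min(self.rpkm_min, self.length_min, self.lfc_min, self.padj_max) <= 0:
            raise ValueError("all selection thresholds must be > 0")


@dataclass
class DirectionalGeneSets:
    """Cross-cell-line intersection of directional differential calls.

    ``upregulated`` holds genes *down* after knockdown in >=1 shRNA of every
    cell line (i.e. activated by the factor); ``downregulated`` is the
    mirror image. Genes qualifying in opposite directions in different cell
    lines land in ``conflicted`` and belong to neither set.
    """

    upregulated: set[str] = field(default_factory=set)
    downregulated: set[str] = field(default_factory=set)
    conflicted: set[str] = field(default_factory=set)
    per_gene_evidence: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j>=i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_contrast(stats: pd.DataFrame, cfg: DESelectionConfig | None = None) -> pd.DataFrame:
    """Apply the selection thresholds to one contrast's statistics table.

    Returns a frame with ``gene_id``, ``passed`` (bool) and ``direction``
    (sign of log2fc: -1, 0, +1). A missing (NaN) adjusted p fails the gene
    and is logged, never raised.
    """
    cfg = cfg or DESelectionConfig()
    missing = [c for c in ("gene_id", "log2fc", "padj", "mean_rpkm", "gene_length") if c not in stats.columns]
    if missing:
        raise ValueError(f"contrast table missing columns {missing}")
    padj = stats["padj"].to_numpy(dtype=float)
    n_missing = int(np.isnan(padj).sum())
    if n_missing:
        logger.info("select_de_contrast: %d genes lack an adjusted p and fail", n_missing)
    lfc = stats["log2fc"].to_numpy(dtype=float)
    base = (
        (stats["mean_rpkm"].to_numpy(dtype=float) > cfg.rpkm_min)
        & (stats["gene_length"].to_numpy(dtype=float) >= cfg.length_min)
        & (np.abs(lfc) > cfg.lfc_min)
    )
    return pd.DataFrame(
        {
            "gene_id": stats["gene_id"].astype(str),
            "passed": base & (padj < cfg.padj_max),  # NaN compares False
            "passed_no_padj": base,
            "direction": np.sign(lfc).astype(int),
        }
    )


def intersect_directional(
    calls: Mapping[tuple[str, str], pd.DataFrame],
    padj_required_lines: set[str] | None = None,
) -> DirectionalGeneSets:
    """Intersect per-contrast calls across cell lines into directional sets.

    ``calls`` maps (cell_line, shRNA) to the output of
    :func:`select_de_contrast`. A gene enters a directional set iff it
    passes with that sign in at least one shRNA of *every* cell line.
    Opposite-direction qualification across cell lines disqualifies the
    gene (recorded in ``conflicted``).

    ``padj_required_lines`` switches to the variant rule in which the
    adjusted-p criterion is enforced only in the named cell lines; in the
    others the fold-change/expression/length criteria alone qualify a
    contrast. The default (None) requires adjusted p everywhere.
    """
    lines = sorted({cl for cl, _ in calls})
    if not lines:
        raise ValueError("no contrasts supplied")
    neg_lines: dict[str, set[str]] = {}
    pos_lines: dict[str, set[str]] = {}
    evidence: dict[str, list[tuple[str, str, int]]] = {}
    for (cell_line, shrna), df in calls.items():
        if padj_required_lines is not None and cell_line not in padj_required_lines:
            hit = df.loc[df["passed_no_padj"]]
        else:
            hit = df.loc[df["passed"]]
        for gene, direction in zip(hit["gene_id"], hit["direction"]):
            evidence.setdefault(gene, []).append((cell_line, shrna, int(direction)))
            if direction < 0:
                neg_lines.setdefault(gene, set()).add(cell_line)
            elif direction > 0:
                pos_lines.setdefault(gene, set()).add(cell_line)

    result = DirectionalGeneSets(per_gene_evidence=evidence)
    all_lines = set(lines)
    for gene in evidence:
        neg_all = neg_lines.get(gene, set()) == all_lines
        pos_all = pos_lines.get(gene, set()) == all_lines
        if neg_all and not pos_all:
            result.upregulated.add(gene)
        elif pos_all and not neg_all:
            result.downregulated.add(gene)
        elif gene in neg_lines and gene in pos_lines:
            result.conflicted.add(gene)
    if result.conflicted:
        logger.info("intersect_directional: %d direction-conflicted genes excluded",
                    len(result.conflicted))
    return result


def expressed_background(rpkm: pd.DataFrame, threshold: float = 0.5) -> set[str]:
    """Background gene set: RPKM above ``threshold`` in >=1 replicate of every cell line.

    ``rpkm`` is long format with columns gene_id, cell_line, replicate, rpkm.
    """
    needed = {"gene_id", "cell_line", "rpkm"}
    if not needed.issubset(rpkm.columns):
        raise ValueError(f"replicate RPKM table needs columns {sorted(needed)}")
    lines = rpkm["cell_line"].nunique()
    per_line_max = rpkm.groupby(["gene_id", "cell_line"])["rpkm"].max()
    ok = (per_line_max > threshold).groupby("gene_id").agg(["sum", "count"])
    # a gene must clear the threshold in every cell line present in the table
    genes = ok.index[(ok["sum"] == lines) & (ok["count"] == lines)]
    return set(map(str, genes))


def expressed_for_peaks(
    mean_rpkm: Mapping[str, float] | pd.Series, threshold: float = 0.25
) -> set[str]:
    """Expressed-gene set for peak assignment: mean RPKM strictly above threshold."""
    series = pd.Series(mean_rpkm, dtype=float)
    return set(series.index[series > threshold].astype(str))
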