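"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here with a known answer key, so the
full chain — peak annotation, differential-transcription selection, motif
enrichment, survival association — is testable end to end without external
data. The generators emulate the statistical structure of the study
designs they stand in for:

* a compact genome of gene models with strand-aware TSSs;
* replicated ChIP peak sets: bound genes receive a peak near their TSS per
  replicate (with placement jitter and dropout) on top of uniform
  background peaks;
* knockdown differential-transcription tables per (cell line, shRNA)
  contrast: planted effects with Gaussian noise, null genes with uniform
  p-values;
* promoter windows with consensus motif sites planted at a controlled rate
  in designated genes over an i.i.d. background of stated GC content;
* a survival cohort with exponential event times whose hazard depends
  log-linearly on the standardized log10(x+1) expression of planted
  signature genes, independent exponential censoring, and a labelled
  to-be-excluded histology subgroup.

Determinism: each generator takes one integer seed; sub-streams (per cell
line / replicate / contrast) are derived from it with
:func:`derive_rng` (CRC32 of a text label mixed into a SeedSequence), so
identical seed + parameters give identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .de import bh_adjust
from .intervals import GeneModel, GenomicInterval, Peak
from .motif import IUPAC, MotifModel
from .survival import DEFAULT_EXCLUDED_HISTOLOGIES

_BASES = np.array(list("ACGT"))


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic sub-stream: seed mixed with a CRC32 of the label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(label.encode())])
    )


@dataclass
class SimTruth:
    """Answer key for a simulated input bundle."""

    seed: int
    bound_genes: set[str] = field(default_factory=set)
    activated_genes: set[str] = field(default_factory=set)
    repressed_genes: set[str] = field(default_factory=set)
    hazard_genes: dict[str, float] = field(default_factory=dict)
    motif_genes: set[str] = field(default_factory=set)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)


def simulate_genome(
    n_chrom: int = 2,
    genes_per_chrom: int = 100,
    mean_spacing: int = 50_000,
    seed: int = 0,
    length_median: float = 20_000.0,
    length_sigma: float = 2.0,
) -> list[GeneModel]:
    """Gene models on ``n_chrom`` chromosomes with exponential TSS spacing.

    Gene lengths are log-normal (median ``length_median``, log-sd
    ``length_sigma``), so a small tail falls below the 300-base length
    filter. All TSSs are distinct; strands are random.
    """
    if n_chrom < 1 or genes_per_chrom < 1:
        raise ValueError("counts must be >= 1")
    if mean_spacing < 1000:
        raise ValueError("mean_spacing must be >= 1000")
    rng = derive_rng(seed, "genome")
    genes: list[GeneModel] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        gaps = np.maximum(1, rng.exponential(mean_spacing, size=genes_per_chrom).astype(np.int64))
        tss = 1_000_000 + np.cumsum(gaps)
        lengths = np.maximum(
            50, rng.lognormal(np.log(length_median), length_sigma, size=genes_per_chrom)
        ).astype(np.int64)
        strands = rng.choice(["+", "-"], size=genes_per_chrom)
        for i in range(genes_per_chrom):
            gene_id = f"G{c * genes_per_chrom + i + 1:04d}"
            t, ln, s = int(tss[i]), int(lengths[i]), strands[i]
            if s == "+":
                iv = GenomicInterval(chrom, t, t + ln, "+")
            else:
                start = max(0, t + 1 - ln)
                iv = GenomicInterval(chrom, start, t + 1, "-")
            genes.append(GeneModel(gene_id=gene_id, interval=iv))
    return genes


def chromosome_lengths(genes: Sequence[GeneModel], margin: int = 100_000) -> dict[str, int]:
    """Per-chromosome extent implied by the gene models plus a margin."""
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.interval.end + margin)
    return lengths


def simulate_peaks(
    genes: Sequence[GeneModel],
    bound_fraction: float = 0.2,
    cell_lines: Sequence[str] = ("NY8", "NY15"),
    replicates_per_line: int = 2,
    placement_sd: float = 200.0,
    dropout: float = 0.1,
    background_rate: float = 5.0,
    seed: int = 0,
    peak_width: int = 300,
) -> tuple[dict[tuple[str, str], list[Peak]], SimTruth]:
    """Replicated peak sets with planted TSS-bound genes plus background.

    Each bound gene receives, per replicate, a peak centred at
    TSS + Normal(0, ``placement_sd``) with probability 1 - ``dropout``;
    background peaks land uniformly at ``background_rate`` per Mb.
    """
    if not (0 <= bound_fraction <= 1 and 0 <= dropout <= 1):
        raise ValueError("bound_fraction and dropout must lie in [0, 1]")
    rng = derive_rng(seed, "peaks/truth")
    n_bound = round(bound_fraction * len(genes))
    bound = sorted(
        g.gene_id for g in rng.choice(np.array(genes, dtype=object), size=n_bound, replace=False)
    ) if n_bound else []
    bound_set = set(bound)
    truth = SimTruth(seed=seed, bound_genes=bound_set)
    chrom_len = chromosome_lengths(genes)
    half = peak_width // 2

    def _make_peak(center: int, chrom: str, line: str, rep: str) -> Peak:
        start = max(0, center - half)
        end = start + peak_width
        summit = min(max(center, start), end - 1)
        return Peak(GenomicInterval(chrom, start, end), cell_line=line, replicate=rep, summit=summit)

    out: dict[tuple[str, str], list[Peak]] = {}
    for line in cell_lines:
        for r in range(1, replicates_per_line + 1):
            rep = f"rep{r}"
            sub = derive_rng(seed, f"peaks/{line}/{rep}")
            peaks: list[Peak] = []
            for g in genes:
                if g.gene_id in bound_set and sub.random() >= dropout:
                    center = int(round(g.tss + sub.normal(0.0, placement_sd)))
                    peaks.append(_make_peak(center, g.chrom, line, rep))
            for chrom, length in sorted(chrom_len.items()):
                n_bg = sub.poisson(background_rate * length / 1e6)
                for pos in sorted(sub.integers(0, length, size=n_bg)):
                    peaks.append(_make_peak(int(pos), chrom, line, rep))
            out[(line, rep)] = peaks
    return out, truth


def simulate_de_tables(
    genes: Sequence[GeneModel],
    activated: Iterable[str],
    repressed: Iterable[str],
    effect_log2fc: float = 1.0,
    noise_sd: float = 0.2,
    cell_lines: Sequence[str] = ("NY8", "NY15"),
    shrnas: Sequence[str] = ("sh1", "sh2"),
    seed: int = 0,
    replicates_per_line: int = 2,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame, SimTruth]:
    """Knockdown differential-transcription tables with planted effects.

    Activated genes get log2FC ~ -effect + noise (they drop when the factor
    is knocked down), repressed genes the mirror image, null genes ~ noise.
    The two-sided normal p-value of log2fc / noise_sd makes null p-values
    Uniform(0,1); adjusted p is Benjamini-Hochberg within each contrast.
    Also returns a per-replicate RPKM table (gene_id, cell_line, replicate,
    rpkm) for the expressed-background definition.

    Per-gene mean RPKM is log-normal(log 2, 1.5), putting roughly 8% of
    genes below the 0.25 RPKM expression filter.
    """
    activated, repressed = set(activated), set(repressed)
    if activated & repressed:
        raise ValueError("activated and repressed sets must be disjoint")
    truth = SimTruth(seed=seed, activated_genes=activated, repressed_genes=repressed)
    rng = derive_rng(seed, "de/base")
    gene_ids = [g.gene_id for g in genes]
    lengths = {g.gene_id: g.length for g in genes}
    base_rpkm = rng.lognormal(np.log(2.0), 1.5, size=len(genes))
    true_lfc = np.zeros(len(genes))
    for i, gid in enumerate(gene_ids):
        if gid in activated:
            true_lfc[i] = -effect_log2fc
        elif gid in repressed:
            true_lfc[i] = effect_log2fc

    se_nominal = max(noise_sd, 1e-8)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    from scipy.stats import norm  # local import keeps module load light

    for line in cell_lines:
        for sh in shrnas:
            sub = derive_rng(seed, f"de/{line}/{sh}")
            obs = true_lfc + sub.normal(0.0, noise_sd, size=len(genes))
            pvals = np.clip(2.0 * norm.sf(np.abs(obs) / se_nominal), np.finfo(float).tiny, 1.0)
            mean_rpkm = base_rpkm * sub.lognormal(0.0, 0.1, size=len(genes))
            tables[(line, sh)] = pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "log2fc": obs,
                    "pvalue": pvals,
                    "padj": bh_adjust(pvals),
                    "mean_rpkm": mean_rpkm,
                    "gene_length": [lengths[g] for g in gene_ids],
                }
            )

    rows = []
    for line in cell_lines:
        for r in range(1, replicates_per_line + 1):
            sub = derive_rng(seed, f"rpkm/{line}/rep{r}")
            vals = base_rpkm * sub.lognormal(0.0, 0.2, size=len(genes))
            rows.append(pd.DataFrame(
                {"gene_id": gene_ids, "cell_line": line, "replicate": f"rep{r}", "rpkm": vals}
            ))
    rpkm_replicates = pd.concat(rows, ignore_index=True)
    return tables, rpkm_replicates, truth


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """One concrete sequence drawn uniformly from each IUPAC class."""
    return "".join(rng.choice(list(IUPAC[sym])) for sym in consensus)


def simulate_promoters(
    genes: Sequence[GeneModel],
    motif: MotifModel,
    motif_genes: Iterable[str],
    planted_per_gene: int = 2,
    window: int = 2_000,
    gc: float = 0.41,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Per-gene promoter-window sequences with planted consensus sites.

    ``window`` is the total window length (a +/- window/2 TSS window).
    Background bases are i.i.d. with the stated GC fraction; each motif
    gene carries exactly ``planted_per_gene`` non-overlapping realized
    consensus insertions at recorded forward-strand positions.
    """
    m = motif.length
    if motif.consensus is None:
        raise ValueError("simulate_promoters plants consensus motifs only")
    if window < m:
        raise ValueError("window must be at least the motif length")
    if planted_per_gene * m > window:
        raise ValueError(
            f"cannot fit {planted_per_gene} sites of length {m} into a {window} b window"
        )
    motif_genes = set(motif_genes)
    truth = SimTruth(seed=seed, motif_genes=motif_genes)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    for g in genes:
        sub = derive_rng(seed, f"promoter/{g.gene_id}")
        seq = sub.choice(_BASES, size=window, p=probs)
        if g.gene_id in motif_genes:
            positions: list[int] = []
            # rejection-sample non-overlapping start positions
            attempts = 0
            while len(positions) < planted_per_gene:
                pos = int(sub.integers(0, window - m + 1))
                if all(abs(pos - q) >= m for q in positions):
                    positions.append(pos)
                attempts += 1
                if attempts > 10_000:
                    # deterministic fallback: evenly spaced slots
                    positions = [i * (window // planted_per_gene) for i in range(planted_per_gene)]
                    break
            for pos in positions:
                site = _realize_consensus(motif.consensus, sub)
                seq[pos : pos + m] = list(site)
            truth.motif_positions[g.gene_id] = sorted(positions)
        sequences[g.gene_id] = "".join(seq)
    return sequences, truth


def simulate_cohort(
    n_samples: int = 300,
    genes: Sequence[GeneModel] | Sequence[str] = (),
    hazard_genes: Optional[Mapping[str, float]] = None,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.05,
    excluded_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Survival cohort: expression matrix + clinical table with planted hazards.

    Expression is log-normal on a positive scale. The hazard for sample i
    is ``baseline_rate * exp(sum_g beta_g z_gi)`` where z is the per-gene
    z-score of log10(x + 1) (so beta is scale-free); survival time is the
    minimum of an exponential event time at that rate and an independent
    Exponential(``censor_rate``) censoring time. ``excluded_fraction`` of
    samples carry a histology label from the exclusion list.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    hazard_genes = dict(hazard_genes or {})
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    unknown = set(hazard_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"hazard genes not in gene list: {sorted(unknown)[:5]}")
    truth = SimTruth(seed=seed, hazard_genes=hazard_genes)
    rng = derive_rng(seed, "cohort")

    gene_mu = rng.normal(np.log(50.0), 1.0, size=len(gene_ids))
    raw = np.exp(gene_mu[:, None] + rng.normal(0.0, 1.0, size=(len(gene_ids), n_samples)))
    expression = pd.DataFrame(
        raw, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"S{i + 1:04d}" for i in range(n_samples)],
    )

    log_expr = np.log10(raw + 1.0)
    log_hr = np.zeros(n_samples)
    for gid, beta in hazard_genes.items():
        row = log_expr[gene_ids.index(gid)]
        sd = row.std()
        z = (row - row.mean()) / sd if sd > 0 else np.zeros_like(row)
        log_hr += beta * z
    rate = baseline_rate * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    time = np.maximum(np.minimum(event_time, censor_time), 1e-6)
    event = (event_time <= censor_time).astype(int)

    n_excluded = round(excluded_fraction * n_samples)
    histology = np.array(["ductal adenocarcinoma"] * n_samples, dtype=object)
    if n_excluded:
        idx = rng.choice(n_samples, size=n_excluded, replace=False)
        histology[idx] = rng.choice(list(DEFAULT_EXCLUDED_HISTOLOGIES), size=n_excluded)
    clinical = pd.DataFrame(
        {
            "sample_id": expression.columns,
            "time": time,
            "event": event,
            "histology": histology,
        }
    )
    return expression, clinical, truth
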