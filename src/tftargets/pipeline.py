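"""End-to-end orchestration: simulate an input bundle, run every stage, report.

``simulate_bundle`` writes all pipeline inputs (BED peak files per
replicate, blacklist, enhancer regions, gene table, per-contrast
differential-transcription TSVs, promoter FASTA, cohort tables) plus the
planted-truth TSVs into one directory. ``run_all`` consumes such a
directory (or any user-supplied files laid out the same way), runs

    differential selection -> peak annotation -> motif enrichment
    -> survival association + permutation tests

and writes per-stage TSV outputs and a JSON report. Every stochastic step
draws a sub-seed from the single global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate, de, io, motif, simulate, survival
from .intervals import GenomicInterval, Peak, remove_blacklisted

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs for the simulator and every analysis stage.

    The simulation defaults are the desk-scale study conditions: 200 genes
    on two chromosomes, two cell lines x two replicates of peaks, two
    shRNA contrasts per line, and a 300-patient cohort.
    """

    seed: int = 0
    # --- simulation ---
    n_chrom: int = 2
    genes_per_chrom: int = 100
    mean_spacing: int = 50_000
    cell_lines: tuple[str, str] = ("NY8", "NY15")
    replicates_per_line: int = 2
    shrnas: tuple[str, str] = ("sh1", "sh2")
    bound_fraction: float = 0.2
    placement_sd: float = 200.0
    dropout: float = 0.1
    background_rate: float = 5.0
    peak_width: int = 300
    activated_fraction: float = 0.15
    repressed_fraction: float = 0.05
    effect_log2fc: float = 1.0
    noise_sd: float = 0.2
    promoter_window: int = 2_000
    planted_per_gene: int = 2
    gc_content: float = 0.41
    n_samples: int = 300
    hazard_beta: float = 0.8
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    excluded_fraction: float = 0.05
    n_blacklist: int = 20
    n_enhancers: int = 60
    enhancer_width: int = 2_000
    #: plant peaks / knockdown effects / hazards in one coincident gene set
    coincident_truth: bool = False
    # --- analysis ---
    motif_consensus: str = motif.HNF1A_HALF_SITE
    n_decoy_motifs: int = 10
    rpkm_min: float = 0.25
    length_min: int = 300
    lfc_min: float = 0.58
    padj_max: float = 0.1
    background_rpkm: float = 0.5
    proximal_bp: int = 5_000
    distal_bp: int = 100_000
    permutations: int = 10_000
    fdr_thresholds: tuple[float, float] = (0.1, 0.25)
    direction: str = "reduced"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


def _bundle_paths(bundle_dir: Path, cfg: PipelineConfig) -> dict:
    peaks = {
        (line, f"rep{r}"): bundle_dir / f"peaks_{line}_rep{r}.bed"
        for line in cfg.cell_lines
        for r in range(1, cfg.replicates_per_line + 1)
    }
    contrasts = {
        (line, sh): bundle_dir / f"de_{line}_{sh}.tsv"
        for line in cfg.cell_lines
        for sh in cfg.shrnas
    }
    return {
        "genes": bundle_dir / "genes.tsv",
        "peaks": peaks,
        "blacklist": bundle_dir / "blacklist.bed",
        "enhancers": bundle_dir / "enhancers.bed",
        "contrasts": contrasts,
        "rpkm_replicates": bundle_dir / "rpkm_replicates.tsv",
        "promoters": bundle_dir / "promoters.fa",
        "expression": bundle_dir / "expression.tsv",
        "clinical": bundle_dir / "clinical.tsv",
        "truth": bundle_dir / "truth.json",
    }


def simulate_bundle(cfg: PipelineConfig, bundle_dir) -> dict:
    """Write a complete synthetic input bundle plus its truth file.

    With ``coincident_truth`` the peak-bound, knockdown-activated and
    hazard-carrying gene sets are one and the same set, giving the full
    chain a recoverable planted signal.
    """
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    paths = _bundle_paths(bundle_dir, cfg)

    genes = simulate.simulate_genome(
        cfg.n_chrom, cfg.genes_per_chrom, cfg.mean_spacing, seed=cfg.seed
    )
    io.write_gene_table(genes, paths["genes"])
    gene_ids = [g.gene_id for g in genes]
    rng = simulate.derive_rng(cfg.seed, "bundle/truthsets")

    peaks, peak_truth = simulate.simulate_peaks(
        genes,
        bound_fraction=cfg.bound_fraction,
        cell_lines=cfg.cell_lines,
        replicates_per_line=cfg.replicates_per_line,
        placement_sd=cfg.placement_sd,
        dropout=cfg.dropout,
        background_rate=cfg.background_rate,
        seed=cfg.seed,
        peak_width=cfg.peak_width,
    )
    if cfg.coincident_truth:
        activated = set(peak_truth.bound_genes)
        remaining = [g for g in gene_ids if g not in activated]
        repressed = set(rng.choice(remaining, size=round(cfg.repressed_fraction * len(gene_ids)),
                                   replace=False))
    else:
        n_act = round(cfg.activated_fraction * len(gene_ids))
        n_rep = round(cfg.repressed_fraction * len(gene_ids))
        chosen = rng.choice(gene_ids, size=n_act + n_rep, replace=False)
        activated, repressed = set(chosen[:n_act]), set(chosen[n_act:])
    for key, path in paths["peaks"].items():
        io.write_bed(peaks[key], path)

    tables, rpkm_replicates, _ = simulate.simulate_de_tables(
        genes, activated, repressed,
        effect_log2fc=cfg.effect_log2fc, noise_sd=cfg.noise_sd,
        cell_lines=cfg.cell_lines, shrnas=cfg.shrnas, seed=cfg.seed,
        replicates_per_line=cfg.replicates_per_line,
    )
    for key, path in paths["contrasts"].items():
        tables[key].to_csv(path, sep="\t", index=False)
    rpkm_replicates.to_csv(paths["rpkm_replicates"], sep="\t", index=False)

    # blacklist and enhancer regions: random tiles; enhancers biased toward
    # bound-gene TSS flanks so enhancer overlap is informative
    chrom_len = simulate.chromosome_lengths(genes)
    bl_rng = simulate.derive_rng(cfg.seed, "bundle/blacklist")
    blacklist = []
    chroms = sorted(chrom_len)
    for _ in range(cfg.n_blacklist):
        chrom = chroms[int(bl_rng.integers(len(chroms)))]
        start = int(bl_rng.integers(0, max(1, chrom_len[chrom] - 1000)))
        blacklist.append(GenomicInterval(chrom, start, start + 1000))
    io.write_bed(blacklist, paths["blacklist"])

    en_rng = simulate.derive_rng(cfg.seed, "bundle/enhancers")
    tss_by_gene = {g.gene_id: (g.chrom, g.tss) for g in genes}
    enhancers = []
    bound_list = sorted(peak_truth.bound_genes)
    for i in range(cfg.n_enhancers):
        if bound_list and i < cfg.n_enhancers // 2:
            chrom, tss = tss_by_gene[bound_list[int(en_rng.integers(len(bound_list)))]]
            center = int(tss + en_rng.integers(-5_000, 5_000))
        else:
            chrom = chroms[int(en_rng.integers(len(chroms)))]
            center = int(en_rng.integers(0, chrom_len[chrom]))
        start = max(0, center - cfg.enhancer_width // 2)
        enhancers.append(GenomicInterval(chrom, start, start + cfg.enhancer_width))
    io.write_bed(enhancers, paths["enhancers"])

    motif_model = motif.MotifModel(name="planted", consensus=cfg.motif_consensus,
                                   window_bp=cfg.promoter_window // 2)
    promoters, motif_truth = simulate.simulate_promoters(
        genes, motif_model, motif_genes=activated,
        planted_per_gene=cfg.planted_per_gene, window=cfg.promoter_window,
        gc=cfg.gc_content, seed=cfg.seed,
    )
    io.write_fasta(promoters, paths["promoters"])

    hazard_genes = (
        {g: cfg.hazard_beta for g in sorted(activated)} if cfg.coincident_truth else
        {g: cfg.hazard_beta for g in sorted(rng.choice(sorted(activated),
         size=max(1, len(activated) // 3), replace=False))}
    )
    expression, clinical, _ = simulate.simulate_cohort(
        n_samples=cfg.n_samples, genes=genes, hazard_genes=hazard_genes,
        baseline_rate=cfg.baseline_rate, censor_rate=cfg.censor_rate,
        excluded_fraction=cfg.excluded_fraction, seed=cfg.seed,
    )
    expression.to_csv(paths["expression"], sep="\t")
    clinical.to_csv(paths["clinical"], sep="\t", index=False)

    truth = {
        "seed": cfg.seed,
        "bound_genes": sorted(peak_truth.bound_genes),
        "activated_genes": sorted(activated),
        "repressed_genes": sorted(repressed),
        "hazard_genes": hazard_genes,
        "motif_genes": sorted(motif_truth.motif_genes),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    (bundle_dir / "config.json").write_text(cfg.to_json())
    return paths


def run_all(cfg: PipelineConfig, bundle_dir, out_dir) -> dict:
    """Run every stage on a bundle directory; write outputs and return the report."""
    bundle_dir, out_dir = Path(bundle_dir), Path(out_dir)
    paths = _bundle_paths(bundle_dir, cfg)
    report: dict = {"seed": cfg.seed}
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(cfg.to_json())

    # --- stage 1: differential-transcription selection ---
    stage = out_dir / "de"
    stage.mkdir(exist_ok=True)
    genes = io.read_gene_table(paths["genes"])
    cfg_de = de.DESelectionConfig(cfg.rpkm_min, cfg.length_min, cfg.lfc_min, cfg.padj_max)
    tables = {key: pd.read_csv(path, sep="\t", dtype={"gene_id": str})
              for key, path in paths["contrasts"].items()}
    calls = {key: de.select_de_contrast(tbl, cfg_de) for key, tbl in tables.items()}
    sets_ = de.intersect_directional(calls)
    mean_rpkm = pd.concat(tables.values()).groupby("gene_id")["mean_rpkm"].mean()
    expressed = de.expressed_for_peaks(mean_rpkm, cfg.rpkm_min)
    rpkm_replicates = pd.read_csv(paths["rpkm_replicates"], sep="\t", dtype={"gene_id": str})
    background = de.expressed_background(rpkm_replicates, cfg.background_rpkm)
    logger.info("DE stage: %d upregulated, %d downregulated, %d conflicted; "
                "%d expressed (peaks), %d background",
                len(sets_.upregulated), len(sets_.downregulated), len(sets_.conflicted),
                len(expressed), len(background))
    pd.DataFrame({"gene_id": sorted(sets_.upregulated)}).to_csv(
        stage / "upregulated.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(sets_.downregulated)}).to_csv(
        stage / "downregulated.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(background)}).to_csv(
        stage / "background.tsv", sep="\t", index=False)
    report["de"] = {
        "upregulated": len(sets_.upregulated),
        "downregulated": len(sets_.downregulated),
        "conflicted": len(sets_.conflicted),
        "expressed_for_peaks": len(expressed),
        "background": len(background),
    }

    # --- stage 2: peak annotation ---
    stage = out_dir / "peaks"
    stage.mkdir(exist_ok=True)
    blacklist = [iv if isinstance(iv, GenomicInterval) else iv.interval
                 for iv in io.read_bed(paths["blacklist"])]
    peaks_by_rep = {}
    for (line, rep), path in paths["peaks"].items():
        raw = [p for p in io.read_bed(path, cell_line=line, replicate=rep)
               if isinstance(p, Peak)]
        kept = remove_blacklisted(raw, blacklist)
        logger.info("peaks %s/%s: %d called, %d after blacklist", line, rep, len(raw), len(kept))
        peaks_by_rep[(line, rep)] = kept
    expressed_genes = [g for g in genes if g.gene_id in expressed]
    ann_cfg = annotate.PeakAnnotationConfig(cfg.proximal_bp, cfg.distal_bp)
    binding = annotate.classify_genes(peaks_by_rep, expressed_genes, ann_cfg)
    enhancers = [iv if isinstance(iv, GenomicInterval) else iv.interval
                 for iv in io.read_bed(paths["enhancers"])]
    _, enhancer_fraction = annotate.enhancer_overlap_report(binding, enhancers)
    frame = annotate.calls_to_frame(binding)
    frame.to_csv(stage / "gene_binding.tsv", sep="\t", index=False)
    bound = set(frame.loc[frame["consensus_class"].isin(["proximal", "distal"]), "gene_id"])

    def _class_fractions(gene_set: set[str]) -> dict:
        sub = frame[frame["gene_id"].isin(gene_set)]
        n = len(sub)
        counts = sub["consensus_class"].value_counts().to_dict()
        return {
            "n": n,
            "proximal": counts.get("proximal", 0) / n if n else None,
            "distal": counts.get("distal", 0) / n if n else None,
            "neither": counts.get("neither", 0) / n if n else None,
            "bound": (counts.get("proximal", 0) + counts.get("distal", 0)) / n if n else None,
        }

    report["binding"] = {
        "bound_genes": len(bound),
        "enhancer_fraction": enhancer_fraction,
        "upregulated": _class_fractions(sets_.upregulated),
        "downregulated": _class_fractions(sets_.downregulated),
    }

    # --- stage 3: motif enrichment ---
    stage = out_dir / "motifs"
    stage.mkdir(exist_ok=True)
    promoters = io.read_fasta(paths["promoters"])
    windows = motif.extract_windows(genes, promoters, cfg.promoter_window // 2)
    motifs = [motif.MotifModel(name="planted", consensus=cfg.motif_consensus)]
    decoy_rng = simulate.derive_rng(cfg.seed, "analysis/decoys")
    m_len = len(cfg.motif_consensus)
    for i in range(cfg.n_decoy_motifs):
        decoy = "".join(decoy_rng.choice(list("ACGT"), size=m_len))
        motifs.append(motif.MotifModel(name=f"decoy{i + 1}", consensus=decoy))
    motif_report = {}
    for set_name, fg in (("upregulated", sets_.upregulated),
                         ("downregulated", sets_.downregulated)):
        results = [motif.motif_enrichment(fg, background, windows, mm) for mm in motifs]
        ranked = motif.rank_motifs(results)
        pd.DataFrame(
            [(r.name, r.x_t, r.L_t, r.x_b, r.L_b, r.zscore, r.binom_p, r.gene_hits)
             for r in ranked],
            columns=["motif", "fg_hits", "fg_positions", "bg_hits", "bg_positions",
                     "zscore", "binom_p", "gene_hits"],
        ).to_csv(stage / f"enrichment_{set_name}.tsv", sep="\t", index=False)
        motif_report[set_name] = {
            "top_motif": ranked[0].name if ranked else None,
            "top_zscore": ranked[0].zscore if ranked else None,
        }
    report["motifs"] = motif_report

    # --- stage 4: survival association + permutation tests ---
    stage = out_dir / "survival"
    stage.mkdir(exist_ok=True)
    expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    expression.index = expression.index.astype(str)
    clinical = pd.read_csv(paths["clinical"], sep="\t", dtype={"sample_id": str})
    model = survival.GeneSetSurvivalModel(expression, clinical)
    cohort_bg = sorted(background & set(model.genes))
    gene_sets = {
        "upregulated": sorted(sets_.upregulated & set(model.genes)),
        "upregulated_bound": sorted((sets_.upregulated & bound) & set(model.genes)),
        "downregulated": sorted(sets_.downregulated & set(model.genes)),
    }
    surv_report = {}
    perm_seed_rng = simulate.derive_rng(cfg.seed, "analysis/permutations")
    for set_name, gene_list in gene_sets.items():
        entry: dict = {"n_genes": len(gene_list)}
        if len(gene_list) >= 2 and len(cohort_bg) > len(gene_list):
            results = model.fit(gene_list)
            results.table.to_csv(stage / f"cox_{set_name}.tsv", sep="\t")
            for thr in cfg.fdr_thresholds:
                count, frac = results.count_significant(thr, cfg.direction)
                perm = results.permutation_test(
                    cohort_bg, N=cfg.permutations, threshold=thr,
                    direction=cfg.direction,
                    seed=int(perm_seed_rng.integers(2**31)),
                )
                entry[f"fdr_{thr}"] = {
                    "significant": count,
                    "fraction": frac,
                    "permutation_p": perm.empirical_p,
                    "permutations": perm.N,
                }
        else:
            entry["skipped"] = "set too small or background too small"
        surv_report[set_name] = entry
    report["survival"] = surv_report

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
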