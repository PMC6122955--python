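# Methods

This note documents the models and procedures implemented in `tftargets`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter when results
are compared across implementations.

## Differential-transcription selection

Per-contrast statistics (log2 fold change, p, adjusted p, mean RPKM, gene
length) are consumed, not estimated; count-level differential testing is
out of scope. The selection rule per contrast is

    mean_rpkm > 0.25  AND  gene_length >= 300  AND  |log2fc| > 0.58
    AND  padj < 0.1

with every comparison strict exactly as the thresholds are printed:
boundary values (RPKM = 0.25, padj = 0.1, |log2FC| = 0.58) fail, while
gene length 300 passes (a *minimum* length). A missing adjusted p fails
the gene and is logged, never raised — partial DESeq tables are common.

FDR adjustment is Benjamini–Hochberg (the field default where the method
is unstated), delegated to `statsmodels.stats.multitest.multipletests`.

Cross-cell-line intersection: a gene is factor-*upregulated* (down after
knockdown) iff it passes with negative log2FC in at least one shRNA of
every cell line; mirror image for downregulated. A gene qualifying in
opposite directions in different cell lines is placed in a separate
`conflicted` set and belongs to neither — the directional sets are
reported as disjoint, and silent assignment to either side would bias
downstream enrichment. A variant rule (adjusted p required in only one
named cell line) exists in the literature for this design; the explicit
both-lines rule is the default here because it is the only one stated as
a complete list of criteria.

Expressed backgrounds: for peak assignment, mean RPKM > 0.25; for the
survival background, RPKM > 0.5 in at least one replicate of every cell
line. Both strict.

## Peak-to-gene classification

Coordinates are 0-based half-open (BED) everywhere; overlap means at
least one shared base, so abutting intervals do not overlap (but are
merged by `merge_intervals`). A minus-strand gene's TSS is `end − 1`.
Chromosome names match by exact string equality — no "chr" normalization,
so mixed sources fail loudly rather than silently mismatching.

The distance reference point of a peak is its summit when called (e.g.
narrowPeak column 10), else the interval midpoint. Assignment is
nearest-TSS among *expressed* genes on the same chromosome, ties broken
toward the lexicographically smaller gene id for determinism. The
classification is reciprocal: a gene's candidate peaks are exactly those
assigned to it, so a peak sitting nearer a neighbouring gene can never
classify this one — this is what disambiguates genes with nearby TSSs.

Per replicate, the nearest candidate peak at distance d gives class
proximal (d ≤ 5,000), distal (d ≤ 100,000) or none, boundaries
inclusive ("within ±5 kb"). Consensus across 2 cell lines × replicates:

1. proximal if ≥ 1 replicate in *every* cell line is proximal;
2. else distal if *every* replicate in every cell line is distal;
3. else neither (mixed classes, or no peak anywhere).

The proximal rule is evaluated first; the alternative precedence would
push many promoter-bound genes into "neither" whenever a single replicate
also produced a distal call. `common_peaks` (cross-line reproducible
peaks: overlap with ≥ 1 peak of ≥ 1 replicate of the other line) is
exposed separately for workflows that classify from a reproducible peak
set instead of per-replicate consensus.

Enhancer overlap: regions are merged first (merging never changes overlap
semantics); a bound gene is flagged iff any of its assigned peaks (any
replicate) shares a base with a merged region, and the reported fraction
is flagged / bound. Zero bound genes yields a missing fraction.

## Motif scanning and over-representation

IUPAC consensus scanning matches a window iff every base is in the
symbol's class; an `N` in the *sequence* matches nothing, including motif
`N` — conservative handling of masked bases. Matrix mode scores
`(S − S_min)/(S_max − S_min) ≥ 0.85` by default. Reverse-strand hits are
found on the reverse complement and reported in forward coordinates;
overlapping hits are all reported.

Enrichment uses a binomial per-nucleotide model: with background rate
p_bg = x_b/L_b over scanned positions (both strands), the foreground
z-score is (x_t − L_t·p_bg)/√(L_t·p_bg(1−p_bg)), no continuity
correction, plus an exact two-sided binomial p. A degenerate background
(p_bg ∈ {0,1}) yields a flagged missing z, ranked last. Ranking is by z
descending, ties by number of hit-carrying foreground genes, then name.
The published web tools in this space additionally filter hits by
cross-species conservation; that filter requires external alignment
tracks and is deliberately not implemented — reported z-scores are
therefore comparable in design but not numerically to conservation-
filtered ones.

Scale note: the stringent 14-mer HNF1A consensus (`DGTTAATNATTAAC`,
~4.5 × 10⁻⁸ match probability per position) yields essentially zero
background hits over a few hundred desk-scale promoter windows, making
the binomial z degenerate. Synthetic enrichment studies and the pipeline
default therefore scan the 7-base half-site `GTTAATG` (~10⁻⁴ per position
in 41%-GC sequence), while planted sites realize the full consensus —
which contains the half-site on both strands. Both strings are exported
(`HNF1A_CONSENSUS`, `HNF1A_HALF_SITE`).

## Survival association

Expression covariates are log10(x + 1); samples whose histology matches
the neuroendocrine exclusion list (case-insensitive, whitespace-
normalized) are dropped before fitting. Each gene gets a univariate Cox
proportional-hazards fit: scalar Newton iterations on the partial
likelihood to |Δβ| < 1e-8 (max 50), Efron handling of tied event times
(Breslow by flag), standard error from the observed information, Wald p
from χ²₁. When no event times tie, the Efron and Breslow likelihoods
coincide and a fully vectorized score/information path is used; it agrees
with the grouped path and with lifelines to ~1e-8. A constant covariate
raises; a monotone likelihood (perfect separation) returns a
non-converged flag with |β| capped at 20.

Within a gene set, Wald p-values are BH-adjusted *within the set* —
consistent with reporting "k/m significant at FDR < t" for a set of m
genes. Direction: hazard ratio > 1 is "reduced survival"; the signed
significance score is −log10(q), positive for reduced. Both conventions
are recorded in the results table rather than hard-coded into plots.

Permutation test: the observed statistic is the fraction of set genes
with within-set q < threshold in the tested direction (default
"reduced"; thresholds 0.1 and 0.25). Each of N null draws is a uniform
same-size subset of the background, scored *identically* — the FDR is
recomputed within each drawn set, the only symmetric and therefore
unbiased treatment. The empirical p is the add-one estimator
(1 + #{null ≥ observed})/(N + 1), which cannot return zero. Per-gene
fits are cached on the model, so each background gene is fitted exactly
once regardless of N; caching provably cannot change results because the
fit is deterministic per gene. The production default N = 10,000 makes
the relative SE of a p estimated at α = 0.05 equal √(0.95/500) ≈ 4.4%,
below the 10% design bound; `permutation_relative_se` computes this for
any (p, N).

Calibration of the empirical p is inherently conservative when the
tested set is a large fraction of the background: null draws then share
"hot" genes with the observed set and tie with it, and ties count
against significance. Validation studies here use set/background ratios
of ~1/15, where measured coverage (≈ 3.5% of null runs below p = 0.05)
matches the infinite-background ideal (≈ 3.6%).

## Synthetic-data generators

All generators are deterministic per seed; per-replicate and per-contrast
sub-streams are derived by mixing a CRC32 of a text label into the
SeedSequence, so adding a replicate never perturbs the others.

* **Genome**: exponential TSS spacing (default mean 50 kb), random
  strands, log-normal gene lengths (median 20 kb, log-sd 2) so a small
  tail falls below the 300 b filter.
* **Peaks**: each bound gene (default 20% of genes) gets a 300 b peak per
  replicate centred at TSS + N(0, 200 b) with 10% dropout; background
  peaks are uniform at 5/Mb.
* **Knockdown tables**: observed log2FC = true ± N(0, 0.2) with planted
  effect 1.0; p-values are the two-sided normal tail of log2fc/0.2, so
  null p-values are exactly Uniform(0,1); mean RPKM is log-normal(log 2,
  1.5), putting ~8% of genes under the 0.25 filter.
* **Promoters**: i.i.d. bases at 41% GC with exact consensus realizations
  planted non-overlapping at recorded positions.
* **Cohort**: log-normal expression; hazard λ·exp(Σ β·z) with z the
  z-score of log10(x + 1) (β is therefore scale-free); independent
  exponential censoring; a labelled excluded-histology subgroup (5%).

Defaults (200 genes, 2 × 2 peak replicates, 2 × 2 contrasts, 300
patients) keep the full pipeline under a few seconds. What the
generators do **not** emulate: correlated gene expression, read-level
noise, peak-width/signal heterogeneity, non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate correctness
of the selection logic, the estimators and their calibration under the
stated models — not robustness to those real-data violations.

## Validation design

Every operation is tested against an independent oracle sharing no code
with the implementation: interval arithmetic against explicit base sets,
BH against a literal step-up evaluation, peak annotation against an
O(n·m) nested-loop reimplementation over random instances, the Cox
Newton fit against grid-search maximization of the directly-evaluated
partial likelihood and against lifelines, the IUPAC scanner against a
position-by-position matcher, and the sampled permutation test against
exhaustive subset enumeration on a 6-gene background. Estimator studies
use planted-truth simulations: β recovery at n = 1000, null Wald-p
uniformity, permutation calibration and power, planted-motif recovery
against decoys, and end-to-end recovery when the bound, activated and
hazard-carrying sets coincide.

## Known limitations

* One covariate per Cox model; no multivariate or stratified models and
  no proportional-hazards diagnostics.
* The motif stage has no conservation filter and no position-specific
  background model (i.i.d. base composition only).
* `common_peaks` and the per-replicate consensus are alternative
  definitions of reproducible binding; the pipeline reports the
  consensus route.
* The empirical permutation p is conservative for large set/background
  ratios (see above); interpret p near a threshold accordingly.
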