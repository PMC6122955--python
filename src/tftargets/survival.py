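"""Per-gene Cox survival association and the gene-set permutation test.

The modelling surface follows the statsmodels convention: build a
:class:`GeneSetSurvivalModel` from an expression matrix (genes x samples)
and a clinical table; :meth:`~GeneSetSurvivalModel.fit` returns a
:class:`GeneSetSurvivalResults` carrying per-gene estimates, within-set FDR
q-values, directions and signed significance scores, with ``summary()``,
``count_significant()`` and ``permutation_test()`` hanging off the results.

Model. For each gene the covariate is z = log10(expression + 1) and a
univariate Cox proportional-hazards model lambda(t | z) = lambda_0(t)
exp(beta z) is fitted by maximising the partial likelihood (Newton
iterations, Efron handling of tied event times). A hazard ratio
exp(beta) > 1 marks association with *reduced* survival. Within a gene
set, Wald p-values are Benjamini-Hochberg adjusted and each gene receives

    signed_score = -log10(q) * (+1 if reduced survival else -1).

The permutation test draws N random same-size gene sets from a background
set, recomputes the FDR *within each drawn set*, and compares the observed
fraction of significant same-direction genes against that null, with the
add-one empirical p estimator (1 + #{null >= observed}) / (N + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)

#: Histology labels excluded from the cohort (neuroendocrine-origin tumors).
DEFAULT_EXCLUDED_HISTOLOGIES = (
    "82463 neuroendocrine carcinoma nos",
    "moderately differentiated ductal adenocarcinoma 60% + neuroendocrine 40%",
    "neuroendocrine",
    "neuroendocrine carcinoma",
    "neuroendocrine carcinoma nos",
)

_BETA_CAP = 20.0


class DegenerateCovariateError(ValueError):
    """Raised when the covariate is constant across samples."""


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    wald_p: float
    converged: bool


@dataclass
class PermutationTestResult:
    observed_fraction: float
    null_fractions: np.ndarray
    empirical_p: float
    N: int
    threshold: float
    direction: str
    relative_se: float
    seed: Optional[int] = None


def preprocess_expression(raw):
    """log10(x + 1) transform of nonnegative abundances (0 maps to 0)."""
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression values must be nonnegative")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(raw) else out


def _normalize_label(label: str) -> str:
    return " ".join(str(label).lower().split())


def filter_cohort(
    clinical: pd.DataFrame,
    exclusion_labels: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Drop samples whose histology matches an exclusion label.

    Matching is case-insensitive and whitespace-normalized. The default
    exclusion list removes neuroendocrine-origin tumors.
    """
    if exclusion_labels is None:
        exclusion_labels = DEFAULT_EXCLUDED_HISTOLOGIES
    excluded = {_normalize_label(lbl) for lbl in exclusion_labels}
    if "histology" not in clinical.columns or not excluded:
        return clinical.copy()
    keep = ~clinical["histology"].fillna("").map(_normalize_label).isin(excluded)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_cohort: excluded %d samples by histology", dropped)
    return clinical.loc[keep].copy()


def fit_cox_univariate(
    times: Sequence[float],
    events: Sequence[int],
    covariate: Sequence[float],
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Univariate Cox PH fit by scalar Newton iteration.

    Efron's approximation (default) or Breslow's for tied event times;
    standard error from the observed information; two-sided Wald p from
    chi-square(1). A monotone partial likelihood (perfectly separating
    covariate) is reported as a non-converged fit with |beta| capped.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if not (t.shape == d.shape == x.shape):
        raise ValueError("times, events and covariate must have equal length")
    if d.sum() < 2:
        raise ValueError("need at least two observed events")
    if np.ptp(x) == 0:
        raise DegenerateCovariateError("covariate is constant across samples")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")

    # sort by ascending time; risk set at an event time = all with time >= t
    order = np.argsort(t, kind="stable")
    t, d, x = t[order], d[order], x[order]
    n = t.size
    # group boundaries of unique times (ascending)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], n]

    # with no tied event times the Efron and Breslow likelihoods coincide and
    # the score/information reduce to fully vectorized suffix-sum expressions
    dead_any = np.flatnonzero(d == 1)
    has_ties = any(d[a:b].sum() > 1 for a, b in zip(starts, ends))

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        w = np.exp(np.clip(beta * x, -700, 700))
        wx = w * x
        wx2 = wx * x
        # suffix sums: risk-set aggregates for time >= t_k
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum(wx[::-1])[::-1]
        s2 = np.cumsum(wx2[::-1])[::-1]
        if not has_ties:
            first = starts[np.searchsorted(starts, dead_any, side="right") - 1]
            r0, r1, r2 = s0[first], s1[first], s2[first]
            U = float(np.sum(x[dead_any] - r1 / r0))
            I = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
            step_ready = True
        else:
            step_ready = False
        if step_ready:
            if I <= 0:
                break
            step = U / I
            beta_new = beta + step
            if abs(beta_new) > _BETA_CAP:
                beta = math.copysign(_BETA_CAP, beta_new)
                break
            beta = beta_new
            if abs(step) < tol:
                converged = True
                break
            continue
        U = 0.0
        I = 0.0
        for a, b in zip(starts, ends):
            dk = int(d[a:b].sum())
            if dk == 0:
                continue
            dead = a + np.flatnonzero(d[a:b] == 1)
            U += float(x[dead].sum())
            r0, r1, r2 = float(s0[a]), float(s1[a]), float(s2[a])
            if ties == "breslow" or dk == 1:
                for _j in range(dk):
                    U -= r1 / r0
                    I += r2 / r0 - (r1 / r0) ** 2
            else:
                e0 = float(w[dead].sum())
                e1 = float(wx[dead].sum())
                e2 = float(wx2[dead].sum())
                for j in range(dk):
                    f = j / dk
                    q0 = r0 - f * e0
                    q1 = r1 - f * e1
                    q2 = r2 - f * e2
                    U -= q1 / q0
                    I += q2 / q0 - (q1 / q0) ** 2
        if I <= 0:
            break
        step = U / I
        beta_new = beta + step
        if abs(beta_new) > _BETA_CAP:
            beta = math.copysign(_BETA_CAP, beta_new)
            break
        beta = beta_new
        if abs(step) < tol:
            converged = True
            break

    if not converged:
        logger.info("fit_cox_univariate: no convergence (monotone likelihood?); "
                    "beta capped at %.3g", beta)
    se = 1.0 / math.sqrt(I) if I > 0 else float("inf")
    wald = (beta / se) ** 2 if math.isfinite(se) and se > 0 else 0.0
    wald_p = float(stats.chi2.sf(wald, df=1))
    wald_p = max(wald_p, np.finfo(float).tiny)  # keep p in (0, 1]
    return CoxFit(beta=beta, se=se, hr=math.exp(beta), wald_p=wald_p, converged=converged)


def permutation_relative_se(p: float, N: int) -> float:
    """Coefficient of variation of an N-draw empirical p estimate at level p."""
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.sqrt((1.0 - p) / (N * p))


class GeneSetSurvivalModel:
    """Per-gene univariate Cox PH models over a survival cohort.

    Parameters
    ----------
    expression : DataFrame, genes x samples, nonnegative abundances.
    clinical : DataFrame with columns sample_id, time, event and optionally
        histology (used for cohort exclusion before fitting).
    exclusion_labels : histology strings to drop (default: neuroendocrine
        labels); pass an empty list to keep every sample.
    ties : 'efron' (default) or 'breslow'.

    Per-gene fits are cached, so permutation testing fits each background
    gene exactly once.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        clinical: pd.DataFrame,
        exclusion_labels: Optional[Iterable[str]] = None,
        ties: str = "efron",
    ):
        clinical = filter_cohort(clinical, exclusion_labels)
        clinical = clinical.set_index(clinical["sample_id"].astype(str))
        samples = [s for s in map(str, expression.columns) if s in clinical.index]
        if len(samples) < 2:
            raise ValueError("fewer than two samples shared by expression and clinical tables")
        self.expression = expression.copy()
        self.expression.columns = expression.columns.astype(str)
        self.expression = self.expression[samples]
        self.clinical = clinical.loc[samples]
        self.times = self.clinical["time"].to_numpy(dtype=float)
        self.events = self.clinical["event"].to_numpy(dtype=int)
        if np.any(self.times <= 0):
            raise ValueError("follow-up times must be positive")
        self.ties = ties
        self._cache: dict[str, Optional[CoxFit]] = {}

    @classmethod
    def from_files(cls, expression_path, clinical_path, **kwargs) -> "GeneSetSurvivalModel":
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        clin = pd.read_csv(clinical_path, sep="\t", dtype={"sample_id": str})
        return cls(expr, clin, **kwargs)

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.expression.index]

    def fit_gene(self, gene: str) -> Optional[CoxFit]:
        """Cached univariate fit for one gene; None when the fit fails."""
        if gene not in self._cache:
            try:
                cov = preprocess_expression(self.expression.loc[gene].to_numpy(dtype=float))
                self._cache[gene] = fit_cox_univariate(
                    self.times, self.events, cov, ties=self.ties
                )
            except (DegenerateCovariateError, ValueError) as exc:
                logger.warning("fit failed for gene %s: %s", gene, exc)
                self._cache[gene] = None
        return self._cache[gene]

    def fit(self, genes: Optional[Iterable[str]] = None) -> "GeneSetSurvivalResults":
        """Fit every gene in the set; FDR is adjusted *within* the set."""
        gene_list = list(genes) if genes is not None else self.genes
        missing = [g for g in gene_list if g not in self.expression.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}...")
        rows = []
        failures = []
        for g in gene_list:
            res = self.fit_gene(g)
            if res is None:
                failures.append(g)
            else:
                rows.append((g, res.beta, res.se, res.hr, res.wald_p, res.converged))
        table = pd.DataFrame(
            rows, columns=["gene_id", "beta", "se", "hr", "wald_p", "converged"]
        ).set_index("gene_id")
        if len(table):
            table["fdr_q"] = bh_adjust(table["wald_p"].to_numpy())
            table["direction"] = np.where(table["hr"] > 1.0, "reduced", "increased")
            sign = np.where(table["direction"] == "reduced", 1.0, -1.0)
            table["signed_score"] = -np.log10(table["fdr_q"]) * sign
            # deterministic ranking: gene_id breaks signed-score ties
            table = table.sort_index().sort_values("signed_score", ascending=False,
                                                   kind="stable")
        return GeneSetSurvivalResults(self, table, failures)


class GeneSetSurvivalResults:
    """Per-gene survival associations for one gene set, ranked by signed score."""

    def __init__(self, model: GeneSetSurvivalModel, table: pd.DataFrame, failures: list[str]):
        self.model = model
        self.table = table
        self.failures = failures

    def __len__(self) -> int:
        return len(self.table)

    def count_significant(self, threshold: float, direction: str = "reduced"):
        """(count, fraction) of genes with fdr_q < threshold in the given direction."""
        if len(self.table) == 0:
            return 0, None
        mask = (self.table["fdr_q"] < threshold) & (self.table["direction"] == direction)
        count = int(mask.sum())
        return count, count / len(self.table)

    def summary(self) -> str:
        lines = [
            "Gene-set survival association (univariate Cox PH, "
            f"{self.model.ties} ties, n={len(self.model.times)} samples, "
            f"{int(self.model.events.sum())} events)",
            f"genes fitted: {len(self.table)}   fit failures: {len(self.failures)}",
            "",
            self.table[["beta", "se", "hr", "wald_p", "fdr_q", "direction", "signed_score"]]
            .to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        for thr in (0.1, 0.25):
            count, frac = self.count_significant(thr)
            if frac is not None:
                lines.append(
                    f"reduced survival at FDR<{thr}: {count}/{len(self.table)} ({100 * frac:.1f}%)"
                )
        return "\n".join(lines)

    def permutation_test(
        self,
        background: Iterable[str],
        N: int = 10_000,
        threshold: float = 0.1,
        direction: str = "reduced",
        seed: Optional[int] = None,
    ) -> PermutationTestResult:
        """Gene-set permutation test against a background set.

        Null statistic: fraction of a random same-size background subset
        significant (within-subset BH FDR < ``threshold``) in ``direction``.
        """
        if N < 100:
            logger.warning("permutation_test: N=%d is small; empirical p is unstable", N)
        set_genes = list(self.table.index)
        bg = [str(g) for g in background]
        if len(bg) <= len(set_genes):
            raise ValueError("background must be larger than the tested set")
        not_in_bg = set(set_genes) - set(bg)
        if not_in_bg:
            logger.warning("permutation_test: %d set genes not in background", len(not_in_bg))

        # fit each background gene once (cached); drop failures from the pool
        fits = [(g, self.model.fit_gene(g)) for g in bg]
        failed = [g for g, f in fits if f is None]
        if failed:
            logger.warning("permutation_test: %d background genes failed to fit", len(failed))
        pool = [(g, f) for g, f in fits if f is not None]
        p_bg = np.array([f.wald_p for _, f in pool])
        dir_bg = np.array([f.hr > 1.0 for _, f in pool]) if direction == "reduced" else \
            np.array([f.hr <= 1.0 for _, f in pool])
        m = len(set_genes)
        if len(pool) <= m:
            raise ValueError("background too small after removing failed fits")

        _, observed = self.count_significant(threshold, direction)
        rng = np.random.default_rng(seed)
        # N same-size subsets without replacement, drawn as random-key argpartition
        keys = rng.random((N, len(pool)))
        idx = np.argpartition(keys, m, axis=1)[:, :m]
        null_fractions = _fraction_significant(p_bg[idx], dir_bg[idx], threshold)
        empirical_p = (1.0 + np.count_nonzero(null_fractions >= observed - 1e-12)) / (N + 1.0)
        return PermutationTestResult(
            observed_fraction=observed,
            null_fractions=null_fractions,
            empirical_p=float(empirical_p),
            N=N,
            threshold=threshold,
            direction=direction,
            relative_se=permutation_relative_se(0.05, N),
            seed=seed,
        )


def _fraction_significant(p_mat: np.ndarray, dir_mat: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise fraction of genes BH-significant (within row) in the tested direction."""
    N, m = p_mat.shape
    order = np.argsort(p_mat, axis=1)
    p_sorted = np.take_along_axis(p_mat, order, axis=1)
    dir_sorted = np.take_along_axis(dir_mat, order, axis=1)
    ranks = np.arange(1, m + 1)
    q = p_sorted * m / ranks
    q = np.minimum.accumulate(q[:, ::-1], axis=1)[:, ::-1]
    q = np.minimum(q, 1.0)
    hits = (q < threshold) & dir_sorted
    return hits.sum(axis=1) / m


def gene_set_survival(
    genes: Iterable[str],
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    **model_kwargs,
) -> GeneSetSurvivalResults:
    """One-call wrapper: build the model and fit the given gene set."""
    model = GeneSetSurvivalModel(expression, clinical, **model_kwargs)
    return model.fit(list(genes))


def permutation_test(
    set_genes: Iterable[str],
    background: Iterable[str],
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    N: int = 10_000,
    threshold: float = 0.1,
    direction: str = "reduced",
    seed: Optional[int] = None,
    **model_kwargs,
) -> PermutationTestResult:
    """One-call wrapper over :meth:`GeneSetSurvivalResults.permutation_test`."""
    model = GeneSetSurvivalModel(expression, clinical, **model_kwargs)
    results = model.fit(list(set_genes))
    return results.permutation_test(background, N=N, threshold=threshold,
                                    direction=direction, seed=seed)
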