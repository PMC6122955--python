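"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes results by enumeration or direct formula
application, deliberately sharing no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# --- interval arithmetic -------------------------------------------------

def interval_base_set(intervals) -> set[tuple[str, int]]:
    """Explicit set of (chrom, base) positions covered by the intervals."""
    bases = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases


def overlaps_pairwise(a, b) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


# --- BH step-up ----------------------------------------------------------

def bh_stepup(pvalues) -> np.ndarray:
    """Literal step-up formula: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


# --- peak annotation -----------------------------------------------------

def annotate_bruteforce(peaks_by_rep, genes, proximal_bp, distal_bp):
    """Nested-loop reimplementation of assignment + classification + consensus.

    peaks_by_rep: {(line, rep): [(chrom, refpoint), ...]}
    genes: [(gene_id, chrom, tss), ...]
    Returns {gene_id: (consensus_class, {(line, rep): class})}.
    """
    per_rep = {}
    for key, peaks in peaks_by_rep.items():
        # peak -> closest gene (tie: min gene_id), by exhaustive scan
        assigned = {}  # gene_id -> list of distances
        for chrom, ref in peaks:
            best = None
            for gene_id, gchrom, tss in genes:
                if gchrom != chrom:
                    continue
                d = abs(tss - ref)
                if best is None or d < best[0] or (d == best[0] and gene_id < best[1]):
                    best = (d, gene_id)
            if best is not None:
                assigned.setdefault(best[1], []).append(best[0])
        classes = {}
        for gene_id, _, _ in genes:
            if gene_id not in assigned:
                classes[gene_id] = "none"
            else:
                d = min(assigned[gene_id])
                if d <= proximal_bp:
                    classes[gene_id] = "proximal"
                elif d <= distal_bp:
                    classes[gene_id] = "distal"
                else:
                    classes[gene_id] = "none"
        per_rep[key] = classes

    result = {}
    lines = sorted({line for line, _ in peaks_by_rep})
    for gene_id, _, _ in genes:
        by_line = {line: [] for line in lines}
        for (line, rep), classes in per_rep.items():
            by_line[line].append(classes[gene_id])
        if all("proximal" in cls_list for cls_list in by_line.values()):
            consensus = "proximal"
        elif all(c == "distal" for cls_list in by_line.values() for c in cls_list):
            consensus = "distal"
        else:
            consensus = "neither"
        result[gene_id] = (consensus, {k: v[gene_id] for k, v in per_rep.items()})
    return result


# --- Cox partial likelihood ----------------------------------------------

def cox_partial_loglik(beta, times, events, x, ties="efron"):
    """Direct evaluation of the Cox partial log-likelihood at a given beta."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        risk = times >= t
        d = int(dead.sum())
        xb_risk = np.exp(beta * x[risk])
        xb_dead = np.exp(beta * x[dead])
        ll += beta * x[dead].sum()
        for j in range(d):
            if ties == "efron":
                ll -= np.log(xb_risk.sum() - (j / d) * xb_dead.sum())
            else:
                ll -= np.log(xb_risk.sum())
    return ll


def cox_grid_maximizer(times, events, x, lo=-5.0, hi=5.0, ties="efron"):
    """Grid-search maximiser of the partial likelihood, refined to ~1e-4."""
    grid = np.linspace(lo, hi, 2001)
    lls = [cox_partial_loglik(b, times, events, x, ties) for b in grid]
    best = grid[int(np.argmax(lls))]
    fine = np.linspace(best - 0.01, best + 0.01, 201)
    lls = [cox_partial_loglik(b, times, events, x, ties) for b in fine]
    return float(fine[int(np.argmax(lls))])


# --- IUPAC scanning ------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def scan_naive(seq, consensus, both_strands=True):
    """Position-by-position IUPAC matcher; sequence N matches nothing."""
    def matches(s, start):
        for i, sym in enumerate(consensus):
            base = s[start + i]
            if base == "N" or base not in IUPAC[sym]:
                return False
        return True

    m = len(consensus)
    hits = [(i, "+") for i in range(len(seq) - m + 1) if matches(seq, i)]
    if both_strands:
        rc = "".join(_COMP.get(b, "N") for b in reversed(seq))
        for i in range(len(rc) - m + 1):
            if matches(rc, i):
                hits.append((len(seq) - m - i, "-"))
    return sorted(hits)


# --- permutation enumeration ---------------------------------------------

def enumerate_null_fractions(p_bg, dir_bg, set_size, threshold):
    """Exact null: the statistic over every subset of the background."""
    fractions = []
    idx = range(len(p_bg))
    for subset in combinations(idx, set_size):
        p = np.asarray([p_bg[i] for i in subset])
        q = bh_stepup(p)
        hits = sum(1 for i, j in enumerate(subset) if q[i] < threshold and dir_bg[j])
        fractions.append(hits / set_size)
    return np.asarray(fractions)
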