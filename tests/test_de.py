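"""Differential-transcription selection, BH adjustment, and set intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from tftargets.de import (
    DESelectionConfig,
    bh_adjust,
    expressed_background,
    expressed_for_peaks,
    intersect_directional,
    select_de_contrast,
)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_are_fixed_point(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_hand_worked_stepup(self):
        # ranks 1..4: m*p/i = .04, .04, .04, .04 -> all 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle_and_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.max(np.abs(q - oracles.bh_stepup(ps))) < 1e-12
        assert np.all(q >= np.asarray(ps) - 1e-15)  # pointwise >= input
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in p


def contrast_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "pvalue", "padj", "mean_rpkm", "gene_length"]
    )


class TestSelectDeContrast:
    def test_boundary_rows_against_exhaustive_rule(self):
        cfg = DESelectionConfig()
        rows = [
            ("g01", -1.0, 1e-4, 1e-3, 1.0, 1000),   # passes, negative
            ("g02", 1.0, 1e-4, 1e-3, 1.0, 1000),    # passes, positive
            ("g03", 0.0, 1e-4, 1e-3, 1.0, 1000),    # |lfc| fails
            ("g04", -0.58, 1e-4, 1e-3, 1.0, 1000),  # boundary lfc fails (strict >)
            ("g05", -0.59, 1e-4, 1e-3, 1.0, 1000),  # just past boundary
            ("g06", -1.0, 1e-4, 0.1, 1.0, 1000),    # padj boundary fails (strict <)
            ("g07", -1.0, 1e-4, 0.099, 1.0, 1000),
            ("g08", -1.0, 1e-4, 1e-3, 0.25, 1000),  # rpkm boundary fails (strict >)
            ("g09", -1.0, 1e-4, 1e-3, 0.26, 1000),
            ("g10", -1.0, 1e-4, 1e-3, 1.0, 299),    # length 299 fails (>= 300)
            ("g11", -1.0, 1e-4, 1e-3, 1.0, 300),
            ("g12", -1.0, 1e-4, np.nan, 1.0, 1000), # missing padj fails, no error
        ]
        out = select_de_contrast(contrast_frame(rows), cfg).set_index("gene_id")
        expect_pass = {"g01", "g02", "g05", "g07", "g09", "g11"}
        for gid, row in out.iterrows():
            # independent row-by-row application of the printed thresholds
            src = next(r for r in rows if r[0] == gid)
            ref = (
                src[4] > 0.25 and src[5] >= 300 and abs(src[1]) > 0.58
                and not np.isnan(src[3]) and src[3] < 0.1
            )
            assert row["passed"] == ref == (gid in expect_pass)
        assert out.loc["g01", "direction"] == -1
        assert out.loc["g02", "direction"] == 1

    def test_row_order_irrelevant(self, rng):
        cfg = DESelectionConfig()
        rows = [(f"g{i}", float(l), 0.01, float(q), float(r), int(n))
                for i, (l, q, r, n) in enumerate(zip(
                    rng.normal(0, 1, 50), rng.random(50), rng.lognormal(0, 1, 50),
                    rng.integers(100, 5000, 50)))]
        a = select_de_contrast(contrast_frame(rows), cfg)
        shuffled = contrast_frame(rows).sample(frac=1, random_state=0).reset_index(drop=True)
        b = select_de_contrast(shuffled, cfg)
        merged = a.set_index("gene_id").join(b.set_index("gene_id"), rsuffix="_b")
        assert (merged["passed"] == merged["passed_b"]).all()


def calls_from(passes):
    """passes: {(line, sh): [(gene, direction), ...]} -> select_de_contrast-like frames."""
    out = {}
    for key, items in passes.items():
        genes = [g for g, _ in items]
        out[key] = pd.DataFrame(
            {"gene_id": genes, "passed": [True] * len(genes),
             "direction": [d for _, d in items]}
        )
    return out


class TestIntersectDirectional:
    BASE = {("NY8", "sh1"): [], ("NY8", "sh2"): [], ("NY15", "sh1"): [], ("NY15", "sh2"): []}

    def test_single_cell_line_excluded(self):
        calls = calls_from({**self.BASE, ("NY8", "sh1"): [("gA", -1)]})
        sets_ = intersect_directional(calls)
        assert "gA" not in sets_.upregulated and "gA" not in sets_.downregulated

    def test_one_shrna_per_line_suffices(self):
        calls = calls_from({**self.BASE,
                            ("NY8", "sh2"): [("gA", -1)], ("NY15", "sh1"): [("gA", -1)]})
        assert "gA" in intersect_directional(calls).upregulated

    def test_opposite_directions_across_lines_go_to_neither(self):
        calls = calls_from({**self.BASE,
                            ("NY8", "sh1"): [("gA", -1)], ("NY15", "sh1"): [("gA", 1)]})
        sets_ = intersect_directional(calls)
        assert "gA" in sets_.conflicted
        assert "gA" not in sets_.upregulated and "gA" not in sets_.downregulated

    def test_padj_required_in_one_line_variant(self):
        # gA fails padj in NY8 but meets the other criteria there, and fully
        # passes in NY15: excluded by the default rule, included when the
        # adjusted-p requirement applies to NY15 only
        cfg = DESelectionConfig()
        ny8 = contrast_frame([("gA", -1.0, 0.5, 0.9, 1.0, 1000)])
        ny15 = contrast_frame([("gA", -1.0, 1e-4, 1e-3, 1.0, 1000)])
        empty = contrast_frame([])
        calls = {
            ("NY8", "sh1"): select_de_contrast(ny8, cfg),
            ("NY8", "sh2"): select_de_contrast(empty, cfg),
            ("NY15", "sh1"): select_de_contrast(ny15, cfg),
            ("NY15", "sh2"): select_de_contrast(empty, cfg),
        }
        assert "gA" not in intersect_directional(calls).upregulated
        variant = intersect_directional(calls, padj_required_lines={"NY15"})
        assert "gA" in variant.upregulated

    def test_up_down_sets_disjoint(self):
        calls = calls_from({**self.BASE,
                            ("NY8", "sh1"): [("gA", -1), ("gB", 1)],
                            ("NY15", "sh2"): [("gA", -1), ("gB", 1)]})
        sets_ = intersect_directional(calls)
        assert sets_.upregulated == {"gA"} and sets_.downregulated == {"gB"}
        assert not sets_.upregulated & sets_.downregulated


class TestExpressedSets:
    def test_background_requires_every_cell_line(self):
        rpkm = pd.DataFrame({
            "gene_id": ["g1"] * 4 + ["g2"] * 4,
            "cell_line": ["NY8", "NY8", "NY15", "NY15"] * 2,
            "replicate": ["rep1", "rep2"] * 4,
            "rpkm": [0.6, 0.1, 0.0, 0.0,   # g1: fails NY15
                     0.6, 0.1, 0.51, 0.2],  # g2: max > 0.5 in both
        })
        assert expressed_background(rpkm) == {"g2"}

    def test_background_matches_max_and_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        rows = []
        for g in genes:
            for line in ("NY8", "NY15"):
                for rep in ("rep1", "rep2"):
                    rows.append((g, line, rep, float(rng.lognormal(-0.5, 1))))
        rpkm = pd.DataFrame(rows, columns=["gene_id", "cell_line", "replicate", "rpkm"])
        expected = set()
        for g in genes:
            sub = rpkm[rpkm.gene_id == g]
            ok = all(sub[sub.cell_line == line]["rpkm"].max() > 0.5
                     for line in ("NY8", "NY15"))
            if ok:
                expected.add(g)
        assert expressed_background(rpkm) == expected

    def test_expressed_for_peaks_strict_threshold(self):
        means = pd.Series({"g1": 0.25, "g2": 0.26, "g3": 5.0, "g4": 0.0})
        assert expressed_for_peaks(means) == {"g2", "g3"}
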