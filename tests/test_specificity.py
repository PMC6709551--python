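"""Specificity score, breadth classification, and circRNA/gene overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import circpanel as cp
from circpanel.core import ConfigurationError
from circpanel.specificity import (
    CATEGORY_INTERMEDIATE,
    CATEGORY_SPECIFIC,
    CATEGORY_UBIQUITOUS,
    calibrate_cutoff,
    call_specific_genes,
    classify_breadth,
    specific_overlap_fraction,
    specificity_score,
)

from conftest import make_matrix, make_meta


def _expr(values_by_cell: dict[str, list[float]], genes=None) -> pd.DataFrame:
    df = pd.DataFrame(values_by_cell)
    df.index = pd.Index(genes or [f"g{i}" for i in range(len(df))], name="gene")
    return df


class TestSpecificityScore:
    def test_direct_formula(self):
        cells = {f"c{i}": [v] for i, v in enumerate([0.0, 0.0, 2.0, 4.0, 8.0, 8.0])}
        expr = _expr(cells, genes=["g"])
        # linear-interpolation quantiles of [0,0,2,4,8,8]: Q1 at rank 1.25 ->
        # 0.5, Q3 at rank 3.75 -> 7.0, IQR 6.5; med_all = 3.0; lineage
        # {c4, c5} median = 8.0 -> s = 5/6.5
        meta = make_meta({f"c{i}": ("L" if i >= 4 else "M") for i in range(6)})
        rec = specificity_score(expr, meta, "g", "L")
        assert rec["s"] == pytest.approx(5.0 / 6.5)
        assert rec["specific"]

    def test_zero_numerator_not_specific(self):
        cells = {f"c{i}": [float(i)] for i in range(8)}
        expr = _expr(cells, genes=["g"])
        lineages = {f"c{i}": ("L" if i in (3, 4) else "M") for i in range(8)}
        meta = make_meta(lineages)
        rec = specificity_score(expr, meta, "g", "L")
        assert rec["s"] == pytest.approx(0.0)
        assert not rec["specific"]

    @given(
        a=st.floats(0.01, 100), b=st.floats(-50, 50),
        data=st.lists(st.floats(-100, 100), min_size=6, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_location_scale_invariance(self, a, b, data):
        x = np.asarray(data)
        if np.quantile(x, 0.75) - np.quantile(x, 0.25) <= 1e-9:
            return
        cells = {f"c{i}": [v] for i, v in enumerate(x)}
        lineages = {f"c{i}": ("L" if i < 3 else "M") for i in range(len(x))}
        meta = make_meta(lineages)
        s1 = specificity_score(_expr(cells, ["g"]), meta, "g", "L")["s"]
        cells2 = {k: [a * v[0] + b] for k, v in cells.items()}
        s2 = specificity_score(_expr(cells2, ["g"]), meta, "g", "L")["s"]
        assert s2 == pytest.approx(s1, rel=1e-6, abs=1e-9)

    def test_constant_gene_is_undefined_everywhere(self):
        cells = {f"c{i}": [5.0, float(i)] for i in range(6)}
        expr = _expr(cells, genes=["flat", "varies"])
        meta = make_meta({f"c{i}": ("L" if i < 3 else "M") for i in range(6)})
        table = call_specific_genes(expr, meta)
        flat = table[table["gene"] == "flat"]
        assert not flat["defined"].any()
        assert not flat["specific"].any()

    def test_infinite_cutoff_calls_nothing(self, small_panel):
        table = call_specific_genes(small_panel.expression, small_panel.meta, cutoff=np.inf)
        assert not table["specific"].any()

    def test_planted_high_lineage_gene_called_only_there(self):
        rng = np.random.default_rng(0)
        lineages = {f"c{i}": f"L{i % 4}" for i in range(40)}
        base = rng.normal(0, 1, size=(5, 40))
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(5)], columns=list(lineages))
        boost = [c for c in expr.columns if lineages[c] == "L2"]
        expr.loc["g0", boost] += 10.0
        table = call_specific_genes(expr, make_meta(lineages))
        called = table[(table["gene"] == "g0") & table["specific"]]["lineage"].tolist()
        assert called == ["L2"]

    def test_calibration_fraction_decreases_with_cutoff(self, small_panel):
        out = calibrate_cutoff(
            small_panel.expression.iloc[:100], small_panel.meta, cutoffs=[0.1, 0.5, 1.0, 5.0]
        )
        fracs = out["frac_specific_somewhere"].tolist()
        assert fracs == sorted(fracs, reverse=True)


class TestBreadth:
    def _setup(self):
        lineages = {
            "a1": "LUAD", "a2": "LUAD", "a3": "LUAD",
            "b1": "BRCA", "c1": "COAD", "d1": "PRAD",
        }
        m = make_matrix(
            {
                "chr1:0-10:+": {"a1": 1.0, "a2": 2.0, "a3": 0.5},          # 1 lineage
                "chr1:20-30:+": {"a1": 1.0, "b1": 1.0},                     # 2 lineages
                "chr1:40-50:+": {"a1": 1.0, "b1": 1.0, "c1": 1.0, "d1": 1.0},  # 4
            }
        )
        return m, make_meta(lineages)

    def test_categories_assigned_by_lineage_count(self):
        m, meta = self._setup()
        out = classify_breadth(m, meta, ubiquity_min=4)
        assert out.loc["chr1:0-10:+", "category"] == CATEGORY_SPECIFIC
        assert out.loc["chr1:0-10:+", "lineage"] == "LUAD"
        assert out.loc["chr1:20-30:+", "category"] == CATEGORY_INTERMEDIATE
        assert out.loc["chr1:40-50:+", "category"] == CATEGORY_UBIQUITOUS

    def test_fifteen_lineage_rule(self):
        lineages = {f"c{i}": f"L{i}" for i in range(16)}
        m = make_matrix(
            {
                "chr1:0-10:+": {f"c{i}": 1.0 for i in range(15)},
                "chr1:20-30:+": {f"c{i}": 1.0 for i in range(14)},
            }
        )
        out = classify_breadth(m, make_meta(lineages))
        assert out.loc["chr1:0-10:+", "category"] == CATEGORY_UBIQUITOUS
        assert out.loc["chr1:20-30:+", "category"] == CATEGORY_INTERMEDIATE

    def test_missing_lineage_is_configuration_error(self):
        m, _ = self._setup()
        with pytest.raises(ConfigurationError):
            classify_breadth(m, make_meta({"a1": "LUAD"}), ubiquity_min=4)

    def test_specific_sets_partition_single_lineage_circs(self, small_matrix, small_panel):
        out = classify_breadth(small_matrix, small_panel.meta, ubiquity_min=3)
        single = set(out.index[out["n_lineages"] == 1])
        spec = out[out["category"] == CATEGORY_SPECIFIC]
        per_lineage = {
            lin: set(sub.index) for lin, sub in spec.groupby("lineage")
        }
        union = set().union(*per_lineage.values()) if per_lineage else set()
        assert union == single
        sets = list(per_lineage.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_category_counts_sum_to_total(self, small_matrix, small_panel):
        out = classify_breadth(small_matrix, small_panel.meta, ubiquity_min=3)
        assert out["category"].value_counts().sum() == small_matrix.values.shape[0]

    def test_fully_restricted_panel_is_all_lineage_specific(self):
        cfg = cp.PanelConfig(
            seed=2, n_lineages=3, lines_per_lineage=6, n_genes=60, n_circ=120,
            frac_lineage_specific=1.0, n_planted_drug_effects=0,
        )
        panel = cp.simulate_panel(cfg)
        m = cp.normalize_reads(
            cp.merge_calls(panel.tool_calls), panel.meta, cell_lines=panel.cell_lines
        )
        true_calls = m.values.index.isin(panel.truth.true_reads.index)
        out = classify_breadth(cp.CircMatrix(m.values[true_calls]), panel.meta)
        assert (out["category"] == CATEGORY_SPECIFIC).all()


class TestOverlapFraction:
    def test_simple_ratio(self):
        lineages = {"a1": "L1", "b1": "L2"}
        values = {f"chr1:{i}-{i+5}:+": {"a1": 1.0} for i in range(100)}
        m = make_matrix(values)
        gene_of_circ = {c: f"g{i}" for i, c in enumerate(values)}
        meta = make_meta(lineages, gene_of_circ=gene_of_circ)
        breadth = classify_breadth(m, meta)
        spec = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(100)],
                "lineage": "L1",
                "s": 1.0,
                "defined": True,
                "specific": [i < 2 for i in range(100)],  # exactly 2 specific parents
            }
        )
        out = specific_overlap_fraction(breadth, spec, meta).set_index("lineage")
        assert out.loc["L1", "fraction"] == pytest.approx(0.02)

    def test_lineage_without_specific_circs_is_undefined(self):
        lineages = {"a1": "L1", "b1": "L2"}
        m = make_matrix({"chr1:0-5:+": {"a1": 1.0}})
        meta = make_meta(lineages, gene_of_circ={"chr1:0-5:+": "g0"})
        breadth = classify_breadth(m, meta)
        spec = pd.DataFrame(
            {"gene": ["g0"], "lineage": ["L2"], "s": [0.0], "defined": [True], "specific": [False]}
        )
        out = specific_overlap_fraction(breadth, spec, meta).set_index("lineage")
        assert np.isnan(out.loc["L2", "fraction"])
        assert out.loc["L2", "n_circ"] == 0

    def test_independent_generation_keeps_fractions_small(self, small_panel, small_matrix):
        """circRNA presence is generated independently of parental-gene
        expression, so the overlap should be near the product of marginal
        specific rates (small), never large."""
        meta = small_panel.meta
        breadth = classify_breadth(small_matrix, meta, ubiquity_min=3)
        spec = call_specific_genes(small_panel.expression, meta)
        out = specific_overlap_fraction(breadth, spec, meta)
        fracs = out["fraction"].dropna()
        assert len(fracs)
        # marginal rate of lineage-specific genes per lineage is ~what chance
        # overlap allows; generous bound well below 1
        assert (fracs <= 0.35).all()
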