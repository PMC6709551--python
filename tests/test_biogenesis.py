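"""Regulator correlation screen, EMT scores, load splits, group comparisons."""

import numpy as np
import pandas as pd
import pytest

import circpanel as cp
from circpanel.biogenesis import (
    GROUP_HIGH,
    GROUP_LOW,
    compare_load_groups,
    correlate_regulators,
    emt_score,
    export_gsea_inputs,
    per_lineage_correlations,
    read_cls,
    split_high_low,
)
from circpanel.core import ConfigurationError, ValidationError

from conftest import make_meta


def _expr(rows: dict[str, list[float]], cells: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=cells).T


class TestCorrelateRegulators:
    def test_monotone_gene_has_rs_one(self):
        cells = [f"c{i}" for i in range(10)]
        load = pd.Series(np.arange(10.0), index=cells)
        expr = _expr({"g": list(np.exp(np.arange(10.0)))}, cells)  # monotone, nonlinear
        out = correlate_regulators(expr, load, ["g"])
        assert out.iloc[0]["rs"] == pytest.approx(1.0)

    def test_rs_below_threshold_not_significant_despite_tiny_q(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(500)]
        load = pd.Series(rng.normal(size=500), index=cells)
        # weak true correlation ~0.25: significant p but fails |rs| > 0.3
        g = 0.25 * (load - load.mean()) / load.std() + np.sqrt(1 - 0.0625) * rng.normal(size=500)
        expr = _expr({"g": list(g)}, cells)
        out = correlate_regulators(expr, load, ["g"])
        row = out.iloc[0]
        assert row["q"] < 0.01 and abs(row["rs"]) < 0.3
        assert not row["significant"]

    def test_missing_gene_recorded_not_dropped(self):
        cells = [f"c{i}" for i in range(5)]
        load = pd.Series(np.arange(5.0), index=cells)
        expr = _expr({"g": [1, 2, 3, 4, 5]}, cells)
        out = correlate_regulators(expr, load, ["g", "absent"])
        assert set(out["gene"]) == {"g", "absent"}
        assert (out.set_index("gene").loc["absent", "status"]) == "missing"

    def test_planted_regulator_flagged_nulls_controlled(self, small_panel, small_matrix):
        load = cp.total_backsplice_load(small_matrix)
        truth = small_panel.truth.genes
        planted = list(truth[truth["regulator_effect"] != 0]["gene"])
        nulls = [g for g in small_panel.expression.index if g not in set(planted)][:99]
        out = correlate_regulators(small_panel.expression, load, planted + nulls)
        flagged = set(out[out["significant"]]["gene"])
        assert set(planted) <= flagged
        assert len(flagged - set(planted)) <= 5  # q_max * 100 on average

    def test_bh_nesting_significant_at_01_subset_of_05(self, small_panel, small_matrix):
        load = cp.total_backsplice_load(small_matrix)
        genes = list(small_panel.expression.index[:120])
        strict = correlate_regulators(small_panel.expression, load, genes, q_max=0.01)
        loose = correlate_regulators(small_panel.expression, load, genes, q_max=0.05)
        s1 = set(strict[strict["significant"]]["gene"])
        s5 = set(loose[loose["significant"]]["gene"])
        assert s1 <= s5


class TestPerLineage:
    def test_small_lineages_skipped(self):
        cells = [f"c{i}" for i in range(9)]
        meta = make_meta({c: "L1" for c in cells})
        load = pd.Series(np.arange(9.0), index=cells)
        expr = _expr({"g": list(range(9))}, cells)
        out = per_lineage_correlations(expr, load, meta, ["g"], min_lines=10)
        assert out.empty

    def test_identical_lineages_get_identical_rs(self):
        cells = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        lineage = {c: ("LA" if c.startswith("a") else "LB") for c in cells}
        meta = make_meta(lineage)
        vec = list(np.arange(10.0))
        load = pd.Series(vec + vec, index=cells)
        expr = _expr({"g": [v**2 for v in vec] + [v**2 for v in vec]}, cells)
        out = per_lineage_correlations(expr, load, meta, ["g"], min_lines=10)
        rs = out.set_index("lineage")["rs"]
        assert rs["LA"] == pytest.approx(rs["LB"])

    def test_lineage_restricted_regulator_flagged_only_there(self):
        rng = np.random.default_rng(1)
        n = 30
        cells = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        meta = make_meta({c: ("LA" if c.startswith("a") else "LB") for c in cells})
        load = pd.Series(rng.gamma(5, 1, size=2 * n), index=cells)
        g = np.empty(2 * n)
        zl = (load.values - load.values.mean()) / load.values.std()
        g[:n] = 0.9 * zl[:n] + 0.3 * rng.normal(size=n)   # coupled in LA
        g[n:] = rng.normal(size=n)                         # null in LB
        expr = _expr({"g": list(g)}, cells)
        out = per_lineage_correlations(expr, load, meta, ["g"], min_lines=10)
        sig = out.set_index("lineage")["significant"]
        assert bool(sig["LA"]) and not bool(sig["LB"])


class TestEmtScore:
    def _z(self, mes_val, epi_val, cells=3):
        idx = list(cp.biogenesis.MESENCHYMAL_MARKERS) + list(cp.biogenesis.EPITHELIAL_MARKERS)
        data = np.vstack(
            [np.full((len(cp.biogenesis.MESENCHYMAL_MARKERS), cells), mes_val),
             np.full((len(cp.biogenesis.EPITHELIAL_MARKERS), cells), epi_val)]
        )
        return pd.DataFrame(data, index=idx, columns=[f"c{i}" for i in range(cells)])

    def test_all_zero_z_gives_zero(self):
        assert (emt_score(self._z(0.0, 0.0)) == 0).all()

    def test_plus_minus_one_gives_two(self):
        assert np.allclose(emt_score(self._z(1.0, -1.0)), 2.0)

    def test_missing_marker_listed(self):
        z = self._z(1.0, -1.0).drop(index=["VIM", "CDH1"])
        with pytest.raises(ConfigurationError, match="VIM"):
            emt_score(z)

    def test_load_correlates_with_emt_on_coupled_panel(self):
        cfg = cp.PanelConfig(seed=11, n_lineages=5, lines_per_lineage=100,
                             n_genes=30, n_circ=300)
        panel = cp.simulate_panel(cfg)
        m = cp.normalize_reads(
            cp.merge_calls(panel.tool_calls), panel.meta, cell_lines=panel.cell_lines
        )
        load = cp.total_backsplice_load(m)
        score = emt_score(panel.zscores)
        from scipy.stats import spearmanr
        rs = spearmanr(score[load.index], load).statistic
        assert rs > 0.3


class TestSplitAndCompare:
    def test_median_split_strictly_above(self):
        load = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        groups = split_high_low(load)
        assert set(groups[groups == GROUP_HIGH].index) == {"c", "d"}

    def test_all_equal_everything_low(self):
        groups = split_high_low(pd.Series({"a": 2.0, "b": 2.0, "c": 2.0}))
        assert (groups == GROUP_LOW).all()

    def test_shift_invariance(self):
        load = pd.Series({"a": 1.0, "b": 5.0, "c": 2.0, "d": 9.0})
        pd.testing.assert_series_equal(split_high_low(load), split_high_low(load + 100.0))

    def test_identical_constant_groups_give_p_one(self):
        load = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0, "x": 5.0, "y": 5.0, "z": 5.0})
        groups = pd.Series({"a": "t", "b": "t", "c": "t", "x": "u", "y": "u", "z": "u"})
        t, p = compare_load_groups(load, groups)
        assert (t, p) == (0.0, 1.0)

    def test_identical_varying_groups_give_p_one(self):
        load = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "x": 1.0, "y": 2.0, "z": 3.0})
        groups = pd.Series({"a": "t", "b": "t", "c": "t", "x": "u", "y": "u", "z": "u"})
        t, p = compare_load_groups(load, groups)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        load = pd.Series({"a": 0.0, "b": 1.0, "c": 2.0, "x": 10.0, "y": 11.0, "z": 12.0})
        groups = pd.Series({"a": "t", "b": "t", "c": "t", "x": "u", "y": "u", "z": "u"})
        _, p = compare_load_groups(load, groups)
        assert p < 0.01

    def test_degenerate_unequal_means_is_error(self):
        load = pd.Series({"a": 1.0, "b": 1.0, "x": 2.0, "y": 2.0})
        groups = pd.Series({"a": "t", "b": "t", "x": "u", "y": "u"})
        with pytest.raises(ValidationError):
            compare_load_groups(load, groups)


class TestGseaExport:
    def test_phenotype_file_round_trips_and_counts_match(self, tmp_path):
        cells = ["c1", "c2", "c3", "c4"]
        expr = pd.DataFrame(
            np.arange(12.0).reshape(3, 4), index=["g1", "g2", "g3"], columns=cells
        )
        groups = pd.Series([GROUP_HIGH, GROUP_HIGH, GROUP_LOW, GROUP_LOW], index=cells)
        gct, cls = export_gsea_inputs(expr, groups, tmp_path / "export")
        back = read_cls(cls, cells)
        pd.testing.assert_series_equal(back, groups, check_names=False)
        assert (back == GROUP_HIGH).sum() == 2
        lines = gct.read_text().splitlines()
        assert lines[0] == "#1.2"
        assert lines[1].split("\t") == ["3", "4"]
        assert lines[2].split("\t")[:2] == ["NAME", "DESCRIPTION"]
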