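"""Genotype-contrast classification, key pairs, enrichment, qPCR arithmetic."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from lncscreen.screen import (
    CATEGORIES,
    NOT_LINKED,
    S_ONLY,
    T_DOWN,
    T_UP,
    ToleranceCall,
    concordance_r2,
    contrast_classify,
    overrepresentation,
    qpcr_log2_fold_changes,
    relative_expression_ddct,
    screen_features,
    select_key_pairs,
)

STATES = ("up", "down", "unchanged")


class TestContrastClassify:
    @pytest.mark.parametrize(
        "tol,sen,expected",
        [("up", "down", T_UP), ("up", "unchanged", T_UP),
         ("down", "up", T_DOWN), ("down", "unchanged", T_DOWN),
         ("unchanged", "down", S_ONLY), ("unchanged", "up", S_ONLY),
         ("up", "up", NOT_LINKED), ("down", "down", NOT_LINKED),
         ("unchanged", "unchanged", NOT_LINKED)],
    )
    def test_category_mapping(self, tol, sen, expected):
        assert contrast_classify(tol, sen) == expected

    def test_total_over_grid_with_three_concordant_cells(self):
        grid = [contrast_classify(a, b) for a, b in itertools.product(STATES, repeat=2)]
        assert len(grid) == 9
        assert grid.count(NOT_LINKED) == 3
        assert all(c in CATEGORIES for c in grid)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            contrast_classify("up", "sideways")


class TestScreenFeatures:
    def _de(self, mapping, genotype):
        return pd.DataFrame(
            {"feature_id": list(mapping), "genotype": genotype,
             "log2fc": 0.0, "pvalue": 1.0, "fdr": 1.0, "state": list(mapping.values())}
        )

    def test_counts_sum_to_universe(self):
        det = self._de({"a": "up", "b": "down", "c": "unchanged"}, "tolerant")
        des = self._de({"a": "down", "b": "down", "c": "up"}, "sensitive")
        calls, summary = screen_features(det, des)
        assert len(calls) == 3
        assert summary["n"].sum() == 3

    def test_one_sided_feature_counts_as_unchanged(self):
        det = self._de({"a": "up"}, "tolerant")
        des = self._de({"b": "down"}, "sensitive")
        calls, _ = screen_features(det, des)
        by_id = {c.feature_id: c for c in calls}
        assert by_id["a"].state_sensitive == "unchanged"
        assert by_id["a"].category == T_UP
        assert by_id["b"].category == S_ONLY

    def test_empty_input_gives_empty_output(self):
        empty = self._de({}, "tolerant")
        calls, summary = screen_features(empty, empty)
        assert calls == [] and summary["n"].sum() == 0


class TestSelectKeyPairs:
    def _calls(self, d):
        return [
            ToleranceCall(f, st, ss, contrast_classify(st, ss)) for f, (st, ss) in d.items()
        ]

    def test_linked_lnc_with_discordant_target_retained(self):
        calls = self._calls({"l": ("up", "down"), "t": ("up", "unchanged")})
        pairs = pd.DataFrame({"lncrna_id": ["l"], "target_id": ["t"]})
        assert len(select_key_pairs(pairs, calls)) == 1

    def test_not_linked_lnc_dropped(self):
        calls = self._calls({"l": ("up", "up"), "t": ("up", "unchanged")})
        pairs = pd.DataFrame({"lncrna_id": ["l"], "target_id": ["t"]})
        assert select_key_pairs(pairs, calls).empty

    def test_concordant_target_dropped(self):
        calls = self._calls({"l": ("up", "down"), "t": ("down", "down")})
        pairs = pd.DataFrame({"lncrna_id": ["l"], "target_id": ["t"]})
        assert select_key_pairs(pairs, calls).empty


class TestOverrepresentation:
    def test_query_equal_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(20)]
        table = overrepresentation(uni, {"t1": uni[:5], "t2": uni[5:]}, uni)
        assert (table["pvalue"] == 1.0).all()

    def test_fully_contained_term_closed_form(self):
        uni = [f"g{i}" for i in range(100)]
        table = overrepresentation(uni[:5], {"term": uni[:5]}, uni)
        assert table["pvalue"][0] == pytest.approx(1 / comb(100, 5))

    def test_disjoint_term_complement_against_enumeration(self):
        uni = [f"g{i}" for i in range(30)]
        genes, term = uni[:6], uni[10:15]
        table = overrepresentation(genes, {"t": term}, uni)
        assert table["pvalue"][0] == pytest.approx(1.0)
        # enumeration oracle for P(overlap >= 1) of a random 6-gene draw
        N, K, n = 30, 5, 6
        p_ge1 = sum(
            comb(K, k) * comb(N - K, n - k) for k in range(1, min(K, n) + 1)
        ) / comb(N, n)
        from scipy.stats import hypergeom

        assert hypergeom.sf(0, N, K, n) == pytest.approx(p_ge1)

    def test_qvalues_monotone_in_p(self):
        uni = [f"g{i}" for i in range(50)]
        tmap = {f"t{i}": uni[i : i + 8] for i in range(0, 40, 4)}
        table = overrepresentation(uni[:10], tmap, uni)
        assert (table["qvalue"].diff().dropna() >= -1e-12).all()

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(["x"], {"t": ["a"]}, ["a", "b"])


class TestQpcr:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "group", "gene", "target_ct", "reference_ct"]
        )

    def test_ddct_arithmetic(self):
        tab = self._table(
            [("c1", "control", "g", 25.0, 20.0), ("t1", "treated", "g", 23.0, 20.0)]
        )
        rel = relative_expression_ddct(tab)
        by = dict(zip(rel["sample"], rel["relative_expression"]))
        assert by["c1"] == pytest.approx(1.0)
        assert by["t1"] == pytest.approx(4.0)

    def test_downregulation(self):
        tab = self._table(
            [("c1", "control", "g", 25.0, 20.0), ("t1", "treated", "g", 27.0, 20.0)]
        )
        rel = relative_expression_ddct(tab)
        assert rel.loc[rel["sample"] == "t1", "relative_expression"].iloc[0] == pytest.approx(0.25)

    def test_control_group_mean_anchors_ddct(self):
        tab = self._table(
            [("c1", "control", "g", 24.0, 20.0), ("c2", "control", "g", 26.0, 20.0),
             ("t1", "treated", "g", 23.0, 20.0)]
        )
        rel = relative_expression_ddct(tab)
        ctl = rel[rel["group"] == "control"]
        assert ctl["delta_delta_ct"].mean() == pytest.approx(0.0)

    def test_missing_reference_ct_names_sample(self):
        tab = self._table([("c1", "control", "g", 25.0, np.nan)])
        with pytest.raises(ValueError, match="c1"):
            relative_expression_ddct(tab)

    def test_fold_change_extraction(self):
        tab = self._table(
            [("c1", "control", "g", 25.0, 20.0), ("t1", "treated", "g", 22.0, 20.0)]
        )
        lfc = qpcr_log2_fold_changes(relative_expression_ddct(tab))
        assert lfc.loc[0, "log2fc_qpcr"] == pytest.approx(3.0)


class TestConcordance:
    def test_exact_line_gives_unity(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert concordance_r2(2 * x + 1, x) == pytest.approx(1.0)

    def test_orthogonal_residual_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # residualised against x by symmetry
        assert concordance_r2(y, x) == pytest.approx(0.0, abs=1e-12)

    def test_four_point_closed_form(self):
        x = [0.5, 1.5, 3.0, 4.0]
        y = [1.0, 2.2, 2.8, 4.4]
        assert concordance_r2(y, x) == pytest.approx(0.9416091954022987)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            concordance_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
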