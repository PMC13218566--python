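"""Numeric-to-theme pipeline, mapping power, and the DEG-analogy selection."""

import numpy as np
import pandas as pd
import pytest

from themecast import (NumericPanel, SyntheticSpec, binarize_presence,
                       deg_select, dichotomize, gen_two_domain_panel,
                       mapping_power, numeric_to_theme, paired_t_within,
                       tokenize_and_occur)
from themecast.errors import ParameterError
from themecast.numeric_mp import person_tokens


def panel_of(values, label=None):
    values = np.asarray(values, float)
    return NumericPanel([f"p{i}" for i in range(values.shape[0])],
                        [f"I{j}" for j in range(values.shape[1])],
                        values, true_label=label)


class TestDichotomize:
    def test_strict_mean_threshold(self):
        b = dichotomize(panel_of([[1], [2], [3]]))
        assert b.values[:, 0].tolist() == [0, 0, 1]
        assert b.item_means[0] == pytest.approx(2.0)

    def test_constant_item_all_zeros(self):
        with pytest.warns(UserWarning):
            b = dichotomize(panel_of([[5, 1], [5, 2]]))
        assert b.values[:, 0].tolist() == [0, 0]

    def test_binary_input_reproduces_pattern(self):
        """A 0/1 column with mean in (0,1) dichotomizes to itself."""
        col = [[0], [1], [1]]
        b1 = dichotomize(panel_of(col))
        b2 = dichotomize(NumericPanel(b1.persons, b1.items, b1.values))
        assert np.array_equal(b1.values, b2.values)
        assert np.array_equal(b1.values, np.array(col, float))

    def test_needs_two_persons(self):
        with pytest.raises(ParameterError):
            dichotomize(panel_of([[1, 2]]))


class TestTokenize:
    def test_row_yields_y_tokens(self):
        p = NumericPanel(["p0"] * 0 + ["p0", "p1"], ["A", "B", "C"],
                         np.array([[1, 0, 1], [0, 0, 0]], float))
        tdm = tokenize_and_occur(p)
        assert set(tdm.terms) == {"YA", "YC"}
        assert person_tokens(p)["p0"] == ["YA", "YC"]
        assert person_tokens(p)["p1"] == []  # all-zero row: empty document

    def test_token_count_equals_matrix_sum(self):
        rng = np.random.default_rng(1)
        vals = (rng.random((8, 5)) > 0.5).astype(float)
        p = NumericPanel([f"p{i}" for i in range(8)],
                         [f"I{j}" for j in range(5)], vals)
        tdm = tokenize_and_occur(p)
        assert tdm.total_mass() == int(vals.sum())

    def test_rejects_non_binary(self):
        with pytest.raises(ParameterError):
            tokenize_and_occur(panel_of([[0.5]]))


class TestNumericToTheme:
    def test_disjoint_item_blocks_separate_groups(self):
        # persons 0-2 answer items A,B only; persons 3-5 answer C,D only
        vals = np.array([[5, 5, 0, 0]] * 3 + [[0, 0, 5, 5]] * 3, float)
        asg = numeric_to_theme(panel_of(vals), target_clusters=2)
        themes = [a.theme for a in asg]
        assert len(set(themes[:3])) == 1 and len(set(themes[3:])) == 1
        assert themes[0] != themes[3]

    def test_deterministic(self):
        panel = gen_two_domain_panel(SyntheticSpec(seed=8))
        a = [x.theme for x in numeric_to_theme(panel)]
        b = [x.theme for x in numeric_to_theme(panel)]
        assert a == b


class TestMappingPower:
    def test_perfect_agreement(self):
        panel = gen_two_domain_panel(SyntheticSpec(seed=0))
        asg = numeric_to_theme(panel, target_clusters=2)
        assert mapping_power(asg, panel.true_label).mp == pytest.approx(1.0)

    def test_flip_invariance(self):
        """Relabeling themes or flipping the binary label leaves MP unchanged."""
        panel = gen_two_domain_panel(SyntheticSpec(seed=2))
        asg = numeric_to_theme(panel, target_clusters=2)
        mp = mapping_power(asg, panel.true_label).mp
        flipped_label = 1 - np.asarray(panel.true_label)
        assert mapping_power(asg, flipped_label).mp == pytest.approx(mp)
        import copy
        relabeled = copy.deepcopy(asg)
        for a in relabeled:
            a.theme = {1: 2, 2: 1}[a.theme]
        assert mapping_power(relabeled, panel.true_label).mp == pytest.approx(mp)

    def test_null_effect_mean_near_zero(self):
        mps = []
        for seed in range(30):
            panel = gen_two_domain_panel(SyntheticSpec(seed=seed, effect_d=0.0))
            asg = numeric_to_theme(panel, target_clusters=2)
            mps.append(mapping_power(asg, panel.true_label).mp)
        assert abs(np.mean(mps)) < 0.15

    def test_too_many_themes_rejected(self):
        from themecast.taaa_core import ThemeAssignment
        asg = [ThemeAssignment(f"p{i}", {i % 3 + 1: 1}, i % 3 + 1, "L")
               for i in range(9)]
        with pytest.raises(ParameterError, match="target_clusters"):
            mapping_power(asg, [0, 1, 0, 1, 0, 1, 0, 1, 0])


class TestDegSelect:
    def toy(self):
        # 6 persons, 4 items on a positive scale: I0 planted up in group 1,
        # I1 planted down, I2/I3 null
        rng = np.random.default_rng(0)
        base = rng.normal(5, 0.1, (6, 4))
        base[3:, 0] += 4.0
        base[3:, 1] -= 4.0
        return base, np.array([0, 0, 0, 1, 1, 1])

    def test_planted_items_in_core_terms(self):
        vals, groups = self.toy()
        sel = deg_select(vals, groups, items=["I0", "I1", "I2", "I3"], top_n=1)
        assert "I0" in sel.core_terms and "I1" in sel.core_terms
        st = sel.stats.set_index("item")
        assert st.loc["I0", "direction"] == "up"
        assert st.loc["I1", "direction"] == "down"
        assert st.loc["I0", "p_value"] < st.loc["I2", "p_value"]

    def test_identical_means_flat_never_selected(self):
        vals = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 0.0], [1.0, 2.0]])
        groups = [0, 0, 1, 1]
        sel = deg_select(vals, groups, items=["flat", "varies"], top_n=1)
        assert "flat" not in sel.selected_by_p
        assert "flat" not in sel.selected_by_fc

    def test_selection_size_bounds(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (10, 30))
        sel = deg_select(vals, [0] * 5 + [1] * 5,
                         items=[f"I{j}" for j in range(30)], top_n=10)
        assert len(sel.selected_by_p) <= 20
        assert len(sel.core_terms) <= 40

    def test_welch_p_matches_scipy(self):
        from scipy import stats as sps
        vals, groups = self.toy()
        sel = deg_select(vals, groups, items=list("ABCD"))
        expected = sps.ttest_ind(vals[3:, 0], vals[:3, 0], equal_var=False).pvalue
        got = sel.stats.set_index("item").loc["A", "p_value"]
        assert got == pytest.approx(expected)


class TestBinarizePresence:
    def test_strict_mean_row_example(self):
        df = pd.DataFrame([[0, 0, 4]], index=["t"], columns=list("abc"))
        assert binarize_presence(df).loc["t"].tolist() == [0, 0, 1]

    def test_constant_term_all_zeros(self):
        df = pd.DataFrame([[2, 2, 2]], index=["t"], columns=list("abc"))
        assert binarize_presence(df).loc["t"].tolist() == [0, 0, 0]

    def test_equivalent_to_dichotomize_transposed(self):
        rng = np.random.default_rng(7)
        vals = rng.random((5, 8))  # terms x persons
        df = pd.DataFrame(vals, index=[f"t{i}" for i in range(5)],
                          columns=[f"p{j}" for j in range(8)])
        via_binarize = binarize_presence(df).to_numpy()
        via_dicho = dichotomize(panel_of(vals.T)).values.T
        assert np.array_equal(via_binarize, via_dicho)


class TestPairedT:
    def test_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 5.0]
        res = paired_t_within(a, b)
        d = np.array(a) - np.array(b)
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t == pytest.approx(t_manual)
        assert 0 < res.p < 1 and not res.degenerate

    def test_identical_vectors_degenerate(self):
        assert paired_t_within([1, 2, 3], [1, 2, 3]).degenerate

    def test_constant_nonzero_difference_degenerate(self):
        assert paired_t_within([1, 2, 3], [2, 3, 4]).degenerate

    def test_length_validation(self):
        with pytest.raises(ParameterError):
            paired_t_within([1], [2])
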