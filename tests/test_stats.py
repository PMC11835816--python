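"""ANOVA layer, Tukey HSD and compact letter displays."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kiwiphen.errors import DesignError
from kiwiphen.reference_data import reference_cell, load_reference_means, \
    synthesize_replicates
from kiwiphen.stats import (
    check_assumptions,
    compact_letter_display,
    one_way_anova,
    tukey_hsd,
    two_way_anova,
)
from oracles import balanced_two_way_anova


def _balanced(a_levels, b_levels, n, values):
    """Long DataFrame from an (a, b, n) value array."""
    rows = []
    for i, trt in enumerate(a_levels):
        for j, cult in enumerate(b_levels):
            for k in range(n):
                rows.append({"treatment": trt, "cultivar": cult, "daw": 1,
                             "y": float(values[i, j, k])})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_closed_form_oracle_to_six_decimals(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(10, 2, size=(2, 2, 4))
        df = _balanced(["WW", "WL"], ["B", "D"], 4, vals)
        res = two_way_anova(df, "y")
        oracle = balanced_two_way_anova(vals)
        assert res.p_treatment == pytest.approx(oracle["A"][1], abs=1e-6)
        assert res.p_cultivar == pytest.approx(oracle["B"][1], abs=1e-6)
        assert res.p_interaction == pytest.approx(oracle["AB"][1], abs=1e-6)

    def test_type_II_equals_type_I_on_balanced_data(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(3)
        df = _balanced(["WW", "WL"], ["B", "D", "H"], 4,
                       rng.normal(5, 1, size=(2, 3, 4)))
        model = ols("y ~ C(treatment) * C(cultivar)", data=df).fit()
        t1 = sm.stats.anova_lm(model, typ=1)
        t2 = sm.stats.anova_lm(model, typ=2)
        for term in ("C(treatment)", "C(cultivar)", "C(treatment):C(cultivar)"):
            assert t1.loc[term, "sum_sq"] == pytest.approx(t2.loc[term, "sum_sq"])

    def test_cultivar_shift_detected_while_null_treatment_stays_quiet(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, size=(2, 3, 5))
        vals[:, 1, :] += 10.0
        vals[:, 2, :] += 20.0
        res = two_way_anova(_balanced(["WW", "WL"], ["B", "D", "H"], 5, vals), "y")
        assert res.p_cultivar < 0.001
        assert res.p_treatment > 0.01

    def test_empty_cell_failure_names_the_cell(self):
        df = _balanced(["WW", "WL"], ["B", "D"], 3,
                       np.zeros((2, 2, 3)) + np.arange(3))
        df = df[~((df.treatment == "WL") & (df.cultivar == "D"))]
        with pytest.raises(DesignError, match="treatment=WL, cultivar=D"):
            two_way_anova(df, "y")

    def test_null_rejection_rate_is_near_alpha(self):
        rng = np.random.default_rng(202)
        rejections = 0
        n_sim = 250
        for _ in range(n_sim):
            vals = rng.normal(0, 1, size=(2, 3, 4))
            res = two_way_anova(_balanced(["WW", "WL"], ["B", "D", "H"], 4, vals), "y")
            rejections += res.p_treatment < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09


class TestOneWayAnova:
    def test_two_group_f_equals_pooled_t(self):
        rng = np.random.default_rng(4)
        df = _balanced(["WW", "WL"], ["B"], 6, rng.normal(0, 1, size=(2, 1, 6)))
        p_f = one_way_anova(df, "y")
        a = df[df.treatment == "WW"].y
        b = df[df.treatment == "WL"].y
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert p_f == pytest.approx(p_t, abs=1e-12)

    def test_published_daw4_photosynthesis_cell_is_significant(self):
        """Replicates rebuilt from the printed D/DAW 4 means and SEs (n=4)
        separate WW from WL at alpha = 0.05, as the published letters do."""
        means = load_reference_means("rootstock")
        rows = []
        for trt in ("WW", "WL"):
            cell = reference_cell(means, "D", trt, 4, "A")
            for v in synthesize_replicates(cell["mean"], cell.se, int(cell.n)):
                rows.append({"treatment": trt, "cultivar": "D", "daw": 4, "y": v})
        assert one_way_anova(pd.DataFrame(rows), "y") < 0.05

    def test_requires_two_treatment_groups(self):
        df = pd.DataFrame({"treatment": ["WW"] * 4, "cultivar": "B",
                           "daw": 1, "y": [1.0, 2, 3, 4]})
        with pytest.raises(DesignError):
            one_way_anova(df, "y")


class TestAssumptionChecks:
    def test_skewed_data_is_rejected_by_shapiro(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = check_assumptions({"g": rng.lognormal(0, 1.5, 20)})
            rejections += rep.shapiro["g"][1] < 0.05
        assert rejections / 100 > 0.9

    def test_constant_data_is_skipped_with_signal(self):
        rep = check_assumptions({"a": np.full(5, 3.0), "b": np.full(5, 3.0)})
        assert rep.shapiro["a"] == "skipped: zero variance"
        assert rep.levene == "skipped: zero variance"

    def test_insufficient_n_is_skipped(self):
        rep = check_assumptions({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        assert rep.shapiro["a"] == "skipped: n < 3"

    def test_well_behaved_groups_pass(self):
        rng = np.random.default_rng(0)
        rep = check_assumptions({k: rng.normal(0, 1, 20) for k in "abc"})
        assert rep.all_normal
        assert rep.levene[1] > 0.05


def _letter_graph_valid(grouping):
    """Letter sharing must encode exactly the non-significant pairs."""
    for a in grouping.groups:
        for b in grouping.groups:
            if a >= b:
                continue
            share = bool(set(grouping.letters[a]) & set(grouping.letters[b]))
            nonsig = grouping.p_adjusted[frozenset((a, b))] >= grouping.alpha
            if share != nonsig:
                return False
    return True


class TestTukey:
    def _df(self, means, sd=0.1, n=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, mu in enumerate(means):
            for v in rng.normal(mu, sd, n):
                rows.append({"group": f"g{i}", "y": v})
        return pd.DataFrame(rows)

    def test_identical_groups_share_one_letter(self):
        g = tukey_hsd(self._df([5.0, 5.0, 5.0], sd=0.01), "y", "group")
        assert set(g.letters.values()) == {"a"}

    def test_clear_outlier_gets_its_own_letter(self):
        g = tukey_hsd(self._df([0.0, 0.0, 10.0], sd=0.05), "y", "group")
        assert g.letters["g0"] == g.letters["g1"]
        assert g.letters["g2"] != g.letters["g0"]
        assert _letter_graph_valid(g)
        # adjusted p for the distant pair is essentially zero
        assert g.p_adjusted[frozenset(("g0", "g2"))] < 1e-6

    def test_two_groups_collapse_to_unadjusted_t_test(self):
        df = self._df([1.0, 1.4], sd=0.5, n=8, seed=2)
        g = tukey_hsd(df, "y", "group")
        a = df[df.group == "g0"].y
        b = df[df.group == "g1"].y
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert g.p_adjusted[frozenset(("g0", "g1"))] == pytest.approx(p_t, abs=1e-9)

    def test_uppercase_letters_for_interaction_cells(self):
        g = tukey_hsd(self._df([0.0, 10.0], sd=0.05), "y", "group", uppercase=True)
        assert set("".join(g.letters.values())) <= set("AB")

    def test_small_group_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(DesignError):
            tukey_hsd(df, "y", "group")

    def test_relabeling_changes_letters_only_by_renaming(self):
        df = self._df([0.0, 0.5, 4.0], sd=0.3, n=6, seed=5)
        g1 = tukey_hsd(df, "y", "group")
        relabeled = df.assign(group=df.group.map(
            {"g0": "zebra", "g1": "apple", "g2": "mango"}))
        g2 = tukey_hsd(relabeled, "y", "group")
        mapping = {"g0": "zebra", "g1": "apple", "g2": "mango"}
        part1 = {frozenset(mapping[g] for g in grp.split()) for grp in
                 _partition(g1.letters)}
        part2 = {frozenset(grp.split()) for grp in _partition(g2.letters)}
        assert part1 == part2


def _partition(letters):
    """Letter classes as space-joined group sets."""
    classes = {}
    for g, ls in letters.items():
        for ch in ls:
            classes.setdefault(ch, set()).add(g)
    return [" ".join(sorted(v)) for v in classes.values()]


class TestCompactLetterDisplay:
    def test_chain_structure_a_ab_b(self):
        means = {"hi": 10.0, "mid": 5.0, "lo": 0.0}
        p = {frozenset(("hi", "mid")): 0.2,
             frozenset(("mid", "lo")): 0.3,
             frozenset(("hi", "lo")): 0.001}
        letters = compact_letter_display(means, p)
        assert letters == {"hi": "a", "mid": "ab", "lo": "b"}

    def test_validity_on_random_significance_patterns(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            k = int(rng.integers(2, 7))
            names = [f"g{i}" for i in range(k)]
            means = {g: float(rng.normal()) for g in names}
            p = {frozenset((a, b)): float(rng.uniform())
                 for i, a in enumerate(names) for b in names[i + 1:]}
            letters = compact_letter_display(means, p)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    share = bool(set(letters[a]) & set(letters[b]))
                    assert share == (p[frozenset((a, b))] >= 0.05)
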