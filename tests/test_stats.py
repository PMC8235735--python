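"""Marker statistics: filtering, testing, ROC, panels, class roll-ups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kstest, norm

import glycomud as g
from glycomud.stats import _vectorized_ttest


def _matrix(values, groups, entries=None, columns=None):
    idx = [f"s{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=idx, columns=columns)
    df.columns = [str(c) for c in df.columns]
    return g.AbundanceMatrix(
        values=df,
        groups=pd.Series(groups, index=idx),
        detected=df > 0,
        entries=entries or {},
    )


class TestFrequencyFilter:
    def test_boundary_inclusive_at_63_of_90(self):
        vals = np.zeros((90, 2))
        vals[:63, 0] = 1.0  # 63/90 = 0.70 exactly
        vals[:62, 1] = 1.0
        mx = _matrix(vals, ["control"] * 45 + ["cancer"] * 45)
        kept = g.frequency_filter(mx, 0.70)
        assert kept.entry_keys == ["0"]

    def test_zero_threshold_keeps_everything(self, toy_matrix):
        assert g.frequency_filter(toy_matrix, 0.0).entry_keys == toy_matrix.entry_keys

    def test_monotone_in_threshold(self, toy_matrix):
        rng = np.random.default_rng(2)
        mx = toy_matrix
        mx.values.iloc[:, 2] *= rng.random(len(mx.sample_ids)) < 0.5
        mx.detected = mx.values > 0
        kept = [set(g.frequency_filter(mx, t).entry_keys) for t in (0.2, 0.5, 0.8, 1.0)]
        for a, b in zip(kept, kept[1:]):
            assert b <= a

    def test_empty_matrix_rejected(self):
        mx = _matrix(np.empty((0, 0)), [])
        with pytest.raises(ValueError):
            g.frequency_filter(mx, 0.5)


class TestTwoSampleTest:
    def test_identical_groups_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert g.two_sample_test(x, x.copy()) == pytest.approx(1.0)

    def test_complete_separation_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1e-6, 20)
        y = 1 + rng.normal(0, 1e-6, 20)
        assert g.two_sample_test(x, y) < 1e-30

    def test_zero_variance_conventions(self):
        assert g.two_sample_test([5.0, 5.0], [5.0, 5.0]) == 1.0
        assert g.two_sample_test([0.0, 0.0], [1.0, 1.0]) == 0.0

    def test_degenerate_group_size_is_an_error(self):
        with pytest.raises(ValueError):
            g.two_sample_test([1.0], [1.0, 2.0])

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        x, y = rng.lognormal(8, 0.5, 30), rng.lognormal(8.3, 0.5, 25)
        assert g.two_sample_test(x, y) == pytest.approx(g.two_sample_test(y, x))

    def test_null_pvalues_uniform(self):
        # 10,000 simulated null tests: KS against U(0,1) and type-I error
        rng = np.random.default_rng(2024)
        a = rng.lognormal(10, 0.4, size=(45, 10_000))
        b = rng.lognormal(10, 0.4, size=(45, 10_000))
        p = _vectorized_ttest(a, b)
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        assert kstest(p, "uniform").pvalue > 1e-3


class TestSelectMarkers:
    def _stats(self):
        return pd.DataFrame(
            {
                "entry_key": ["a", "b", "c", "d"],
                "p_value": [3.11e-11, 2e-5, 1e-12, 5e-7],
                "frequency": [0.95, 0.95, 0.80, 1.0],
            }
        )

    def test_two_criteria(self):
        assert g.select_markers(self._stats()) == ["a", "d"]

    def test_is_intersection_of_single_criterion_selections(self):
        df = self._stats()
        p_only = set(g.select_markers(df, freq_threshold=0.0))
        f_only = set(g.select_markers(df, p_threshold=1.0))
        assert set(g.select_markers(df)) == p_only & f_only

    def test_p_strict_frequency_inclusive(self):
        df = pd.DataFrame(
            {"entry_key": ["x", "y"], "p_value": [1e-5, 0.99e-5], "frequency": [0.90, 0.90]}
        )
        assert g.select_markers(df) == ["y"]


class TestRocAuc:
    def test_worked_examples(self):
        assert g.roc_auc([1, 2, 3, 4], [False, False, True, True]) == 1.0
        assert g.roc_auc([2, 3, 1, 4], [False, False, True, True]) == 0.5
        assert g.roc_auc([7, 7, 7, 7], [False, True, False, True]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            g.roc_auc([1, 2], [True, True])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30))
    def test_negation_flips_auc(self, scores):
        labels = [i % 2 == 0 for i in range(len(scores))]
        auc = g.roc_auc(scores, labels)
        assert g.roc_auc([-s for s in scores], labels) == pytest.approx(1 - auc)

    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, scores):
        labels = [i % 2 == 0 for i in range(len(scores))]
        auc = g.roc_auc(scores, labels)
        assert g.roc_auc(np.log(scores), labels) == pytest.approx(auc)
        assert g.roc_auc(np.asarray(scores) ** 3, labels) == pytest.approx(auc)


class TestCombinedPanel:
    def test_single_marker_panel_equals_marker_auc(self, toy_matrix):
        key = toy_matrix.entry_keys[0]
        labels = toy_matrix.groups == "cancer"
        marker_auc = g.roc_auc(toy_matrix.values[key], labels)
        model = g.fit_combined_panel(toy_matrix, [key])
        assert model.combined_auc == pytest.approx(marker_auc, abs=1e-12)

    def test_two_binormal_markers_reach_closed_form_auc(self):
        # two independent equal-strength markers: control N(0,1), cancer
        # N(delta,1) each; the optimal combination is the sum, with
        # closed-form AUC Phi(delta) vs Phi(delta/sqrt(2)) individually
        rng = np.random.default_rng(7)
        n, delta = 2000, 1.0
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(delta, 1, (n, 2))])
        mx = _matrix(X, ["control"] * n + ["cancer"] * n)
        model = g.fit_combined_panel(mx, mx.entry_keys)
        assert model.combined_auc == pytest.approx(norm.cdf(delta), abs=0.03)
        assert not model.separation_fallback

    def test_null_weight_marker_leaves_auc_unchanged(self, toy_matrix):
        key = toy_matrix.entry_keys[0]
        labels = toy_matrix.groups == "cancer"
        base = g.fit_combined_panel(toy_matrix, [key]).combined_auc
        # append a constant column: its standardised coefficient is 0
        toy_matrix.values["GP1:null"] = 1.0
        toy_matrix.detected["GP1:null"] = True
        got = g.fit_combined_panel(toy_matrix, [key, "GP1:null"]).combined_auc
        assert got == pytest.approx(base, abs=1e-9)

    def test_perfect_separation_uses_flagged_fallback(self):
        vals = np.vstack([np.full((10, 1), 1.0), np.full((10, 1), 100.0)])
        rng = np.random.default_rng(1)
        vals = vals + rng.normal(0, 1e-3, vals.shape)
        mx = _matrix(vals, ["control"] * 10 + ["cancer"] * 10)
        model = g.fit_combined_panel(mx, mx.entry_keys)
        assert model.separation_fallback
        assert model.combined_auc == 1.0


class TestClassSummaries:
    def _classified_matrix(self, scale_cancer=2.0):
        lib = g.make_fixture_library(6, 1, 1, seed=13)
        rng = np.random.default_rng(4)
        keys = [e.key for e in lib.entries]
        vals = rng.lognormal(8, 0.1, size=(20, len(keys)))
        vals[10:] *= scale_cancer
        return _matrix(
            vals, ["control"] * 10 + ["cancer"] * 10,
            entries={e.key: e for e in lib.entries}, columns=keys,
        ), lib

    def test_exact_doubling_gives_log2fc_one(self):
        mx, _ = self._classified_matrix(scale_cancer=2.0)
        # force exact doubling: cancer rows are exactly 2x control rows
        mx.values.iloc[10:] = 2 * mx.values.iloc[:10].to_numpy()
        summary, _ = g.class_summaries(mx)
        fc = summary.dropna(subset=["log2fc"])
        assert np.allclose(fc["log2fc"], 1.0)

    def test_swapping_labels_negates_log2fc(self):
        mx, _ = self._classified_matrix()
        s1, _ = g.class_summaries(mx, positive_group="cancer")
        s2, _ = g.class_summaries(mx, positive_group="control")
        a = s1.dropna(subset=["log2fc"]).set_index(["group", "glycan_class"])["log2fc"]
        b = s2.dropna(subset=["log2fc"]).set_index(["group", "glycan_class"])["log2fc"]
        assert np.allclose(a, -b.loc[a.index])

    def test_relative_abundances_sum_to_one(self):
        mx, _ = self._classified_matrix()
        _, rel = g.class_summaries(mx)
        for gp in rel.columns.get_level_values(0).unique():
            assert np.allclose(rel[gp].sum(axis=1), 1.0)

    def test_zero_control_mean_flagged_undefined(self):
        mx, lib = self._classified_matrix()
        cls = g.classify_glycan(lib.entries[0].total_composition).value
        members = [
            e.key for e in lib.entries
            if g.classify_glycan(e.total_composition).value == cls
        ]
        mx.values.loc[mx.groups == "control", members] = 0.0
        summary, _ = g.class_summaries(mx)
        row = summary[(summary["group"] == "GP1") & (summary["glycan_class"] == cls)]
        assert not row["fold_defined"].item()
        assert np.isnan(row["log2fc"].item())


class TestSiteMapReport:
    def test_tiers_and_ranking(self):
        profile = pd.Series(
            {
                "GP1:major": 55.0,
                "GP1:mid": 30.0,
                "GP1:one_pct": 1.0,
                "GP1:tiny": 0.5,
                "GP1:rest": 13.5,
            }
        )
        out = g.site_map_report(profile)
        tiers = out.set_index("entry_key")["tier"]
        assert tiers["GP1:major"] == ">10%"
        assert tiers["GP1:one_pct"] == "1-10%"  # boundary inclusive upward
        assert tiers["GP1:tiny"] == "<1%"
        assert list(out["rank"]) == [1, 2, 3, 4, 5]

    def test_small_group_lists_all_members(self):
        profile = pd.Series({"GP2:a": 3.0, "GP2:b": 2.0, "GP2:c": 1.0})
        assert len(g.site_map_report(profile, top_n=10)) == 3

    def test_top_n_cap(self):
        profile = pd.Series({f"GP1:{i}": float(i) for i in range(15)})
        assert len(g.site_map_report(profile, top_n=10)) == 10
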