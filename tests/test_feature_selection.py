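"""Closed-form oracles and properties of the four-selector nexus."""

import numpy as np
import pytest
from scipy import stats

from cigtml import (
    EmptySelectionError,
    SelectorResult,
    anova_select,
    chi2_select,
    combine_selections,
    pearson_select,
    rfe_select,
)
from cigtml.select import apply_bh, default_n_keep

from conftest import make_dataset


def _result(selector, selected, names=("a", "b", "c", "d")):
    return SelectorResult(
        selector=selector,
        feature_names=tuple(names),
        statistic=np.zeros(len(names)),
        p_value=np.zeros(len(names)),
        rank=None,
        selected=frozenset(selected),
    )


class TestPearson:
    def test_feature_identical_to_label_is_perfect(self):
        ds = make_dataset(
            np.column_stack([[0, 0, 1, 1], [5, 1, 3, 2]]), [0, 0, 1, 1]
        )
        res = pearson_select(ds, alpha=0.05)
        assert res.statistic[0] == pytest.approx(1.0)
        assert "f0" in res.selected

    def test_hand_computed_point_biserial(self):
        # r = cov(x, y) / (sd_x sd_y) for x=[1,2,3,4], y=[0,0,1,1] = 0.894427...
        ds = make_dataset(np.array([[1.0], [2.0], [3.0], [4.0]]), [0, 0, 1, 1])
        res = pearson_select(ds, alpha=0.05)
        assert res.statistic[0] == pytest.approx(0.8944271909999159, abs=1e-12)
        # cross-check p against scipy's point-biserial implementation
        r_sp, p_sp = stats.pointbiserialr([0, 0, 1, 1], [1, 2, 3, 4])
        assert res.statistic[0] == pytest.approx(r_sp)
        assert res.p_value[0] == pytest.approx(p_sp)

    def test_too_few_samples(self):
        ds = make_dataset(np.array([[1.0], [2.0]]), [0, 1])
        with pytest.raises(ValueError, match=">=3"):
            pearson_select(ds)


class TestChi2:
    @staticmethod
    def _binary_cohort(low_high_class0, low_high_class1):
        """Cohort whose pooled-mean split yields the given low/high counts."""
        values, labels = [], []
        for cls, (lo, hi) in enumerate([low_high_class0, low_high_class1]):
            values += [0.0] * lo + [1.0] * hi
            labels += [cls] * (lo + hi)
        extra = np.linspace(10, 11, len(labels))  # second, irrelevant feature
        return make_dataset(np.column_stack([values, extra]), labels)

    def test_contingency_oracle_6_67(self):
        # table [[20,10],[10,20]]: expected 15 per cell, sum (o-e)^2/e = 6.667
        ds = self._binary_cohort((20, 10), (10, 20))
        res = chi2_select(ds, alpha=0.05)
        assert res.statistic[0] == pytest.approx(20 / 3, abs=1e-9)
        # independent oracle: scipy contingency test without correction
        chi_sp = stats.chi2_contingency(
            [[20, 10], [10, 20]], correction=False
        )
        assert res.statistic[0] == pytest.approx(chi_sp[0])
        assert res.p_value[0] == pytest.approx(chi_sp[1])
        assert "f0" in res.selected

    def test_homogeneous_table_scores_zero(self):
        ds = self._binary_cohort((10, 10), (10, 10))
        res = chi2_select(ds, alpha=0.05)
        assert res.statistic[0] == pytest.approx(0.0)
        assert "f0" not in res.selected

    def test_constant_feature_excluded_with_warning(self, caplog):
        vals = np.column_stack([np.ones(8), np.arange(8.0)])
        ds = make_dataset(vals, [0, 1] * 4)
        with caplog.at_level("WARNING"):
            res = chi2_select(ds)
        assert "f0" in res.excluded
        assert np.isnan(res.statistic[0])
        assert any("zero-variance" in r.message for r in caplog.records)


class TestAnova:
    def test_toy_f_statistic(self):
        # cases [1,2,3] vs controls [2,3,4]: SSB=1.5, SSW=4 over 4 df -> F=1.5
        ds = make_dataset(
            np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]]),
            [1, 1, 1, 0, 0, 0],
        )
        res = anova_select(ds, alpha=0.05)
        assert res.statistic[0] == pytest.approx(1.5, abs=1e-12)

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(30, 6)), rng.integers(0, 2, 30))
        res = anova_select(ds)
        t, _ = stats.ttest_ind(
            ds.values[ds.labels == 1], ds.values[ds.labels == 0], equal_var=True
        )
        np.testing.assert_allclose(res.statistic, t**2, atol=1e-9)

    def test_single_sample_group_rejected(self):
        ds = make_dataset(np.arange(6.0).reshape(3, 2), [0, 0, 1])
        with pytest.raises(ValueError, match="<2 samples"):
            anova_select(ds)


class TestRFE:
    def test_keep_all_means_all_rank_one(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(20, 4)), [0, 1] * 10)
        res = rfe_select(ds, n_keep=4, seed=0)
        assert set(res.rank) == {1}
        assert res.selected == frozenset(ds.feature_names)

    def test_rank_is_permutation_with_kept_ties(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(size=(24, 5)), [0, 1] * 12)
        res = rfe_select(ds, n_keep=2, seed=0)
        assert sorted(res.rank) == [1, 1, 2, 3, 4]

    def test_determinism(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(size=(30, 6)), [0, 1] * 15)
        r1 = rfe_select(ds, n_keep=2, seed=5)
        r2 = rfe_select(ds, n_keep=2, seed=5)
        np.testing.assert_array_equal(r1.rank, r2.rank)

    def test_recovers_planted_genes(self, benchmark_cohort):
        ds, truth = benchmark_cohort
        res = rfe_select(ds, n_keep=5, seed=0)
        assert len(res.selected & set(truth.informative_genes)) >= 4

    @pytest.mark.parametrize("n_keep", [0, 51])
    def test_n_keep_bounds(self, benchmark_cohort, n_keep):
        ds, _ = benchmark_cohort
        with pytest.raises(ValueError):
            rfe_select(ds, n_keep=n_keep)

    def test_default_fraction_rule(self):
        assert default_n_keep(50) == 5
        assert default_n_keep(3) == 1


class TestCombine:
    def test_union_in_column_order(self):
        fs = combine_selections(
            [_result("pearson", {"a", "b"}), _result("anova", {"b", "c"})],
            feature_order=["a", "b", "c", "d"],
            mode="union",
        )
        assert fs.features == ("a", "b", "c")
        assert fs.provenance["b"] == frozenset({"pearson", "anova"})

    def test_intersection(self):
        fs = combine_selections(
            [_result("pearson", {"a", "b"}), _result("anova", {"b", "c"})],
            feature_order=["a", "b", "c", "d"],
            mode="intersection",
        )
        assert fs.features == ("b",)

    def test_vote_k(self):
        fs = combine_selections(
            [
                _result("pearson", {"a", "b"}),
                _result("anova", {"b", "c"}),
                _result("chi2", {"b", "d"}),
            ],
            feature_order=["a", "b", "c", "d"],
            mode="vote_k",
            vote_k=2,
        )
        assert fs.features == ("b",)

    def test_empty_combination_raises_with_advice(self):
        with pytest.raises(EmptySelectionError, match="relax alpha"):
            combine_selections(
                [_result("pearson", set()), _result("anova", {"c"})],
                feature_order=["a", "b", "c", "d"],
                mode="intersection",
            )

    def test_force_include(self):
        fs = combine_selections(
            [_result("pearson", {"a"})],
            feature_order=["a", "b", "c", "d"],
            mode="union",
            force_include=["d"],
        )
        assert fs.features == ("a", "d")


def test_selectors_invariant_to_column_order():
    rng = np.random.default_rng(6)
    values = rng.normal(size=(40, 5))
    labels = rng.integers(0, 2, 40)
    labels[:3] = [0, 1, 0]  # guarantee both classes
    ds = make_dataset(values, labels)
    perm = [3, 0, 4, 1, 2]
    ds_perm = make_dataset(
        values[:, perm], labels, names=[f"f{j}" for j in perm]
    )
    for select in (pearson_select, chi2_select, anova_select):
        base = select(ds)
        permuted = select(ds_perm)
        for j, orig in enumerate(perm):
            assert permuted.statistic[j] == pytest.approx(base.statistic[orig])
        assert permuted.selected == base.selected


def test_bh_correction_is_more_conservative():
    rng = np.random.default_rng(8)
    values = rng.normal(size=(60, 30))
    labels = np.r_[np.ones(30, int), np.zeros(30, int)]
    values[labels == 1, 0] += 2.0
    ds = make_dataset(values, labels)
    raw = pearson_select(ds, alpha=0.2)
    corrected = apply_bh(raw, alpha=0.2)
    assert corrected.selected <= raw.selected
    assert "f0" in corrected.selected
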