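"""I-Gene scoring: shares, HHI weighting, conservation, directionality."""

import numpy as np
import pytest

from cigtml import classifier_weights, hhi, igene_scores, importance_shares
from cigtml.attribution import AttributionMatrix
from cigtml.scoring import (
    NEUTRAL,
    OVEREXPRESSED,
    UNDEREXPRESSED,
    DegenerateAttributionError,
    direction,
)
from cigtml.simulate import UP


def _att(phi, name="clf"):
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    return AttributionMatrix(classifier=name, phi=phi, baseline=np.zeros(len(phi)))


class TestShares:
    def test_normalizes_mean_abs(self):
        # one sample with |phi| = (2, 1, 1) -> shares (0.5, 0.25, 0.25)
        shares = importance_shares(_att([[2.0, -1.0, 1.0]]))
        np.testing.assert_allclose(shares, [0.5, 0.25, 0.25])

    def test_single_feature_share_is_one(self):
        np.testing.assert_allclose(importance_shares(_att([[3.0], [1.0]])), [1.0])

    def test_constant_model_degenerate(self):
        assert importance_shares(_att([[0.0, 0.0]])) is None


class TestHHI:
    @pytest.mark.parametrize(
        "shares,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.25),  # uniform -> 1/n
            ([1.0, 0.0, 0.0], 1.0),  # monopoly
            ([0.5, 0.3, 0.2], 0.38),  # 0.25 + 0.09 + 0.04
        ],
    )
    def test_oracles(self, shares, expected):
        assert hhi(shares) == pytest.approx(expected, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            hhi([0.5, 0.4])

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            hhi([1.5, -0.5])


class TestWeights:
    def test_proportional_to_hhi(self):
        w = classifier_weights({"a": 0.38, "b": 0.62})
        assert w == pytest.approx({"a": 0.38, "b": 0.62})

    def test_single_classifier(self):
        assert classifier_weights({"only": 0.41}) == {"only": 1.0}

    def test_symmetry(self):
        w = classifier_weights({f"c{i}": 0.3 for i in range(5)})
        assert all(v == pytest.approx(0.2) for v in w.values())

    def test_monotone_in_hhi(self):
        w = classifier_weights({"lo": 0.2, "mid": 0.5, "hi": 0.9})
        assert w["lo"] < w["mid"] < w["hi"]

    def test_all_degenerate_is_an_error(self):
        with pytest.raises(DegenerateAttributionError):
            classifier_weights({})


class TestScores:
    def test_single_classifier_identity(self):
        raw, disp = igene_scores(
            {"c": np.array([0.5, 0.25, 0.25])}, {"c": 1.0}
        )
        np.testing.assert_allclose(raw, [0.5, 0.25, 0.25])
        np.testing.assert_allclose(disp, [100.0, 50.0, 50.0])

    def test_two_classifier_weighted_sum(self):
        raw, disp = igene_scores(
            {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])},
            {"a": 0.5, "b": 0.5},
        )
        np.testing.assert_allclose(raw, [0.5, 0.5])
        np.testing.assert_allclose(disp, [100.0, 100.0])

    def test_conservation_raw_sums_to_one(self):
        rng = np.random.default_rng(0)
        shares = {}
        for name in ("a", "b", "c"):
            s = rng.uniform(size=6)
            shares[name] = s / s.sum()
        hhis = {name: hhi(s) for name, s in shares.items()}
        raw, _ = igene_scores(shares, classifier_weights(hhis))
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_classifier_set_mismatch(self):
        with pytest.raises(ValueError, match="classifier sets differ"):
            igene_scores({"a": np.array([1.0])}, {"b": 1.0})


class TestDirection:
    def test_zero_attributions_are_neutral(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        labels, stat = direction(
            {"c": _att(np.zeros((20, 2)))}, X, None, {"c": 1.0}
        )
        assert labels == [NEUTRAL, NEUTRAL]
        np.testing.assert_allclose(stat, 0.0)

    def test_positive_and_negative_coupling(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2))
        phi = np.column_stack([X[:, 0], -X[:, 1]])  # up-coupled, down-coupled
        labels, _ = direction({"c": _att(phi)}, X, None, {"c": 1.0})
        assert labels == [OVEREXPRESSED, UNDEREXPRESSED]

    def test_zero_variance_feature_neutral_with_warning(self, caplog):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        phi = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with caplog.at_level("WARNING"):
            labels, _ = direction({"c": _att(phi)}, X, None, {"c": 1.0})
        assert labels[0] == NEUTRAL
        assert any("zero variance" in r.message for r in caplog.records)

    def test_positive_mean_compare_variant(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        x = rng.normal(size=80) + 1.5 * y  # higher in cases
        X = x[:, None]
        phi = (x - x.mean())[:, None]  # high values push toward case
        labels, stat = direction(
            {"c": _att(phi)}, X, y, {"c": 1.0}, method="positive_mean_compare"
        )
        assert labels == [OVEREXPRESSED]
        assert stat[0] > 0


class TestProfileOnBenchmark:
    def test_planted_genes_lead_the_ranking(self, fitted):
        profile, truth = fitted["profile"], fitted["truth"]
        top = set(profile.table.nsmallest(10, "rank")["feature"])
        assert set(truth.informative_genes) <= top

    def test_directions_match_ground_truth(self, fitted):
        profile, truth = fitted["profile"], fitted["truth"]
        by_feature = profile.table.set_index("feature")["direction"]
        for gene, d in truth.directions.items():
            expected = OVEREXPRESSED if d == UP else UNDEREXPRESSED
            assert by_feature[gene] == expected, gene

    def test_profile_invariants(self, fitted):
        profile = fitted["profile"]
        t = profile.table
        assert t["raw_score"].sum() == pytest.approx(1.0, abs=1e-9)
        assert t["igene_score"].max() == pytest.approx(100.0)
        assert sorted(t["rank"]) == list(range(1, len(t) + 1))
        assert sum(profile.weights.values()) == pytest.approx(1.0, abs=1e-12)
        for name in profile.weights:
            assert t[f"share_{name}"].sum() == pytest.approx(1.0, abs=1e-9)
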