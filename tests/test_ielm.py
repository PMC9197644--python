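"""The imbalance-aware boosted ensemble: weight bookkeeping and behaviour."""

import numpy as np
import pytest

from ielm.boosting import round_coefficient, update_sample_weights, weighted_error
from ielm.elm import ELM
from ielm.ensemble import (
    IELM,
    IELMResults,
    ensemble_coefficient,
    imbalance_ratio,
    initial_weight_distribution,
    label_class_coefficient,
    label_class_error,
    update_weight_distribution,
)
from ielm.synthetic import generate_feature_dataset, split_table


def one_hot(y, k):
    return np.eye(k, dtype=int)[np.asarray(y)]


class TestImbalanceRatio:
    @pytest.mark.parametrize(
        "pos,neg,expected", [(5, 5, 1.0), (9, 1, 9.0), (2, 8, 4.0)]
    )
    def test_ratio_examples(self, pos, neg, expected):
        Y = np.array([[1]] * pos + [[0]] * neg)
        assert imbalance_ratio(Y, 0) == expected

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="label 0"):
            imbalance_ratio(np.ones((4, 1), dtype=int), 0)


class TestInitialWeights:
    def test_balanced_single_label_uniform_eighth(self):
        Y = np.array([[1]] * 4 + [[0]] * 4)
        W = initial_weight_distribution(Y)
        np.testing.assert_allclose(W, 0.125)

    def test_imbalanced_single_label_hand_values(self):
        # 2 positive / 8 negative: each positive 1/4, each negative 1/16
        Y = np.array([[1]] * 2 + [[0]] * 8)
        W = initial_weight_distribution(Y)
        np.testing.assert_allclose(W[:2, 0], 0.25, atol=1e-15)
        np.testing.assert_allclose(W[2:, 0], 1.0 / 16.0, atol=1e-15)

    def test_grand_total_is_one(self, rng):
        y = rng.integers(0, 3, 60)
        W = initial_weight_distribution(one_hot(y, 3))
        assert W.sum() == pytest.approx(1.0, abs=1e-12)

    def test_minority_sample_weight_grows_with_imbalance(self):
        for npos in (4, 2, 1):
            Y = np.array([[1]] * npos + [[0]] * (10 - npos))
            W = initial_weight_distribution(Y)
            assert W[0, 0] >= W[-1, 0]  # minority sample never lighter
        # heavier imbalance -> heavier minority sample
        w_mild = initial_weight_distribution(np.array([[1]] * 4 + [[0]] * 6))[0, 0]
        w_hard = initial_weight_distribution(np.array([[1]] * 1 + [[0]] * 9))[0, 0]
        assert w_hard > w_mild


class TestBlockArithmetic:
    @staticmethod
    def _fixture():
        # q=1, 2 positives + 4 negatives, 2 of the negatives wrong
        Y = np.array([[1]] * 2 + [[0]] * 4)
        W = initial_weight_distribution(Y)
        correct = np.array([[1], [1], [1], [1], [0], [0]], dtype=bool)
        return Y, W, correct

    def test_all_correct_block_error_zero(self):
        Y, W, _ = self._fixture()
        correct = np.ones((6, 1), dtype=bool)
        assert label_class_error(correct, Y, W, 0, 1) == 0.0

    def test_all_wrong_block_error_is_block_mass(self):
        Y, W, _ = self._fixture()
        correct = np.zeros((6, 1), dtype=bool)
        assert label_class_error(correct, Y, W, 0, 0) == pytest.approx(0.5, abs=1e-12)

    def test_error_matches_direct_summation(self):
        Y, W, correct = self._fixture()
        # negatives are uniform at 1/8 each; two wrong -> 1/4
        assert label_class_error(correct, Y, W, 0, 0) == pytest.approx(0.25, abs=1e-12)

    def test_coefficient_balanced_block_is_zero(self):
        Y, W, correct = self._fixture()
        # negative block: half the mass correct, half wrong
        assert label_class_coefficient(correct, Y, W, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_coefficient_inverts_exp2_mass_ratio(self):
        Y = np.array([[0]] * 10)
        Y[0, 0] = 1  # keep the positive block nonempty elsewhere
        Y = np.vstack([np.ones((1, 1), int), np.zeros((9, 1), int)])
        W = np.zeros((10, 1))
        W[0, 0] = 0.5  # positive block
        wrong_mass = 0.5 / (1.0 + np.e**2)
        W[1, 0] = wrong_mass
        W[2:, 0] = (0.5 - wrong_mass) / 8.0
        correct = np.ones((10, 1), dtype=bool)
        correct[1, 0] = False
        assert label_class_coefficient(correct, Y, W, 0, 0) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_round_hits_clip_ceiling(self):
        # a perfect block's wrong mass clips to 1e-10, so the coefficient
        # saturates at (1/2) ln(block mass / 1e-10); with q=1 each block
        # carries mass 1/2 and the whole distribution mass 1
        Y, W, _ = self._fixture()
        correct = np.ones((6, 1), dtype=bool)
        assert label_class_coefficient(correct, Y, W, 0, 1) == pytest.approx(
            0.5 * np.log(0.5 / 1e-10)
        )
        assert ensemble_coefficient(correct, W) == pytest.approx(
            0.5 * np.log(1.0 / 1e-10)
        )

    def test_half_correct_total_mass_gives_zero(self):
        Y, W, correct = self._fixture()
        # correct mass: both positives (0.5) + two negatives (0.25) = 0.75
        # build a pattern with exactly half the mass correct instead
        correct = np.array([[1], [0], [1], [1], [0], [0]], dtype=bool)
        assert ensemble_coefficient(correct, W) == pytest.approx(0.0, abs=1e-12)


class TestWeightUpdate:
    def test_zero_coefficients_leave_distribution_unchanged(self, rng):
        y = rng.integers(0, 3, 30)
        Y = one_hot(y, 3)
        W = initial_weight_distribution(Y)
        correct = rng.integers(0, 2, (30, 3)).astype(bool)
        out = update_weight_distribution(W, np.zeros((3, 2)), correct, Y)
        np.testing.assert_allclose(out, W, atol=1e-15)

    def test_blocks_conserved_after_update(self, rng):
        y = rng.integers(0, 3, 40)
        Y = one_hot(y, 3)
        q = 3
        W = initial_weight_distribution(Y)
        for _ in range(5):
            correct = rng.integers(0, 2, (40, 3)).astype(bool)
            coefs = rng.normal(0, 1, (3, 2))
            W = update_weight_distribution(W, coefs, correct, Y)
            for l in range(q):
                for side in (0, 1):
                    block = W[Y[:, l] == side, l].sum()
                    assert block == pytest.approx(1.0 / (2 * q), abs=1e-12)
            assert W.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_label_update_matches_classic_adaboost_within_blocks(self, rng):
        # q=1: within each (side) block the relative weights after the update
        # must match classic AdaBoost's relative weights
        Y = np.array([[1]] * 3 + [[0]] * 3)
        W = initial_weight_distribution(Y)
        correct = np.array([[1], [0], [1], [1], [0], [1]], dtype=bool)
        pred = np.where(correct[:, 0], Y[:, 0], 1 - Y[:, 0])
        eps = weighted_error(pred, Y[:, 0], W[:, 0])
        sigma = round_coefficient(eps)
        classic = update_sample_weights(W[:, 0], sigma, pred, Y[:, 0])
        ours = update_weight_distribution(
            W, np.array([[sigma, sigma]]), correct, Y
        )[:, 0]
        for side in (0, 1):
            blk = Y[:, 0] == side
            np.testing.assert_allclose(
                ours[blk] / ours[blk].sum(),
                classic[blk] / classic[blk].sum(),
                atol=1e-12,
            )

    def test_ensemble_coefficient_equals_adaboost_coefficient_q1(self, rng):
        # q=1 cross-oracle identity: sigma = 1/2 ln((1-eps)/eps)
        Y = np.array([[1]] * 4 + [[0]] * 6)
        W = initial_weight_distribution(Y)
        correct = rng.integers(0, 2, (10, 1)).astype(bool)
        pred = np.where(correct[:, 0], Y[:, 0], 1 - Y[:, 0])
        eps = weighted_error(pred, Y[:, 0], W[:, 0])
        assert ensemble_coefficient(correct, W) == pytest.approx(
            round_coefficient(eps), abs=1e-12
        )


class TestIELMModel:
    def test_single_round_balanced_two_class_equals_plain_elm(self, rng):
        X = rng.standard_normal((40, 4))
        y = np.array(["a", "b"] * 20)
        ielm = IELM(X, y, n_rounds=1, n_hidden=20, seed=5).fit()
        elm = ELM(X, y, n_hidden=20, seed=5).fit()
        Xq = rng.standard_normal((30, 4))
        np.testing.assert_array_equal(ielm.predict(Xq), elm.predict(Xq))

    def test_separable_three_class_training_accuracy_one(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in (0.0, 3.0, 6.0)])
        X = (X - X.min()) / np.ptp(X)
        y = np.repeat(["low", "moderate", "high"], 20)
        res = IELM(X, y, n_rounds=5, n_hidden=80, seed=2).fit()
        assert (res.predict(X) == y).mean() == 1.0

    def test_minority_recall_beats_plain_elm_on_imbalanced_data(self):
        wins = 0
        for seed in range(10):
            table = generate_feature_dataset(
                500, proportions=(0.42, 0.46, 0.12), separation=1.5, seed=seed
            )
            train, test = split_table(table, seed=seed)
            from ielm.features import scale_feature_tables

            train, test = scale_feature_tables(train, test)
            Xte = test.drop(columns=["label"]).to_numpy()
            yte = test["label"].to_numpy()
            ielm = IELM.from_dataframe(train, n_rounds=10, seed=seed).fit()
            elm = ELM.from_dataframe(train, seed=seed).fit()
            rec = {
                name: (res.predict(Xte)[yte == "high"] == "high").mean()
                for name, res in (("ielm", ielm), ("elm", elm))
            }
            wins += rec["ielm"] >= rec["elm"]
        assert wins >= 8

    def test_prediction_equivariant_under_class_relabelling(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.choice(["a", "b", "c"], 60)
        mapping = {"a": "x", "b": "y", "c": "z"}  # preserves sort order
        pred1 = IELM(X, y, n_rounds=3, n_hidden=30, seed=8).fit().predict(X)
        y2 = np.array([mapping[v] for v in y])
        pred2 = IELM(X, y2, n_rounds=3, n_hidden=30, seed=8).fit().predict(X)
        np.testing.assert_array_equal(np.array([mapping[v] for v in pred1]), pred2)

    def test_two_rounds_zero_second_coefficient_ignores_it(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array(["a", "b", "c"] * 10)
        res = IELM(X, y, n_rounds=2, n_hidden=15, seed=3).fit()
        if len(res.rounds) == 2:
            res.rounds[1].coefficient = 0.0
            single = IELMResults(res.model, res.rounds[:1], [])
            np.testing.assert_array_equal(res.predict(X), single.predict(X))

    def test_weight_history_blocks_conserved_through_fit(self, imbalanced_table):
        from ielm.features import scale_feature_tables

        (train,) = scale_feature_tables(imbalanced_table)
        model = IELM.from_dataframe(train, n_rounds=4, n_hidden=40, seed=1)
        res = model.fit()
        Y = model._one_hot()
        q = Y.shape[1]
        for W in res.weight_history:
            assert W.sum() == pytest.approx(1.0, abs=1e-12)
            for l in range(q):
                for side in (0, 1):
                    assert W[Y[:, l] == side, l].sum() == pytest.approx(
                        1.0 / (2 * q), abs=1e-12
                    )

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((30, 4))
        y = rng.choice(["low", "moderate", "high"], 30)
        res = IELM(X, y, n_rounds=3, n_hidden=10, seed=0).fit()
        res.save(tmp_path / "ens.json")
        back = IELMResults.load(tmp_path / "ens.json")
        Xq = rng.standard_normal((7, 4))
        np.testing.assert_array_equal(back.predict(Xq), res.predict(Xq))
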