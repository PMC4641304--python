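import numpy as np
import pytest

from conftest import make_features
from oracles import src_reference_predict
from seqppi import wsrc
from seqppi.features import PairFeature


class TestFit:
    def test_columns_are_unit_norm(self, feature_factory):
        model = wsrc.fit(feature_factory(4))
        np.testing.assert_allclose(np.linalg.norm(model.train_matrix, axis=0), 1.0)

    def test_default_hyperparameters(self, feature_factory):
        model = wsrc.fit(feature_factory(4))
        assert model.sigma == 1.5
        assert model.epsilon == 0.00005

    def test_zero_vector_rejected_naming_pair(self, feature_factory):
        feats = feature_factory(4)
        feats[2] = PairFeature(np.zeros(8), ("zp", "zq"), 0)
        with pytest.raises(ValueError, match="zp"):
            wsrc.fit(feats)

    def test_single_class_rejected(self, rng):
        feats = make_features(rng, 4, n_classes=1)
        with pytest.raises(ValueError, match="single class"):
            wsrc.fit(feats)

    def test_inconsistent_lengths_rejected(self, feature_factory):
        feats = feature_factory(3) + make_features(np.random.default_rng(0), 1, dim=5)
        with pytest.raises(ValueError, match="length"):
            wsrc.fit(feats)

    @pytest.mark.parametrize("kw", [{"sigma": 0.0}, {"epsilon": -1.0}, {"weight_mode": "x"}])
    def test_invalid_hyperparameters(self, kw, feature_factory):
        with pytest.raises(ValueError):
            wsrc.fit(feature_factory(4), **kw)


class TestGaussianDistance:
    def test_identical_vectors_give_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert wsrc.gaussian_distance(x, x, 1.5) == 1.0

    def test_squared_distance_two_sigma_squared_gives_inverse_e(self):
        sigma = 0.7
        x = np.zeros(1)
        y = np.array([np.sqrt(2.0) * sigma])
        assert wsrc.gaussian_distance(x, y, sigma) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_hand_evaluated_example(self):
        value = wsrc.gaussian_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.5)
        assert value == pytest.approx(np.exp(-2.0 / 4.5), rel=1e-12)
        assert value == pytest.approx(0.641180, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wsrc.gaussian_distance(np.ones(2), np.ones(3), 1.0)


class TestLocalityWeights:
    def test_training_column_has_minimal_weight_one(self, feature_factory):
        model = wsrc.fit(feature_factory(6))
        y = model.train_matrix[:, 2]
        weights = wsrc.locality_weights(model, y)
        assert weights[2] == pytest.approx(1.0, rel=1e-12)
        assert np.all(weights >= 1.0 - 1e-12)
        assert np.argmin(weights) == 2

    def test_reciprocal_of_similarity(self, feature_factory):
        model = wsrc.fit(feature_factory(5))
        y = np.ones(8) / np.sqrt(8)
        weights = wsrc.locality_weights(model, y)
        sims = np.array(
            [wsrc.gaussian_distance(y, model.train_matrix[:, i], model.sigma) for i in range(5)]
        )
        np.testing.assert_allclose(weights, 1.0 / sims, rtol=1e-12)

    def test_similarity_mode_inverts(self, feature_factory):
        feats = feature_factory(5)
        model = wsrc.fit(feats, weight_mode="similarity")
        y = np.ones(8) / np.sqrt(8)
        weights = wsrc.locality_weights(model, y)
        assert np.all(weights <= 1.0)

    def test_large_sigma_degenerates_to_unit_weights(self, feature_factory):
        model = wsrc.fit(feature_factory(5), sigma=1e9)
        weights = wsrc.locality_weights(model, np.ones(8))
        np.testing.assert_allclose(weights, 1.0, rtol=1e-9)


class TestPredict:
    def test_memorized_sample_assigned_its_class(self, rng):
        V = rng.standard_normal((20, 10))
        feats = [PairFeature(V[:, i], (f"a{i}", f"b{i}"), int(i >= 5)) for i in range(10)]
        model = wsrc.fit(feats)
        pred = wsrc.predict(model, V[:, 7])
        assert pred.predicted_class == 1
        assert pred.residuals.min() < 1e-6

    def test_orthogonal_class_subspaces(self, rng):
        """Class atoms span disjoint coordinate blocks; membership is exact."""
        dim = 8
        feats = []
        for i in range(4):  # class 0 lives in coordinates 0..3
            v = np.zeros(dim)
            v[:4] = rng.standard_normal(4)
            feats.append(PairFeature(v, (f"a{i}", f"b{i}"), 0))
        for i in range(4):  # class 1 lives in coordinates 4..7
            v = np.zeros(dim)
            v[4:] = rng.standard_normal(4)
            feats.append(PairFeature(v, (f"c{i}", f"d{i}"), 1))
        model = wsrc.fit(feats, epsilon=1e-6)
        y = np.zeros(dim)
        y[:4] = rng.standard_normal(4)
        pred = wsrc.predict(model, y)
        assert pred.predicted_class == 0
        # direct least-squares residuals per class agree with the rule
        r0 = np.linalg.norm(
            y / np.linalg.norm(y)
            - model.train_matrix[:, :4]
            @ np.linalg.lstsq(model.train_matrix[:, :4], y / np.linalg.norm(y), rcond=None)[0]
        )
        assert pred.residuals[0] == pytest.approx(r0, abs=1e-6)
        assert pred.residuals[1] == pytest.approx(1.0, abs=1e-9)  # orthogonal class

    def test_score_sign_matches_decision(self, rng):
        for _ in range(10):
            feats = make_features(rng, 12, dim=6)
            model = wsrc.fit(feats, epsilon=1e-3)
            pred = wsrc.predict(model, rng.standard_normal(6))
            if pred.score > 0:
                assert pred.predicted_class == 1
            else:  # ties go to the smaller class label
                assert pred.predicted_class == 0

    def test_scale_invariance(self, rng):
        feats = make_features(rng, 10, dim=6)
        model = wsrc.fit(feats)
        y = rng.standard_normal(6)
        p1 = wsrc.predict(model, y)
        p2 = wsrc.predict(model, 37.5 * y)
        assert p1.predicted_class == p2.predicted_class
        np.testing.assert_allclose(p1.residuals, p2.residuals, rtol=1e-9)

    def test_permutation_invariance(self, rng):
        feats = make_features(rng, 12, dim=6)
        model = wsrc.fit(feats, epsilon=1e-3)
        y = rng.standard_normal(6)
        base = wsrc.predict(model, y)
        perm = rng.permutation(12)
        model_p = wsrc.fit([feats[i] for i in perm], epsilon=1e-3)
        assert wsrc.predict(model_p, y).predicted_class == base.predicted_class

    def test_sigma_infinity_matches_unweighted_src(self, rng):
        """Unit weights reduce WSRC to plain sparse-representation SRC."""
        for _ in range(5):
            V = rng.standard_normal((6, 14))
            labels = np.arange(14) % 2
            feats = [PairFeature(V[:, i], (f"a{i}", f"b{i}"), int(labels[i])) for i in range(14)]
            model = wsrc.fit(feats, sigma=1e9, epsilon=1e-3)
            y = rng.standard_normal(6)
            ref = src_reference_predict(model.train_matrix, model.labels, y, 1e-3)
            assert wsrc.predict(model, y).predicted_class == ref

    def test_zero_vector_rejected(self, feature_factory):
        model = wsrc.fit(feature_factory(4))
        with pytest.raises(ValueError, match="zero"):
            wsrc.predict(model, np.zeros(8))

    def test_wrong_dimension_rejected(self, feature_factory):
        model = wsrc.fit(feature_factory(4))
        with pytest.raises(ValueError, match="length"):
            wsrc.predict(model, np.ones(9))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, feature_factory, rng):
        model = wsrc.fit(feature_factory(6), sigma=2.0, epsilon=1e-4)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = wsrc.WSRCModel.load(path)
        np.testing.assert_array_equal(loaded.train_matrix, model.train_matrix)
        np.testing.assert_array_equal(loaded.labels, model.labels)
        assert loaded.sigma == model.sigma
        assert loaded.epsilon == model.epsilon
        assert loaded.pair_ids == model.pair_ids
        y = rng.standard_normal(8)
        assert (
            wsrc.predict(loaded, y).predicted_class == wsrc.predict(model, y).predicted_class
        )
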