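"""MLP on circuit parameters: splits, normalization, training, CV."""

import numpy as np
import pytest

from dentaleis import (
    DM_PARAMS,
    ND_PARAMS,
    MLPConfig,
    apply_normalizer,
    cross_validate,
    dataset_features,
    fit_normalizer,
    generate_labeled_dataset,
    predict,
    split_dataset,
    train_mlp,
)
from dentaleis.synthetic_data import PopulationModel


@pytest.fixture(scope="module")
def mlp_dataset():
    """80 teeth (40 per class): a 70/30 split leaves 24 test samples."""
    return generate_labeled_dataset(n_per_class=40)


class TestSplit:
    def test_70_30_sizes(self, mlp_dataset):
        train, test = split_dataset(mlp_dataset, 0.7, seed=0)
        assert len(train) == 56 and len(test) == 24
        assert set(train).isdisjoint(test)

    def test_reproducible(self, mlp_dataset):
        assert split_dataset(mlp_dataset, 0.7, seed=3) == split_dataset(
            mlp_dataset, 0.7, seed=3)

    def test_stratified(self, mlp_dataset):
        train, test = split_dataset(mlp_dataset, 0.7, seed=1)
        labels = mlp_dataset.labels()
        n_nd = sum(labels[t] == "ND" for t in train)
        assert abs(n_nd - len(train) / 2) <= 1

    def test_too_small_class_rejected(self):
        d = generate_labeled_dataset(n_per_class=1)
        with pytest.raises(ValueError):
            split_dataset(d)


class TestNormalizer:
    def test_endpoints_map_to_unit_interval(self):
        X = np.array([[3.9e3], [7.5e4]])
        nrm = fit_normalizer(X)
        out = apply_normalizer(X, nrm)
        assert out[0, 0] == pytest.approx(0.0) and out[1, 0] == pytest.approx(1.0)

    def test_midpoint_maps_to_half(self):
        nrm = fit_normalizer(np.array([[0.0, 10.0], [2.0, 30.0]]))
        assert np.allclose(apply_normalizer(np.array([1.0, 20.0]), nrm), 0.5)

    def test_out_of_range_values_not_clipped(self):
        nrm = fit_normalizer(np.array([[1.0], [2.0]]))
        assert apply_normalizer(np.array([0.5]), nrm)[0] == pytest.approx(-0.5)
        assert apply_normalizer(np.array([3.0]), nrm)[0] == pytest.approx(2.0)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.array([[1.0, 5.0], [2.0, 5.0]]))

    def test_no_test_set_leakage(self, mlp_dataset):
        # normalizer fitted on train rows only: adding extreme test rows
        # afterwards must not change the transform of a train row
        X, y, _ = dataset_features(mlp_dataset)
        nrm = fit_normalizer(X[:40])
        before = apply_normalizer(X[0], nrm)
        _ = np.vstack([X[40:], X[40:] * 100])  # "test" rows, never touched
        assert np.array_equal(apply_normalizer(X[0], nrm), before)


class TestTrainPredict:
    def test_separable_centers_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            [[ND_PARAMS.r1, ND_PARAMS.r2, ND_PARAMS.q]] * 10,
            [[DM_PARAMS.r1, DM_PARAMS.r2, DM_PARAMS.q]] * 10,
        ]) * (1 + rng.normal(0, 1e-3, (20, 3)))
        y = ["ND"] * 10 + ["DM"] * 10
        m = train_mlp(X, y, MLPConfig(seed=0))
        _, labels = predict(m, X)
        assert labels == y

    def test_deterministic_given_seed(self, mlp_dataset):
        X, y, _ = dataset_features(mlp_dataset)
        p1, _ = predict(train_mlp(X, y, MLPConfig(seed=7)), X)
        p2, _ = predict(train_mlp(X, y, MLPConfig(seed=7)), X)
        assert np.array_equal(p1, p2)

    def test_end_to_end_test_accuracy(self, mlp_dataset):
        train, test = split_dataset(mlp_dataset, 0.7, seed=0)
        X, y, ids = dataset_features(mlp_dataset)
        pos = {t: i for i, t in enumerate(ids)}
        m = train_mlp(X[[pos[t] for t in train]], [y[pos[t]] for t in train])
        _, labels = predict(m, X[[pos[t] for t in test]])
        truth = [y[pos[t]] for t in test]
        acc = np.mean([a == b for a, b in zip(labels, truth)])
        assert 0.75 <= acc <= 1.0

    def test_class_centers_classified_correctly(self, mlp_dataset):
        X, y, _ = dataset_features(mlp_dataset)
        m = train_mlp(X, y)
        _, labels = predict(m, np.array([
            [ND_PARAMS.r1, ND_PARAMS.r2, ND_PARAMS.q],
            [DM_PARAMS.r1, DM_PARAMS.r2, DM_PARAMS.q],
        ]))
        assert labels == ["ND", "DM"]

    def test_probability_in_unit_interval_and_tie_rule(self, mlp_dataset):
        X, y, _ = dataset_features(mlp_dataset)
        m = train_mlp(X, y)
        proba, labels = predict(m, X)
        assert np.all((proba >= 0) & (proba <= 1))
        for p, l in zip(proba, labels):
            assert l == ("DM" if p >= 0.5 else "ND")

    def test_wrong_feature_count_rejected(self, mlp_dataset):
        X, y, _ = dataset_features(mlp_dataset)
        m = train_mlp(X, y)
        with pytest.raises(ValueError):
            predict(m, np.ones((1, 2)))


class TestCrossValidate:
    def test_report_consistency_and_spread(self, mlp_dataset):
        rep = cross_validate(mlp_dataset, k=5, seed=0)
        assert len(rep.accuracy) == 5
        assert rep.mean["accuracy"] == pytest.approx(np.mean(rep.accuracy), abs=1e-12)
        assert rep.sd["accuracy"] <= 0.15

    def test_separable_data_all_splits_perfect(self):
        m = PopulationModel(log_sd={"r1": 1.0, "r2": 1.0, "q": 1.0}, n_sd=0.0)
        d = generate_labeled_dataset(m, n_per_class=10)
        rep = cross_validate(d, k=5, seed=0)
        assert rep.accuracy == (1.0,) * 5
        assert rep.sd["accuracy"] == 0.0

    def test_adding_n_feature_does_not_help(self, mlp_dataset):
        base = cross_validate(mlp_dataset, MLPConfig(), k=5, seed=0)
        with_n = cross_validate(mlp_dataset, MLPConfig(features=("r1", "r2", "q", "n")),
                                k=5, seed=0)
        assert with_n.mean["accuracy"] <= base.mean["accuracy"] + 0.02

    def test_k_larger_than_class_rejected(self):
        d = generate_labeled_dataset(n_per_class=3)
        with pytest.raises(ValueError):
            cross_validate(d, k=5)


def test_config_validation():
    with pytest.raises(ValueError):
        MLPConfig(features=())
    with pytest.raises(ValueError):
        MLPConfig(features=("r1", "bogus"))
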