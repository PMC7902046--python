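"""Surrogate ensemble: fitting, cross-validation, recommendation."""

import numpy as np
import pytest

from mockomics import (
    SurrogateConfig,
    TrainingSet,
    crossval_predictions,
    fit_surrogate,
    latin_hypercube_designs,
    make_ground_truth,
    recommend,
)
from mockomics.fixtures import DEFAULT_TARGET_REACTIONS

SMALL = SurrogateConfig(ensemble_size=30, n_boosted=8)


def lhs_training(truth, n, reactions, seed):
    batch = latin_hypercube_designs(n, reactions, rng_seed=seed)
    keys = [d.key() for d in batch]
    return TrainingSet(
        X=np.array(keys), y=np.array([truth[k] for k in keys]), reactions=reactions
    )


@pytest.fixture(scope="module")
def additive_truth(toy_model):
    return make_ground_truth(toy_model, None, "additive", rng_seed=3)


class TestTrainingSet:
    def test_duplicate_rows_rejected(self):
        X = np.array([[0, 1], [0, 1]])
        with pytest.raises(ValueError, match="duplicate"):
            TrainingSet(X, np.array([1.0, 2.0]), ["a", "b"])

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            TrainingSet(np.array([[0, 1]]), np.array([-1.0]), ["a", "b"])

    def test_too_few_instances_for_fit(self):
        X = np.array([[0, 0], [0, 1], [1, 0]])
        training = TrainingSet(X, np.ones(3), ["a", "b"])
        with pytest.raises(ValueError, match="at least"):
            fit_surrogate(training, SMALL)


class TestFit:
    def test_constant_response(self):
        rng = np.random.default_rng(0)
        X = np.array(
            [list(np.base_repr(i, 3).zfill(3)) for i in range(15)], dtype=int
        )
        training = TrainingSet(X, np.full(15, 4.2), ["a", "b", "c"])
        model = fit_surrogate(training, SMALL, rng_seed=1)
        mean, sd = model.predict(rng.integers(0, 3, size=(8, 3)))
        np.testing.assert_allclose(mean, 4.2, atol=1e-9)
        np.testing.assert_allclose(sd, 0.0, atol=1e-9)

    def test_row_order_invariance(self, additive_truth):
        training = lhs_training(additive_truth, 40, DEFAULT_TARGET_REACTIONS, 2)
        perm = np.random.default_rng(5).permutation(training.n)
        shuffled = TrainingSet(
            training.X[perm], training.y[perm], training.reactions
        )
        a = fit_surrogate(training, SMALL, rng_seed=3)
        b = fit_surrogate(shuffled, SMALL, rng_seed=3)
        probe = np.array(
            [d.key() for d in latin_hypercube_designs(
                20, DEFAULT_TARGET_REACTIONS, 9)]
        )
        np.testing.assert_array_equal(
            a.member_predictions(probe), b.member_predictions(probe)
        )

    def test_mean_within_ensemble_range(self, additive_truth):
        training = lhs_training(additive_truth, 40, DEFAULT_TARGET_REACTIONS, 2)
        model = fit_surrogate(training, SMALL, rng_seed=3)
        dist = model.predictive_distribution(training.X[0])
        assert dist.samples.min() <= dist.mean <= dist.samples.max()
        assert dist.sd >= 0

    def test_additive_ground_truth_crossval_r2(self, additive_truth):
        training = lhs_training(additive_truth, 96, DEFAULT_TARGET_REACTIONS, 0)
        triples = crossval_predictions(training, folds=10, rng_seed=0)
        obs = np.array([t[0] for t in triples])
        pred = np.array([t[1] for t in triples])
        r2 = 1 - ((obs - pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum()
        assert r2 >= 0.9

    def test_noisy_additive_crossval_rmse(self, toy_model):
        noise = 0.3
        truth = make_ground_truth(
            toy_model, None, "additive", rng_seed=3, noise_sd=noise
        )
        training = lhs_training(truth, 96, DEFAULT_TARGET_REACTIONS, 0)
        triples = crossval_predictions(training, folds=10, rng_seed=0)
        obs = np.array([t[0] for t in triples])
        pred = np.array([t[1] for t in triples])
        rmse = float(np.sqrt(((obs - pred) ** 2).mean()))
        assert rmse <= 1.2 * noise


class TestCrossval:
    def test_constant_response_predicts_constant(self):
        X = np.array(
            [list(np.base_repr(i, 3).zfill(3)) for i in range(15)], dtype=int
        )
        training = TrainingSet(X, np.full(15, 1.5), ["a", "b", "c"])
        triples = crossval_predictions(training, folds=5, rng_seed=0, config=SMALL)
        assert all(p == pytest.approx(1.5, abs=1e-9) for _, p, _ in triples)

    def test_every_instance_predicted_once(self, additive_truth):
        training = lhs_training(additive_truth, 30, DEFAULT_TARGET_REACTIONS, 1)
        triples = crossval_predictions(training, folds=5, rng_seed=0, config=SMALL)
        assert len(triples) == 30
        np.testing.assert_allclose(
            [t[0] for t in triples], training.y
        )

    def test_too_many_folds_rejected(self, additive_truth):
        training = lhs_training(additive_truth, 20, DEFAULT_TARGET_REACTIONS, 1)
        with pytest.raises(ValueError):
            crossval_predictions(training, folds=21)
        with pytest.raises(ValueError):
            crossval_predictions(training, folds=1)


class TestRecommend:
    def test_single_unseen_optimum_is_recommended_first(self):
        reactions = ["a", "b", "c"]
        truth = make_ground_truth(
            None, None, "additive", reactions=reactions, rng_seed=8
        )
        best = max(truth, key=truth.get)
        keys = [k for k in truth if k != best]
        training = TrainingSet(
            np.array(keys), np.array([truth[k] for k in keys]), reactions
        )
        model = fit_surrogate(training, SMALL, rng_seed=0)
        recs = recommend(model, k=1, exclude=training, config=SMALL)
        assert recs.keys() == [best]

    def test_entire_space_excluded_raises(self):
        reactions = ["a", "b"]
        truth = make_ground_truth(
            None, None, "additive", reactions=reactions, rng_seed=8
        )
        keys = list(truth)
        training = TrainingSet(
            np.array(keys), np.array([truth[k] for k in keys]), reactions
        )
        model = fit_surrogate(training, SMALL, rng_seed=0)
        with pytest.raises(ValueError, match="no unseen"):
            recommend(model, k=1, exclude=training, config=SMALL)

    def test_k10_on_full_space_distinct_and_unseen(self, additive_truth):
        training = lhs_training(additive_truth, 96, DEFAULT_TARGET_REACTIONS, 0)
        model = fit_surrogate(training, SMALL, rng_seed=0)
        recs = recommend(model, k=10, exclude=training, config=SMALL)
        keys = recs.keys()
        assert len(keys) == 10 and len(set(keys)) == 10
        assert not set(keys) & training.keys()
        means = [dist.mean for _, dist in recs]
        assert means == sorted(means, reverse=True)

    def test_recommendations_never_intersect_training(self, additive_truth):
        for seed in range(5):
            training = lhs_training(
                additive_truth, 40, DEFAULT_TARGET_REACTIONS, seed
            )
            model = fit_surrogate(training, SMALL, rng_seed=seed)
            recs = recommend(model, k=5, exclude=training, config=SMALL)
            assert not set(recs.keys()) & training.keys()

    def test_uncertainty_shrinks_with_training_size(self, additive_truth):
        probe = np.array(
            [d.key() for d in latin_hypercube_designs(
                50, DEFAULT_TARGET_REACTIONS, 123)]
        )
        sds = []
        for n in (24, 96):
            training = lhs_training(additive_truth, n, DEFAULT_TARGET_REACTIONS, 0)
            model = fit_surrogate(training, SMALL, rng_seed=0)
            _, sd = model.predict(probe)
            sds.append(sd.mean())
        assert sds[1] < sds[0]

    def test_expected_improvement_acquisition(self, additive_truth):
        training = lhs_training(additive_truth, 40, DEFAULT_TARGET_REACTIONS, 0)
        config = SurrogateConfig(
            ensemble_size=30, n_boosted=8, acquisition="expected_improvement"
        )
        model = fit_surrogate(training, config, rng_seed=0)
        recs = recommend(model, k=3, exclude=training, config=config)
        assert len(recs) == 3
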