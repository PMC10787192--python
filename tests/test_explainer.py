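import numpy as np
import pytest

from drtransfer.explainer import (ContributionSet, DrugGeneScores,
                                  aggregate_scores, granger_contributions,
                                  score_samples, train_explainer)
from drtransfer.nn import DenseNet
from drtransfer.predictor import TrainedPredictor

from conftest import linear_predictor


def brute_force_contributions(w, x, y, clamp=True):
    """Independent oracle for a linear model yhat = w . x: evaluate the
    masking definition symbolically, no shared code with the implementation."""
    w, x = np.asarray(w, float), np.asarray(x, float)
    base_err = (y - w @ x) ** 2
    deltas = []
    for i in range(len(x)):
        xm = x.copy()
        xm[i] = 0.0
        deltas.append((y - w @ xm) ** 2 - base_err)
    deltas = np.asarray(deltas)
    if clamp:
        deltas = np.clip(deltas, 0.0, None)
    total = deltas.sum()
    return np.full(len(x), 1.0 / len(x)) if total <= 0 else deltas / total


class TestGrangerContributions:
    def test_hand_example_two_genes(self):
        # yhat = x1 + x2; X = (1, 1), y = 2: masking either gene gives
        # error 1 while the base error is 0, so contributions split evenly.
        model = linear_predictor([1.0, 1.0])
        c = granger_contributions(model, np.array([[1.0, 1.0]]), np.array([2.0]))
        np.testing.assert_allclose(c.omega[0], [0.5, 0.5], atol=1e-12)
        assert c.eps[0] == pytest.approx(0.0)

    def test_single_gene_is_one(self):
        c = granger_contributions(linear_predictor([2.0]),
                                  np.array([[3.0]]), np.array([1.0]))
        np.testing.assert_allclose(c.omega, [[1.0]])

    def test_ignored_gene_scores_zero(self):
        model = linear_predictor([1.5, 0.0, -2.0])
        c = granger_contributions(model, np.array([[1.0, 5.0, 2.0]]),
                                  np.array([0.0]))
        assert c.omega[0, 1] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=6)
        model = linear_predictor(w)
        X = rng.normal(size=(20, 6))
        y = X @ w + rng.normal(0, 0.3, size=20)
        c = granger_contributions(model, X, y)
        for i in range(20):
            np.testing.assert_allclose(
                c.omega[i], brute_force_contributions(w, X[i], y[i]), atol=1e-8)

    def test_simplex_contract(self):
        rng = np.random.default_rng(1)
        model = linear_predictor(rng.normal(size=5))
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        c = granger_contributions(model, X, y)
        assert np.all(c.omega >= 0)
        np.testing.assert_allclose(c.omega.sum(axis=1), 1.0, atol=1e-8)

    def test_uniform_fallback_flagged(self):
        # constant predictor: masking never changes the error
        net = DenseNet(3, (4,), 1, seed=0)
        w = {k: np.zeros_like(v) for k, v in net.get_weights().items()}
        net.set_weights(w)
        model = TrainedPredictor(members=[net], gene_ids=["a", "b", "c"],
                                 hyperparams={})
        c = granger_contributions(model, np.array([[1.0, 2.0, 3.0]]),
                                  np.array([5.0]))
        assert c.uniform_fallback[0]
        np.testing.assert_allclose(c.omega[0], 1.0 / 3.0)


class TestExplainerTraining:
    def test_output_dimensionality_matches_input(self):
        rng = np.random.default_rng(2)
        model = linear_predictor(rng.normal(size=4))
        X = rng.normal(size=(30, 4))
        y = X @ np.ones(4)
        ens = train_explainer(model, X, y, n_explainers=2, hidden=8, layers=1,
                              epochs=5)
        assert ens.members[0].n_in == ens.members[0].n_out == 4

    def test_identical_seeds_collapse_median(self):
        rng = np.random.default_rng(3)
        model = linear_predictor(rng.normal(size=3))
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        targets = granger_contributions(model, X, y)
        nets = [DenseNet(3, (8,), 3, output="softmax", seed=5) for _ in range(3)]
        for n in nets:
            n.fit(X, targets.omega, epochs=10, batch_size=8, learning_rate=1e-2)
        preds = np.stack([n.predict(X) for n in nets])
        np.testing.assert_array_equal(np.median(preds, axis=0), preds[0])

    def test_distills_constant_target(self):
        """A constant contribution vector is recovered on held-out samples."""
        rng = np.random.default_rng(4)
        model = linear_predictor(rng.normal(size=4))
        X = rng.normal(size=(150, 4))
        v = np.array([0.5, 0.3, 0.15, 0.05])
        targets = ContributionSet(sample_ids=[f"s{i}" for i in range(150)],
                                  gene_ids=list(model.gene_ids),
                                  omega=np.tile(v, (150, 1)))
        ens = train_explainer(model, X[:100], np.zeros(100), n_explainers=3,
                              hidden=32, layers=1, epochs=400,
                              targets=ContributionSet(
                                  sample_ids=targets.sample_ids[:100],
                                  gene_ids=targets.gene_ids,
                                  omega=targets.omega[:100]))
        scored = score_samples(ens, X[100:])
        tv = 0.5 * np.abs(scored.omega - v).sum(axis=1)
        assert tv.mean() < 0.05


class TestScoring:
    def _ensemble(self, seed=0):
        rng = np.random.default_rng(seed)
        model = linear_predictor(rng.normal(size=4))
        X = rng.normal(size=(40, 4))
        y = X @ np.ones(4) + rng.normal(0, 0.1, 40)
        return train_explainer(model, X, y, n_explainers=3, hidden=8,
                               layers=1, epochs=20), X

    def test_simplex_and_duplicate_sample_consistency(self):
        ens, X = self._ensemble()
        dup = np.vstack([X[0], X[0], X[1]])
        scored = score_samples(ens, dup)
        np.testing.assert_allclose(scored.omega.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(scored.omega[0], scored.omega[1])

    def test_gene_mismatch_error(self):
        ens, X = self._ensemble()
        with pytest.raises(ValueError):
            score_samples(ens, X[:, :3])


class TestAggregation:
    def test_two_sample_arithmetic(self):
        c = ContributionSet(sample_ids=["a", "b"], gene_ids=["g1", "g2"],
                            omega=np.array([[0.2, 0.8], [0.4, 0.6]]))
        scores = aggregate_scores(c, ["a", "b"])
        np.testing.assert_allclose(scores.scores, [0.3 / 0.7, 1.0], atol=1e-12)

    def test_single_sample_rescaled(self):
        c = ContributionSet(sample_ids=["a"], gene_ids=["g1", "g2"],
                            omega=np.array([[0.25, 0.75]]))
        np.testing.assert_allclose(aggregate_scores(c, ["a"]).scores,
                                   [1.0 / 3.0, 1.0])

    def test_symmetric_genes_all_one(self):
        c = ContributionSet(sample_ids=["a", "b"], gene_ids=["g1", "g2"],
                            omega=np.full((2, 2), 0.5))
        np.testing.assert_allclose(aggregate_scores(c).scores, 1.0)

    def test_empty_sample_set_error(self):
        c = ContributionSet(sample_ids=["a"], gene_ids=["g"],
                            omega=np.array([[1.0]]))
        with pytest.raises(ValueError):
            aggregate_scores(c, [])

    def test_scores_validated(self):
        with pytest.raises(ValueError):
            DrugGeneScores(gene_ids=["a", "b"], scores=[0.5, 0.9])  # max != 1
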