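import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genesig._reference import solve_l1svm_reference
from genesig.svm import (
    L1NormSVC,
    L2NormSVC,
    OneVsRestL1SVM,
    l1svm_objective,
    nonzero_genes,
)


def random_instance(rng, n_max=20, p_max=10):
    n = int(rng.integers(6, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    X = rng.normal(size=(n, p))
    y = rng.choice([-1, 1], size=n)
    while len(np.unique(y)) < 2:
        y = rng.choice([-1, 1], size=n)
    return X, y


class TestL1NormSVC:
    def test_objective_matches_proximal_gradient_oracle(self):
        rng = np.random.default_rng(123)
        for i in range(20):
            X, y = random_instance(rng)
            C = [0.1, 0.5, 0.9][i % 3]
            model = L1NormSVC(C=C).fit(X, y)
            _, _, obj_ref = solve_l1svm_reference(X, y, C)
            rel = abs(model.objective_value_ - obj_ref) / max(1e-12, abs(obj_ref))
            assert rel < 1e-6

    def test_penalty_dominated_regime_zeroes_weights(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng)
        model = L1NormSVC(C=1e-4).fit(X, y)
        assert np.abs(model.coef_).max() < 1e-8
        # with w = 0 the intercept solves the 1-D squared-hinge problem,
        # whose optimum cannot be improved by the full model's objective
        b = model.intercept_[0]
        ys = np.where(y == model.classes_[1], 1.0, -1.0)
        for b_alt in np.linspace(b - 1, b + 1, 41):
            assert l1svm_objective(X, ys, np.zeros(X.shape[1]), b, 1e-4) <= (
                l1svm_objective(X, ys, np.zeros(X.shape[1]), b_alt, 1e-4) + 1e-10
            )

    def test_separable_1d_single_nonzero_weight(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = L1NormSVC(C=0.9).fit(X, y)
        assert (model.predict(X) == y).all()
        assert np.count_nonzero(np.abs(model.coef_) > 1e-8) == 1

    def test_single_class_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="2 classes"):
            L1NormSVC(C=0.5).fit(X, np.ones(4))

    @pytest.mark.parametrize("C", [0.0, 1.0, -0.2, 1.5])
    def test_tradeoff_outside_open_interval_rejected(self, C):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError, match="C"):
            L1NormSVC(C=C).fit(X, np.array([-1, 1]))

    def test_non_finite_input_rejected(self):
        X = np.array([[np.nan], [1.0]])
        with pytest.raises(ValueError):
            L1NormSVC(C=0.5).fit(X, np.array([-1, 1]))

    def test_intercept_is_unpenalized_translation_property(self):
        # translating all samples leaves the optimal w (and objective)
        # unchanged: the shift is absorbed entirely by the free intercept
        rng = np.random.default_rng(42)
        X, y = random_instance(rng)
        shift = rng.normal(size=X.shape[1]) * 5.0
        base = L1NormSVC(C=0.5).fit(X, y)
        moved = L1NormSVC(C=0.5).fit(X + shift, y)
        assert abs(base.objective_value_ - moved.objective_value_) < 1e-7
        np.testing.assert_allclose(base.coef_, moved.coef_, atol=1e-5)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000), C=st.sampled_from([0.2, 0.5, 0.8]))
    def test_feature_permutation_permutes_weights(self, seed, C):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng, n_max=15, p_max=6)
        perm = rng.permutation(X.shape[1])
        base = L1NormSVC(C=C).fit(X, y)
        permuted = L1NormSVC(C=C).fit(X[:, perm], y)
        np.testing.assert_allclose(base.coef_.ravel()[perm], permuted.coef_.ravel(), atol=1e-5)

    def test_sparsity_monotone_trend_along_path(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 12))
        w_true = np.zeros(12)
        w_true[:3] = [2.0, -1.5, 1.0]
        y = np.sign(X @ w_true + 0.1 * rng.normal(size=40)).astype(int)
        grid = [0.95, 0.6, 0.3, 0.1, 0.02, 0.002]
        norms = [np.abs(L1NormSVC(C=C).fit(X, y).coef_).sum() for C in grid]
        # ||w||_1 -> 0 as C -> 0+, with a decreasing overall trend
        assert norms[-1] < 1e-8
        assert norms[0] > norms[-1]


class TestNonzeroGenes:
    def test_relative_threshold(self):
        class Model:
            coef_ = np.array([[0.5, 0.0, 1e-12]])

        assert set(nonzero_genes(Model(), eps_w=1e-6, feature_names=["g1", "g2", "g3"])) == {"g1"}

    def test_zero_vector_gives_empty_set(self):
        class Model:
            coef_ = np.zeros((1, 4))

        assert nonzero_genes(Model(), eps_w=1e-6) == {}

    def test_eps_zero_is_bit_exact(self):
        class Model:
            coef_ = np.array([[0.5, 0.0, 1e-300]])

        assert set(nonzero_genes(Model(), eps_w=0.0, feature_names=list("abc"))) == {"a", "c"}


class TestOneVsRest:
    def test_private_feature_blobs_attribute_correctly(self, blobs):
        model = OneVsRestL1SVM(C=0.3).fit(blobs["X"], blobs["y"])
        truth = blobs["truth"]
        genes = blobs["genes"]
        for cls, est in zip(model.classes_, model.estimators_):
            top = genes[int(np.argmax(np.abs(est.coef_)))]
            assert top in truth.informative[cls]

    def test_two_class_decision_values_mirror(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-1, 0.3, (15, 3)), rng.normal(1, 0.3, (15, 3))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        model = OneVsRestL1SVM(C=0.7).fit(X, y)
        d = model.decision_function(X)
        # the two one-vs-rest tasks are label negations of each other
        np.testing.assert_allclose(d[:, 0], -d[:, 1], atol=1e-4)
        assert (model.predict(X) == y).all()

    def test_identical_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ValueError, match="2 classes"):
            OneVsRestL1SVM(C=0.5).fit(X, np.array(["x"] * 8))

    def test_nonzero_union_counts_each_gene_once(self, blobs):
        model = OneVsRestL1SVM(C=0.5).fit(blobs["X"], blobs["y"])
        by_class = model.nonzero_by_class(feature_names=blobs["genes"])
        union = model.nonzero_union(feature_names=blobs["genes"])
        assert union == set().union(*[set(g) for g in by_class.values()])


class TestL2NormSVC:
    def test_separable_training_accuracy(self, blobs):
        model = L2NormSVC().fit(blobs["X"], blobs["y"])
        assert (model.predict(blobs["X"]) == blobs["y"]).mean() == 1.0

    def test_feature_order_symmetry(self, blobs):
        rng = np.random.default_rng(1)
        perm = rng.permutation(blobs["X"].shape[1])
        base = L2NormSVC().fit(blobs["X"], blobs["y"]).predict(blobs["X"])
        shuffled = L2NormSVC().fit(blobs["X"][:, perm], blobs["y"]).predict(blobs["X"][:, perm])
        assert (base == shuffled).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            L2NormSVC().fit(np.zeros((4, 2)), np.array(["a"] * 4))
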