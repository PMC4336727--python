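"""Chi-square kernel, homogeneous kernel map, SVM training and metrics."""

import numpy as np
import pytest

from paddyflower.classifier import (
    BACKGROUND,
    FLOWERING,
    ConfusionCounts,
    FlowerModel,
    chi2_kernel,
    evaluate_metrics,
    kernel_map,
    kernel_map_matrix,
    load_model,
    predict,
    save_model,
    suggested_period,
    train_model,
)
from paddyflower.features import dense_multiscale_sift
from paddyflower.vocabulary import bovw_histogram


def _normalized(rng, k):
    h = rng.random(k)
    return h / h.sum()


class TestChi2Kernel:
    def test_self_similarity_normalized(self):
        h = _normalized(np.random.default_rng(0), 20)
        assert chi2_kernel(h, h) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports(self):
        assert chi2_kernel([1, 0, 2, 0], [0, 3, 0, 4]) == 0.0

    def test_hand_computed(self):
        # 2*0.5*0.25/0.75 + 2*0.5*0.75/1.25 = 1/6 + 0.6 + ... = 14/15
        assert chi2_kernel([0.5, 0.5], [0.25, 0.75]) == pytest.approx(14 / 15, abs=1e-12)

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.random(10), rng.random(10)
            k = chi2_kernel(a, b)
            assert k == pytest.approx(chi2_kernel(b, a), abs=1e-12)
            assert k <= (a.sum() + b.sum()) / 2 + 1e-12

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            chi2_kernel([0.5, -0.1], [0.2, 0.3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            chi2_kernel([1, 2], [1, 2, 3])


class TestKernelMap:
    def test_zero_histogram_maps_to_zero(self):
        out = kernel_map(np.zeros(600), n=2)
        assert out.shape == (3000,)
        assert np.all(out == 0.0)

    def test_output_dimension(self):
        assert kernel_map(np.ones(600) / 600, n=2).shape == (3000,)
        assert kernel_map(np.ones(10) / 10, n=3).shape == (70,)

    def test_approximates_exact_kernel(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x, y = _normalized(rng, 50), _normalized(rng, 50)
            approx = float(kernel_map(x) @ kernel_map(y))
            assert approx == pytest.approx(chi2_kernel(x, y), abs=0.01)

    def test_error_shrinks_with_order_at_suited_period(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 60))
        X /= X.sum(axis=1, keepdims=True)
        Y = rng.random((40, 60))
        Y /= Y.sum(axis=1, keepdims=True)
        exact = np.array([chi2_kernel(x, y) for x, y in zip(X, Y)])
        errs = []
        for n in (1, 2, 3):
            L = suggested_period(n)
            G = np.einsum("ij,ij->i", kernel_map_matrix(X, n, L), kernel_map_matrix(Y, n, L))
            errs.append(np.max(np.abs(G - exact)))
        assert errs[0] > errs[1] > errs[2]

    def test_matches_sklearn_sampler(self):
        # independent route: sklearn's additive chi2 Fourier sampler uses the
        # same closed form; Gram values must agree
        from sklearn.kernel_approximation import AdditiveChi2Sampler

        rng = np.random.default_rng(4)
        X = rng.random((10, 30))
        sampler = AdditiveChi2Sampler(sample_steps=3, sample_interval=0.5).fit(X)
        ours = kernel_map_matrix(X, n=2, L=0.5)
        theirs = sampler.transform(X)
        np.testing.assert_allclose(ours @ ours.T, theirs @ theirs.T, atol=1e-10)

    def test_suggested_period_default_order(self):
        assert suggested_period(2) == pytest.approx(0.5, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            kernel_map(np.ones(4), n=0)
        with pytest.raises(ValueError):
            kernel_map(np.ones(4), L=0.0)
        with pytest.raises(ValueError):
            kernel_map(np.array([0.5, -0.5]))


class TestTrainPredict:
    def test_training_separates_classes(self, patch_db, mini_codebook, mini_model):
        correct = 0
        for p in patch_db:
            h = bovw_histogram(dense_multiscale_sift(p.patch.luminance), mini_codebook)
            label, score = predict(h, mini_model)
            assert label == (FLOWERING if score > 0 else BACKGROUND)
            correct += label == p.label
        assert correct == len(patch_db)

    def test_deterministic_training(self, patch_db, mini_codebook, mini_model):
        again = train_model(patch_db, mini_codebook, seed=7)
        np.testing.assert_array_equal(again.weights, mini_model.weights)
        assert again.bias == mini_model.bias

    def test_single_class_rejected(self, patch_db, mini_codebook):
        pos_only = [p for p in patch_db if p.label == FLOWERING]
        with pytest.raises(ValueError, match="both"):
            train_model(pos_only, mini_codebook)

    def test_empty_rejected(self, mini_codebook):
        with pytest.raises(ValueError, match="empty"):
            train_model([], mini_codebook)

    def test_zero_histogram_scores_bias(self, mini_model):
        label, score = predict(np.zeros(mini_model.k), mini_model)
        assert score == pytest.approx(mini_model.bias)

    def test_score_zero_is_background(self):
        model = FlowerModel(weights=np.zeros(5 * 4), bias=0.0, map_order_n=2,
                            map_period_L=0.5, C=1.0, k=4)
        label, score = predict(np.ones(4) / 4, model)
        assert score == 0.0
        assert label == BACKGROUND

    def test_length_mismatch(self, mini_model):
        with pytest.raises(ValueError, match="length"):
            predict(np.ones(mini_model.k + 1), mini_model)

    def test_model_round_trip(self, mini_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(mini_model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.weights, mini_model.weights)
        assert back.bias == mini_model.bias
        assert back.window_px == mini_model.window_px


class TestEvaluateMetrics:
    def test_hand_computed(self):
        m = evaluate_metrics(ConfusionCounts(TP=59, FN=41, TN=99, FP=1))
        assert m["tp_rate"] == pytest.approx(0.59)
        assert m["tn_rate"] == pytest.approx(0.99)
        assert m["accuracy"] == pytest.approx(0.79)

    def test_perfect_classifier(self):
        m = evaluate_metrics(ConfusionCounts(TP=10, FN=0, TN=20, FP=0))
        assert m == {"accuracy": 1.0, "tp_rate": 1.0, "tn_rate": 1.0}

    def test_undefined_rate_is_none(self):
        m = evaluate_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=5))
        assert m["tp_rate"] is None
        assert m["accuracy"] == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)
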