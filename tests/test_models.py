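import numpy as np
import pytest

from mmpcliff.labeling import AC, EXCLUDED, NONAC, ThresholdPolicy, compute_class_threshold, label_mmps
from mmpcliff.mmp import build_mmps
from mmpcliff.models import (
    ModelSpec,
    SVM_C_GRID,
    hyperparameter_search,
    knn_predict,
    mmp_gram,
    mmp_kernel,
    tanimoto_kernel,
    train_model,
)
from mmpcliff.models.fcnn import FCNNClassifier
from mmpcliff.models.mpnn import MPNNClassifier
from mmpcliff.models.nn import monotone_widths
from mmpcliff.representations import (
    MMPFingerprint,
    build_cgr,
    build_vocabularies,
    encode_mmp_fingerprint,
)
from mmpcliff.splits import random_split


def fp(core, unique, common):
    return MMPFingerprint(
        core_bits=np.array(core, dtype=np.uint8),
        unique_bits=np.array(unique, dtype=np.uint8),
        common_bits=np.array(common, dtype=np.uint8),
    )


class TestTanimoto:
    def test_identical_nonempty(self):
        v = np.array([1, 0, 1, 1])
        assert tanimoto_kernel(v, v) == 1.0

    def test_disjoint(self):
        assert tanimoto_kernel(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_two_of_five(self):
        a = np.array([1, 1, 1, 0, 0])
        b = np.array([1, 1, 0, 1, 1])
        assert tanimoto_kernel(a, b) == pytest.approx(0.4)

    def test_empty_vs_empty_is_one(self):
        z = np.zeros(4)
        assert tanimoto_kernel(z, z) == 1.0

    def test_empty_vs_nonempty_is_zero(self):
        assert tanimoto_kernel(np.zeros(4), np.array([1, 0, 0, 0])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto_kernel(np.zeros(3), np.zeros(4))


class TestMMPKernel:
    def test_self_similarity_is_one(self):
        x = fp([1, 0, 1], [1, 1], [0, 1])
        assert mmp_kernel(x, x) == 1.0

    def test_product_structure(self):
        # core similarity 0.5, substituent similarity 0.4 -> 0.2
        x = fp([1, 1, 0, 0], [1, 1, 1, 0, 0], [])
        y = fp([1, 0, 1, 0], [1, 1, 0, 1, 1], [])
        assert tanimoto_kernel(x.core_bits, y.core_bits) == pytest.approx(1 / 3)
        value = mmp_kernel(x, y)
        assert value == pytest.approx((1 / 3) * 0.4)

    def test_disjoint_cores_annihilate(self):
        x = fp([1, 0], [1, 1], [1, 0])
        y = fp([0, 1], [1, 1], [1, 0])
        assert mmp_kernel(x, y) == 0.0

    def test_bounded_by_factors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = fp(rng.integers(0, 2, 8), rng.integers(0, 2, 6), rng.integers(0, 2, 4))
            y = fp(rng.integers(0, 2, 8), rng.integers(0, 2, 6), rng.integers(0, 2, 4))
            k = mmp_kernel(x, y)
            assert k <= tanimoto_kernel(x.core_bits, y.core_bits) + 1e-12
            assert k <= tanimoto_kernel(x.substituent_bits, y.substituent_bits) + 1e-12

    def test_vocabulary_mismatch(self):
        with pytest.raises(ValueError):
            mmp_kernel(fp([1], [1], []), fp([1, 0], [1], []))

    def test_gram_properties_on_random_fingerprints(self):
        rng = np.random.default_rng(5)
        fps = [
            fp(rng.integers(0, 2, 30), rng.integers(0, 2, 20), rng.integers(0, 2, 10))
            for _ in range(50)
        ]
        G = mmp_gram(fps)
        assert np.allclose(G, G.T)
        assert np.allclose(np.diag(G), 1.0)
        assert G.min() >= 0.0 and G.max() <= 1.0
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_gram_matches_pairwise_kernel(self):
        rng = np.random.default_rng(9)
        fps = [
            fp(rng.integers(0, 2, 10), rng.integers(0, 2, 8), rng.integers(0, 2, 6))
            for _ in range(8)
        ]
        G = mmp_gram(fps)
        for i in range(8):
            for j in range(8):
                assert G[i, j] == pytest.approx(mmp_kernel(fps[i], fps[j]))


class TestKNN:
    def test_self_retrieval(self):
        sims = np.array([[0.3, 1.0, 0.5]])
        y = np.array([0, 1, 0])
        labels, votes = knn_predict(sims, y, k=1)
        assert labels[0] == 1 and votes[0] == 1.0

    def test_majority_of_five(self):
        sims = np.array([[0.9, 0.8, 0.7, 0.6, 0.5, 0.1]])
        y = np.array([1, 1, 1, 0, 0, 0])
        labels, votes = knn_predict(sims, y, k=5)
        assert labels[0] == 1
        assert votes[0] == pytest.approx(3 / 5)

    def test_similarity_tie_breaks_to_lower_index(self):
        sims = np.array([[0.8, 0.8]])
        for y in (np.array([1, 0]), np.array([0, 1])):
            labels, _ = knn_predict(sims, y, k=1)
            assert labels[0] == y[0]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            knn_predict(np.ones((1, 3)), np.array([1, 0, 1]), k=4)


@pytest.fixture(scope="module")
def clean_training_data(clean_class):
    cls, _ = clean_class
    mmps = build_mmps(cls)
    # the classical 100-fold criterion keeps every expressed cliff an AC
    threshold = compute_class_threshold(
        cls, mmps, ThresholdPolicy("fixed", 2.0)
    )
    labeled = [lm for lm in label_mmps(mmps, threshold) if lm.label != EXCLUDED]
    split = random_split([lm.mmp for lm in labeled], 0.2, seed=0)
    by_key = {lm.mmp.key: lm for lm in labeled}
    train = [by_key[k] for k in sorted(split.train_ids)]
    test = [by_key[k] for k in sorted(split.test_ids)]
    vocab = build_vocabularies([lm.mmp for lm in train])
    fps = {lm.mmp.key: encode_mmp_fingerprint(lm.mmp, vocab) for lm in labeled}
    return train, test, fps


class TestTrainedModels:
    def test_constant_label_training_rejected(self, clean_training_data):
        train, _, fps = clean_training_data
        acs = [lm for lm in train if lm.label == AC]
        with pytest.raises(ValueError):
            train_model(
                ModelSpec.default("svm_mmp"),
                [fps[lm.mmp.key] for lm in acs],
                [lm.label for lm in acs],
            )

    @pytest.mark.parametrize("method", ["svm_mmp", "rf", "fcnn"])
    def test_deterministic_given_seed(self, method, clean_training_data):
        train, test, fps = clean_training_data
        X = [fps[lm.mmp.key] for lm in train]
        y = [lm.label for lm in train]
        spec = ModelSpec.default(method, hpo_trials=2, seed=4)
        preds = []
        for _ in range(2):
            model = train_model(spec, X, y)
            labels, prob = model.predict([fps[lm.mmp.key] for lm in test])
            preds.append((labels, prob.round(10).tolist()))
        assert preds[0] == preds[1]

    def test_svm_separates_noise_free_class(self, clean_training_data):
        from mmpcliff.metrics import compute_metrics, confusion

        train, test, fps = clean_training_data
        model = train_model(
            ModelSpec.default("svm_mmp", seed=0),
            [fps[lm.mmp.key] for lm in train],
            [lm.label for lm in train],
        )
        pred, _ = model.predict([fps[lm.mmp.key] for lm in test])
        m = compute_metrics(confusion([lm.label for lm in test], pred))
        assert m["mcc"] > 0.5

    @pytest.mark.parametrize(
        "method,space,floor",
        [
            ("knn1", None, 1.0),  # exact self-retrieval
            ("svm_mmp", {"C": ("choice", (100.0,))}, 1.0),  # hard-margin end
            ("rf", None, 0.95),  # bootstrap voting: near-memorization
            ("xgb", None, 0.9),
        ],
    )
    def test_training_set_memorization(self, method, space, floor, clean_training_data):
        from mmpcliff.metrics import compute_metrics, confusion

        train, _, fps = clean_training_data
        X = [fps[lm.mmp.key] for lm in train]
        y = [lm.label for lm in train]
        spec = ModelSpec.default(method, hpo_trials=0)
        if space is not None:
            spec = ModelSpec(method=method, space=space, hpo_trials=1, seed=0)
        model = train_model(spec, X, y)
        pred, _ = model.predict(X)
        ba = compute_metrics(confusion(y, pred))["ba"]
        if floor == 1.0:
            assert ba == pytest.approx(1.0)
        else:
            assert ba >= floor

    def test_predict_contract(self, clean_training_data):
        train, test, fps = clean_training_data
        model = train_model(
            ModelSpec.default("knn5", seed=0),
            [fps[lm.mmp.key] for lm in train],
            [lm.label for lm in train],
        )
        labels, probs = model.predict([])
        assert labels == [] and len(probs) == 0
        labels, probs = model.predict([fps[lm.mmp.key] for lm in test])
        assert len(labels) == len(test)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_1nn_model_reproduces_raw_knn(self, clean_training_data):
        train, test, fps = clean_training_data
        X = [fps[lm.mmp.key] for lm in train]
        y = np.array([1 if lm.label == AC else 0 for lm in train])
        model = train_model(ModelSpec.default("knn1"), X, [lm.label for lm in train])
        queries = [fps[lm.mmp.key] for lm in test]
        labels, _ = model.predict(queries)
        raw, _ = knn_predict(mmp_gram(queries, X), y, k=1)
        assert [1 if l == AC else 0 for l in labels] == raw.tolist()

    def test_wrong_representation_rejected(self, clean_training_data):
        train, _, fps = clean_training_data
        acs = [lm for lm in train if lm.label == AC][:2]
        nons = [lm for lm in train if lm.label == NONAC][:2]
        subset = acs + nons
        graphs = [build_cgr(lm.mmp) for lm in subset]
        with pytest.raises(TypeError):
            train_model(
                ModelSpec.default("svm_mmp"),
                graphs,
                [lm.label for lm in subset],
            )


class TestNeuralNets:
    def test_fcnn_gradient_check(self):
        from mmpcliff.models.nn import build_mlp, weighted_ce_grad

        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        y = np.array([0, 1, 0, 1, 1, 0])
        net = build_mlp(5, (4,), np.random.default_rng(1))
        logits = net.forward(X)
        _, grad = weighted_ce_grad(logits, y, pos_weight=2.0)
        net.backward(grad)
        layer = net.layers[0]
        analytic = layer.dW.copy()
        eps = 1e-6
        for i, j in [(0, 0), (2, 1), (4, 3)]:
            layer.W[i, j] += eps
            lp, _ = weighted_ce_grad(net.forward(X), y, 2.0)
            layer.W[i, j] -= 2 * eps
            lm, _ = weighted_ce_grad(net.forward(X), y, 2.0)
            layer.W[i, j] += eps
            assert analytic[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)

    def test_mpnn_gradient_check(self, fix_mmps):
        from mmpcliff.models.nn import weighted_ce_grad

        graphs = [build_cgr(m) for m in fix_mmps[:4]]
        y = np.array([0, 1, 0, 1])
        clf = MPNNClassifier(hidden_dim=6, n_steps=2, head=(5,), epochs=0, seed=2)
        clf.fit(graphs, y)  # builds parameters; zero epochs of training
        prepared = clf._prepare_instances(graphs)

        def loss_value():
            vecs = [clf._readouts(p)[0] for p in prepared]
            logits = clf.head_.forward(np.stack(vecs))
            loss, _ = weighted_ce_grad(logits, y, 1.0)
            return loss

        clf._zero_grads()
        vecs, caches = [], []
        for p in prepared:
            v, c = clf._readouts(p)
            vecs.append(v)
            caches.append(c)
        logits = clf.head_.forward(np.stack(vecs))
        _, grad = weighted_ce_grad(logits, y, 1.0)
        dG = clf.head_.backward(grad)
        for row, cache_list in zip(dG, caches):
            for part, cache in enumerate(cache_list):
                H = clf.hidden_dim
                clf._encode_backward(row[part * H : (part + 1) * H], cache)
        eps = 1e-6
        for name in ("Wm", "We", "Wi"):
            W = getattr(clf.p_, name)
            analytic = getattr(clf.p_, "d" + name)
            i, j = 1, 2
            W[i, j] += eps
            lp = loss_value()
            W[i, j] -= 2 * eps
            lm = loss_value()
            W[i, j] += eps
            assert analytic[i, j] == pytest.approx(
                (lp - lm) / (2 * eps), rel=1e-4, abs=1e-7
            ), name

    def test_fcnn_fits_separable_toy_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        clf = FCNNClassifier(hidden=(16,), epochs=150, lr=1e-2, step_size=100, seed=0)
        clf.fit(X, y)
        acc = ((clf.predict_proba(X)[:, 1] > 0.5).astype(int) == y).mean()
        assert acc > 0.9

    def test_monotone_width_constraint(self):
        assert monotone_widths((256, 128, 64)) == (256, 128, 64)
        with pytest.raises(ValueError):
            monotone_widths((64, 128))

    @pytest.mark.parametrize("separate", [False, True])
    def test_mpnn_trains_and_predicts(self, fix_mmps, separate):
        graphs = [build_cgr(m) for m in fix_mmps]
        y = np.array([1 if m.delta >= 2.0 else 0 for m in fix_mmps])
        clf = MPNNClassifier(
            hidden_dim=12, n_steps=2, head=(8,), epochs=200, lr=1e-2,
            step_size=1000, seed=1, separate=separate,
        )
        clf.fit(graphs, y)
        prob = clf.predict_proba(graphs)
        assert prob.shape == (len(graphs), 2)
        assert np.allclose(prob.sum(axis=1), 1.0)
        acc = ((prob[:, 1] > 0.5).astype(int) == y).mean()
        assert acc > 0.9  # memorizes the small noise-free training set


class TestHyperparameterSearch:
    def test_single_trial_returns_that_sample(self, clean_training_data):
        train, _, fps = clean_training_data
        spec = ModelSpec.default("svm_mmp", hpo_trials=1, seed=8)
        best = hyperparameter_search(
            spec,
            [fps[lm.mmp.key] for lm in train],
            [lm.label for lm in train],
        )
        assert set(best) == {"C"}
        assert best["C"] in SVM_C_GRID

    def test_deterministic(self, clean_training_data):
        train, _, fps = clean_training_data
        spec = ModelSpec.default("svm_mmp", hpo_trials=5, seed=8)
        X = [fps[lm.mmp.key] for lm in train]
        y = [lm.label for lm in train]
        assert hyperparameter_search(spec, X, y) == hyperparameter_search(spec, X, y)

    def test_too_small_class_per_fold_rejected(self, clean_training_data):
        train, _, fps = clean_training_data
        acs = [lm for lm in train if lm.label == AC][:2]
        nons = [lm for lm in train if lm.label == NONAC][:10]
        subset = acs + nons
        spec = ModelSpec.default("svm_mmp", hpo_folds=3)
        with pytest.raises(ValueError):
            hyperparameter_search(
                spec,
                [fps[lm.mmp.key] for lm in subset],
                [lm.label for lm in subset],
            )
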