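import numpy as np
import pytest

from ramantdm.errors import RamanTDMError
from ramantdm.sex_classify import (
    cross_validate,
    decision_scores,
    discriminant_weighting,
    pca_reduce,
    threshold_averaged_roc,
    train_classifier,
    training_accuracy,
)


def _blobs(n=40, sep=6.0, seed=0, dims=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, dims))
    b = rng.normal(size=(n, dims))
    b[:, 0] += sep
    X = np.vstack([a, b])
    labels = np.array(["neg"] * n + ["pos"] * n)
    return X, labels


def _annulus(n=60, seed=1):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=2 * n)
    r = np.concatenate([rng.uniform(0, 0.5, n), rng.uniform(1.5, 2.0, n)])
    X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    labels = np.array(["core"] * n + ["ring"] * n)
    return X, labels


class TestPCA:
    def test_exact_2d_subspace_found_by_variance_selector(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 30))
        X = rng.normal(size=(50, 2)) @ basis
        red = pca_reduce(X, variance=0.95)
        assert red.n_pcs == 2
        assert np.isclose(red.explained_variance_ratio.sum(), 1.0)

    def test_fixed_component_count(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 30))
        red = pca_reduce(X, n_pcs=15)
        assert red.scores.shape == (40, 15)
        assert red.loadings.shape == (15, 30)

    def test_loadings_orthonormal_and_ratios_sorted(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 20))
        red = pca_reduce(X, n_pcs=5)
        assert np.allclose(red.loadings @ red.loadings.T, np.eye(5), atol=1e-10)
        assert np.all(np.diff(red.explained_variance_ratio) <= 1e-12)

    def test_full_reconstruction_is_lossless(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 8))
        red = pca_reduce(X, n_pcs=11)
        recon = red.scores @ red.loadings + red.mean
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 10))
        red = pca_reduce(X, n_pcs=3)
        for row in red.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_variance_above_one_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((4, 3)), variance=1.2)


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["lda", "svm_linear", "svm_radial"])
    def test_separable_blobs_fit_perfectly(self, kind):
        X, labels = _blobs()
        model = train_classifier(X, labels, kind)
        assert training_accuracy(model, X, labels) == 1.0

    def test_annulus_separable_only_by_radial_kernel(self):
        X, labels = _annulus()
        radial = train_classifier(X, labels, "svm_radial")
        assert training_accuracy(radial, X, labels) == 1.0
        lda = train_classifier(X, labels, "lda")
        assert training_accuracy(lda, X, labels) <= 0.65

    @pytest.mark.parametrize("kind", ["lda", "svm_linear"])
    def test_label_swap_flips_decision_scores(self, kind):
        X, labels = _blobs(seed=5)
        model = train_classifier(X, labels, kind, positive="pos")
        flipped = train_classifier(X, labels, kind, positive="neg")
        s1 = decision_scores(model, X)
        s2 = decision_scores(flipped, X)
        if kind == "lda":
            assert np.allclose(s1 + s2, 1.0, atol=1e-9)  # posteriors sum to 1
        else:
            assert np.allclose(s1, -s2, atol=1e-9)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(RamanTDMError):
            train_classifier(X, np.array(["a"] * 10), "lda")


class TestCrossValidate:
    def test_separable_classes_score_perfectly_held_out(self):
        X, labels = _blobs(n=30, seed=6)
        groups = np.repeat(np.arange(12), 5)
        out = cross_validate(X, labels, groups, "lda", k=10,
                             rng=np.random.default_rng(0))
        assert len(out) == 10
        for scores, truth in out:
            auc_hits = np.mean((scores > 0.5) == (truth == "neg"))
            assert auc_hits == 1.0  # 'neg' is the positive class (alphabetical)

    def test_null_data_scores_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 4))
        labels = np.array(["a", "b"] * 60)
        groups = np.repeat(np.arange(24), 5)
        out = cross_validate(X, labels, groups, "lda", k=20,
                             rng=np.random.default_rng(1))
        accs = [np.mean((s > 0.5) == (t == "a")) for s, t in out]
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_donor_grouping_respected_and_seed_deterministic(self):
        X, labels = _blobs(n=30, seed=8)
        groups = np.repeat(np.arange(12), 5)
        o1 = cross_validate(X, labels, groups, "svm_linear", k=5,
                            rng=np.random.default_rng(3))
        o2 = cross_validate(X, labels, groups, "svm_linear", k=5,
                            rng=np.random.default_rng(3))
        for (s1, t1), (s2, t2) in zip(o1, o2):
            assert np.array_equal(s1, s2)
            assert np.array_equal(t1, t2)
            # held-out counts are whole donors (multiples of 5 spectra)
            assert len(t1) % 5 == 0


class TestThresholdAveragedROC:
    def test_disjoint_scores_give_perfect_auc(self):
        per_repeat = [
            (np.array([0.9, 0.8, 0.2, 0.1]), np.array(["f", "f", "m", "m"])),
            (np.array([0.7, 0.6, 0.3, 0.0]), np.array(["f", "f", "m", "m"])),
        ]
        roc = threshold_averaged_roc(per_repeat, positive="f")
        assert roc.auc_mean == 1.0
        assert roc.auc_sd == 0.0
        assert np.all(np.diff(roc.mean_tpr) >= -1e-12)
        assert np.all(np.diff(roc.fpr_grid) >= -1e-12)

    def test_hand_counted_single_repeat(self):
        roc = threshold_averaged_roc(
            [(np.array([0.9, 0.8, 0.3]), np.array(["p", "p", "n"]))],
            positive="p",
        )
        assert roc.auc_mean == 1.0
        assert roc.n_repeats == 1

    def test_label_independent_scores_match_permutation_null(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=400)
        truth = np.array(["a"] * 200 + ["b"] * 200)
        roc = threshold_averaged_roc([(scores, truth)], positive="a")
        null_aucs = []
        for _ in range(1000):
            null_aucs.append(
                threshold_averaged_roc(
                    [(scores, rng.permutation(truth))], positive="a"
                ).auc_mean
            )
        null_sd = np.std(null_aucs)
        assert abs(roc.auc_mean - 0.5) < 3 * null_sd + 1e-9

    def test_auc_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=60)
        truth = np.array(["x"] * 30 + ["y"] * 30)
        a = threshold_averaged_roc([(scores, truth)], positive="x").auc_mean
        b = threshold_averaged_roc([(np.tanh(scores) * 7 + 2, truth)],
                                   positive="x").auc_mean
        assert np.isclose(a, b)

    def test_one_class_repeat_rejected(self):
        with pytest.raises(RamanTDMError):
            threshold_averaged_roc([(np.array([0.1, 0.2]),
                                     np.array(["a", "a"]))])


class TestWeightingVector:
    def test_single_informative_channel_is_the_global_extremum(self):
        rng = np.random.default_rng(11)
        n, channels = 80, 120
        wavenumbers = np.linspace(800, 1800, channels)
        X = rng.normal(size=(n, channels)) * 0.01
        labels = np.array(["a", "b"] * (n // 2))
        X[labels == "a", 60] += 1.0  # informative channel at index 60
        red = pca_reduce(X, n_pcs=5)
        lda = train_classifier(red.scores, labels, "lda")
        wv = discriminant_weighting(lda, red, wavenumbers)
        top = np.argmax(np.abs(wv.weights[0]))
        assert abs(wavenumbers[top] - wavenumbers[60]) <= 2 * (1000 / 119)

    def test_weights_stable_under_loading_sign_flip(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 50))
        labels = np.array(["a", "b"] * 30)
        X[labels == "a", 10] += 2.0
        red = pca_reduce(X, n_pcs=4)
        lda = train_classifier(red.scores, labels, "lda")
        w1 = discriminant_weighting(lda, red, np.arange(50.0)).weights
        # flip the sign convention of the reduction and retrain
        red.loadings *= -1
        red.scores *= -1
        lda2 = train_classifier(red.scores, labels, "lda")
        w2 = discriminant_weighting(lda2, red, np.arange(50.0)).weights
        assert np.allclose(np.abs(w1), np.abs(w2), atol=1e-8)

    def test_creatinine_bands_drive_pool_discrimination(self, quiet_config):
        """Pools differing only in creatinine put the discriminant extrema
        on creatinine band centers."""
        from ramantdm.core_io import SpectraSet
        from ramantdm.pipeline import PreprocessParams, preprocess_set
        from ramantdm.preprocess import normalize
        from ramantdm.synthetic_urine import (
            DonorProfile, render_replicates, rng_stream,
        )

        cfg = quiet_config
        cfg.noise_sd = 0.5  # small noise so PCA has full rank
        base = {"urea": 600.0, "creatinine": 300.0, "uric_acid": 120.0}
        spectra = []
        for i, (name, cre) in enumerate(
            [("pool_lo", 250.0), ("pool_hi", 350.0)]
        ):
            profile = DonorProfile(name, "female", {**base, "creatinine": cre})
            spectra += render_replicates(
                profile, 0.0, cfg, rng_stream(5, "pool", i), 10, name
            )
        processed = preprocess_set(SpectraSet(spectra), PreprocessParams())
        X, labels = [], []
        w = None
        for s in processed:
            t = normalize(s, "vector")
            w = t.wavenumbers
            X.append(t.intensities)
            labels.append(s.meta.sample_id)
        red = pca_reduce(np.vstack(X), n_pcs=5)
        lda = train_classifier(red.scores, np.asarray(labels), "lda")
        wv = discriminant_weighting(lda, red, w)
        top = np.argmax(np.abs(wv.weights[0]))
        creatinine_centers = np.array([850.0, 1050.0, 1525.0])
        assert np.min(np.abs(w[top] - creatinine_centers)) <= 5.0
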