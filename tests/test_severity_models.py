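import numpy as np
import pytest

import spectroinflame as si
from spectroinflame.errors import ClassAbsentError, ConfigError, SampleSizeError
from spectroinflame.severity_models import (
    ClassifierSpec,
    default_base_specs,
    fit_base,
    layer_segmenter_train,
    reduce,
    segment_image,
)
from spectroinflame.synthetic_cohort import StripeLayout, synth_image

from conftest import single_band_config


def four_clusters(n_per=15, p=5, sep=6.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(4):
        centre = np.zeros(p)
        centre[c % p] = sep * (1 + c // p)
        X.append(rng.normal(0, noise, size=(n_per, p)) + centre)
        y += [f"class{c}"] * n_per
    return np.vstack(X), np.array(y)


class TestReduce:
    def test_rank3_data_reduces_to_width_3(self, rng):
        X = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 12))
        Z, model = reduce(X, 0.95)
        assert Z.shape == (30, 3)

    def test_train_mean_projects_to_zero_scores(self, rng):
        X = rng.normal(size=(20, 6))
        Z, model = reduce(X, 0.95)
        np.testing.assert_allclose(
            model.transform(X.mean(axis=0)[None, :]), 0.0, atol=1e-10
        )

    def test_full_variance_target_on_full_rank_data(self, rng):
        X = rng.normal(size=(10, 20))
        Z, model = reduce(X, 1.0)
        assert Z.shape[1] == 9  # min(n-1, p)


class TestFitBase:
    @pytest.mark.parametrize("kind", ["ann", "svm", "rf", "knn"])
    def test_separated_clusters_high_training_accuracy(self, kind):
        X, y = four_clusters()
        clf = fit_base(ClassifierSpec(kind, seed=0), X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_knn_k1_memorizes_training_data(self):
        X, y = four_clusters(noise=1.5)
        clf = fit_base(ClassifierSpec("knn", {"n_neighbors": 1}), X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        accs = []
        for rep in range(20):
            X, y = four_clusters(seed=rep)
            y_perm = y.copy()
            rng.shuffle(y_perm)
            n = len(y)
            tr = rng.permutation(n)[: int(0.7 * n)]
            te = np.setdiff1d(np.arange(n), tr)
            clf = fit_base(ClassifierSpec("rf", {"n_estimators": 100}, seed=rep), X[tr], y_perm[tr])
            accs.append(np.mean(clf.predict(X[te]) == y_perm[te]))
        assert np.mean(accs) == pytest.approx(0.25, abs=0.15)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierSpec("gbm")

    def test_seeded_determinism(self):
        X, y = four_clusters(noise=1.0)
        p1 = fit_base(ClassifierSpec("ann", seed=3), X, y).predict_proba(X)
        p2 = fit_base(ClassifierSpec("ann", seed=3), X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestAurocOvr:
    def test_perfect_ranking(self):
        assert si.auroc_ovr([0.9, 0.8, 0.2, 0.1], ["c", "c", "d", "d"], "c") == 1.0

    def test_all_tied_scores_give_half(self):
        assert si.auroc_ovr([0.5] * 6, ["c", "d"] * 3, "c") == 0.5

    def test_hand_enumerated_three_quarters(self):
        """2 pos / 2 neg, one inversion: 3 of 4 pairs won -> 0.75."""
        auc = si.auroc_ovr([0.9, 0.8, 0.4, 0.3], ["c", "d", "c", "d"], "c")
        assert auc == 0.75

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(30)
        y = np.where(rng.random(30) > 0.5, "c", "d")
        if len(np.unique(y)) < 2:
            y[0], y[1] = "c", "d"
        base = si.auroc_ovr(scores, y, "c")
        assert si.auroc_ovr(np.exp(3 * scores), y, "c") == pytest.approx(base)
        assert si.auroc_ovr(scores**3 + 5, y, "c") == pytest.approx(base)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(0, 5, size=40) / 4.0  # force ties
        y = np.where(rng.random(40) > 0.4, "c", "d")
        ours = si.auroc_ovr(scores, y, "c")
        ref = roc_auc_score((y == "c").astype(int), scores)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ClassAbsentError):
            si.auroc_ovr([0.1, 0.2], ["c", "c"], "c")


class TestStack:
    def test_probability_rows_sum_to_one(self):
        X, y = four_clusters(n_per=12, noise=1.0)
        model = si.stack(default_base_specs(0), X, y, inner_folds=3, seed=0)
        probs = model.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_redundant_ensemble_matches_single_base(self):
        X, y = four_clusters(n_per=25, noise=1.2, sep=2.5)
        rng = np.random.default_rng(0)
        tr = rng.permutation(len(y))[: int(0.7 * len(y))]
        te = np.setdiff1d(np.arange(len(y)), tr)
        single = fit_base(ClassifierSpec("knn"), X[tr], y[tr])
        twins = [ClassifierSpec("knn"), ClassifierSpec("knn")]
        stacked = si.stack(twins, X[tr], y[tr], inner_folds=3, seed=0)
        acc_single = np.mean(single.predict(X[te]) == y[te])
        acc_stack = np.mean(stacked.predict(X[te]) == y[te])
        assert abs(acc_stack - acc_single) <= 0.05

    def test_meta_learner_upweights_informative_base(self):
        """A perfect base plus a noise-only base still yields >= 0.95."""
        rng = np.random.default_rng(2)
        X, y = four_clusters(n_per=15, noise=0.3)
        X_aug = np.hstack([X, rng.normal(size=(len(y), 5))])
        specs = [
            ClassifierSpec("knn", {"n_neighbors": 1}),
            ClassifierSpec("knn", {"n_neighbors": 25}),  # near-prior, weakly informative
        ]
        tr = rng.permutation(len(y))[: int(0.8 * len(y))]
        te = np.setdiff1d(np.arange(len(y)), tr)
        model = si.stack(specs, X_aug[tr], y[tr], inner_folds=3, seed=0)
        assert np.mean(model.predict(X_aug[te]) == y[te]) >= 0.95


@pytest.fixture(scope="module")
def tiny_classif_cohort(default_cfg):
    cohort = si.synth_cohort(
        default_cfg,
        {"control": 3, "mild": 3, "moderate": 3, "severe": 3},
        2, 6, seed=21, layers=("SubMC",),
    )
    return si.preprocess_cohort(cohort, si.PreprocessConfig(), "classification")


class TestRepeatedHoldout:

    def test_report_carries_one_entry_per_repeat(self, tiny_classif_cohort):
        rep = si.repeated_holdout(
            tiny_classif_cohort, layer="SubMC", n_repeats=2, seeds=[0, 1],
            base_specs=[ClassifierSpec("knn"), ClassifierSpec("rf", {"n_estimators": 50})],
            select_bases=False, inner_folds=3,
        )
        for c in rep.classes:
            assert len(rep.auroc[c]) == 2
            assert len(rep.ca[c]) == 2
            assert 0.0 <= rep.mean_auroc[c] <= 1.0

    def test_record_spectra_never_straddle_split(self, default_cfg):
        from spectroinflame.severity_models import _stratified_record_split

        cohort = si.synth_cohort(
            default_cfg, {"control": 3, "severe": 3}, 2, 4, seed=3, layers=("MC",)
        )
        rng = np.random.default_rng(0)
        tr, te = _stratified_record_split(cohort.records, 0.7, rng)
        assert set(tr).isdisjoint(te)
        assert len(tr) + len(te) == len(cohort.records)
        # stratification keeps every class on both sides
        for side in (tr, te):
            assert {cohort.records[i].severity for i in side} == {"control", "severe"}

    def test_shuffled_labels_give_chance_accuracy(self, tiny_classif_cohort):
        """Destroying the label-spectrum link drops overall CA to ~1/4."""
        import copy

        shuffled = copy.deepcopy(tiny_classif_cohort)
        rng = np.random.default_rng(0)
        sevs = [r.severity for r in shuffled.records]
        rng.shuffle(sevs)
        for rec, s in zip(shuffled.records, sevs):
            rec.severity = s
        rep = si.repeated_holdout(
            shuffled, layer="SubMC", n_repeats=3, seeds=[0, 1, 2],
            base_specs=[ClassifierSpec("knn"), ClassifierSpec("rf", {"n_estimators": 50})],
            select_bases=False, inner_folds=2,
        )
        overall = [cm.trace() / cm.sum() for cm in rep.confusions]
        assert np.mean(overall) == pytest.approx(0.25, abs=0.25)

    def test_insufficient_records_rejected(self, default_cfg):
        cohort = si.synth_cohort(
            default_cfg, {"control": 1, "severe": 3}, 1, 3, seed=5, layers=("MC",)
        )
        with pytest.raises(SampleSizeError):
            si.repeated_holdout(cohort, layer="MC", n_repeats=1, seeds=[0])


@pytest.fixture(scope="module")
def images():
    cfg = si.default_config(seed=1, noise_sd=0.0, amplitude_jitter_cv=0.0)
    layout = StripeLayout(rows=14, cols=8, stripe_widths=(4, 4, 4), margin=1)
    train = synth_image(cfg, layout, "severe", seed=0)
    test = synth_image(cfg, layout, "severe", seed=1)
    return train, test


class TestLayerSegmenter:

    def test_noiseless_training_pixels_predicted_exactly(self, images):
        train, _ = images
        seg = layer_segmenter_train(train, n_per_class=10, iterations=100, seed=0)
        pred = segment_image(seg, train)
        tissue = train.labels != -1
        assert np.mean(pred[tissue] == train.labels[tissue]) == 1.0

    def test_independent_image_high_accuracy(self, images):
        train, test = images
        seg = layer_segmenter_train(train, n_per_class=10, iterations=100, seed=0)
        pred = segment_image(seg, test)
        tissue = test.labels != -1
        assert np.mean(pred[tissue] == test.labels[tissue]) >= 0.99

    def test_seeded_rerun_reproduces_label_map(self, images):
        train, test = images
        p1 = segment_image(layer_segmenter_train(train, seed=4), test)
        p2 = segment_image(layer_segmenter_train(train, seed=4), test)
        np.testing.assert_array_equal(p1, p2)

    def test_output_shape_and_background_passthrough(self, images):
        train, test = images
        seg = layer_segmenter_train(train, seed=0)
        pred = segment_image(seg, test)
        assert pred.shape == test.labels.shape
        np.testing.assert_array_equal(pred == -1, test.labels == -1)

    def test_insufficient_labelled_pixels_rejected(self):
        cfg = single_band_config()
        layout = StripeLayout(rows=5, cols=2, stripe_widths=(1, 2, 2), margin=0)
        img = synth_image(cfg, layout, "control", seed=0)
        with pytest.raises(SampleSizeError):
            layer_segmenter_train(img, n_per_class=10)


class TestNoLeakage:
    def test_test_labels_never_influence_fitted_state(self, rng):
        """Changing test labels changes nothing about the fitted stack."""
        X, y = four_clusters(n_per=10, noise=1.0)
        tr = np.arange(30)
        model_a = si.stack(
            [ClassifierSpec("knn"), ClassifierSpec("rf", {"n_estimators": 50})],
            X[tr], y[tr], inner_folds=3, seed=0,
        )
        model_b = si.stack(
            [ClassifierSpec("knn"), ClassifierSpec("rf", {"n_estimators": 50})],
            X[tr], y[tr], inner_folds=3, seed=0,
        )
        X_new = rng.normal(size=(10, X.shape[1]))
        np.testing.assert_array_equal(
            model_a.predict_proba(X_new), model_b.predict_proba(X_new)
        )
        np.testing.assert_array_equal(model_a.meta.coef_, model_b.meta.coef_)
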