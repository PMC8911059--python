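"""Multi-class colitis-severity classification and layer segmentation.

The severity classifier follows a PCA-reduce -> base-learner -> stacked
ensemble design: spectra are reduced to the principal components covering a
variance target (default 95%), four base learners (ANN, SVM, RF, kNN) are
fitted on the reduced scores, per-class winners on an inner validation split
are selected, and a multinomial-logistic meta-learner is trained on their
out-of-fold class probabilities.  Evaluation uses repeated stratified 70/30
hold-outs at the sample-record level (all representative spectra of a
section stay on one side of the split), reporting per-class one-vs-rest
AUROC and classification accuracy averaged over repeats.

The hyperspectral layer segmenter is a single-hidden-layer perceptron
trained on a handful of labelled pixel spectra per bowel layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .chemometrics import PCAModel, pca_fit
from .errors import (
    AxisError,
    ClassAbsentError,
    ConfigError,
    FoldError,
    SampleSizeError,
    ShapeError,
)
from .preprocess import PreprocessConfig, preprocess_image, savitzky_golay, snv
from .spectral_core import (
    BACKGROUND,
    CODE_LAYERS,
    LAYER_ALL,
    LAYER_CODES,
    LAYERS,
    CohortSet,
    HyperspectralImage,
)

BASE_KINDS = ("ann", "svm", "rf", "knn")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BASE_KINDS:
            raise ConfigError(f"unknown classifier kind {self.kind!r}")


def default_base_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(kind, seed=seed) for kind in BASE_KINDS]


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "ann":
        return MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (100,)),
            activation=hp.pop("activation", "logistic"),
            max_iter=int(hp.pop("max_iter", 300)),
            random_state=spec.seed,
            **hp,
        )
    if spec.kind == "svm":
        return SVC(
            kernel=hp.pop("kernel", "rbf"),
            C=float(hp.pop("C", 1.0)),
            probability=True,
            random_state=spec.seed,
            **hp,
        )
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(hp.pop("n_estimators", 500)),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=spec.seed,
            **hp,
        )
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=int(hp.pop("n_neighbors", 5)), **hp)
    raise ConfigError(f"unknown classifier kind {spec.kind!r}")


class ProbabilisticClassifier:
    """Seeded wrapper exposing class probabilities on a fixed vocabulary."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._est = _build_estimator(spec)
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y) -> "ProbabilisticClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ClassAbsentError("need at least 2 classes to fit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # sklearn >= 1.9 warns that SVC(probability=True) is deprecated;
            # the pairwise-coupling probabilities are exactly what we want here
            warnings.simplefilter("ignore", FutureWarning)
            self._est.fit(np.asarray(X, dtype=float), y)
        self.classes_ = np.asarray(self._est.classes_)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=float))


def fit_base(spec: ClassifierSpec, X_reduced: np.ndarray, y) -> ProbabilisticClassifier:
    return ProbabilisticClassifier(spec).fit(X_reduced, y)


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def reduce(X: np.ndarray, variance_target: float = 0.95) -> tuple[np.ndarray, PCAModel]:
    """Fit PCA on (training) X and return its scores plus the model."""
    model = pca_fit(X, variance_target)
    return model.transform(X), model


# ---------------------------------------------------------------------------
# one-vs-rest AUROC (rank / Mann-Whitney formulation, midrank ties)
# ---------------------------------------------------------------------------

def auroc_ovr(scores, y_true, class_c) -> float:
    """One-vs-rest AUROC of ``scores`` for membership of ``class_c``."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = y_true == class_c
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassAbsentError(f"need both {class_c!r} and rest in y_true")
    ranks = rankdata(scores)  # midranks for ties
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

@dataclass
class StackedModel:
    base: list[ProbabilisticClassifier]
    meta: LogisticRegression
    classes_: np.ndarray
    pca: PCAModel | None = None

    def _base_features(self, X_reduced: np.ndarray) -> np.ndarray:
        return np.hstack([b.predict_proba(X_reduced) for b in self.base])

    def predict_proba(self, X_reduced: np.ndarray) -> np.ndarray:
        raw = self.meta.predict_proba(self._base_features(X_reduced))
        # meta classes are a permutation of the vocabulary; realign
        order = [list(self.meta.classes_).index(c) for c in self.classes_]
        return raw[:, order]

    def predict(self, X_reduced: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X_reduced), axis=1)]


def stack(
    base_specs: Sequence[ClassifierSpec],
    X_reduced: np.ndarray,
    y,
    inner_folds: int = 5,
    seed: int = 0,
) -> StackedModel:
    """Fit base learners + multinomial-logistic combiner on out-of-fold probs."""
    if len(base_specs) < 2:
        raise ConfigError("stacking needs at least 2 base specs")
    X_reduced = np.asarray(X_reduced, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < inner_folds:
        raise FoldError(
            f"class counts {counts} cannot fill {inner_folds} stratified inner folds"
        )
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    oof = np.zeros((len(y), len(base_specs) * len(classes)))
    for tr, te in skf.split(X_reduced, y):
        if len(np.unique(y[tr])) < len(classes):
            raise FoldError("an inner fold lost a class")
        for bi, spec in enumerate(base_specs):
            clf = fit_base(spec, X_reduced[tr], y[tr])
            probs = clf.predict_proba(X_reduced[te])
            cols = [list(clf.classes_).index(c) for c in classes]
            oof[te, bi * len(classes) : (bi + 1) * len(classes)] = probs[:, cols]
    meta = LogisticRegression(max_iter=2000, random_state=seed).fit(oof, y)
    bases = [fit_base(spec, X_reduced, y) for spec in base_specs]
    # final bases are refitted on all training data; align their columns too
    model = StackedModel(base=bases, meta=meta, classes_=classes)
    return model


def select_best_bases(
    specs: Sequence[ClassifierSpec],
    X_train: np.ndarray,
    y_train,
    X_val: np.ndarray,
    y_val,
) -> list[ClassifierSpec]:
    """Per-class winners by one-vs-rest AUROC on a validation split, deduped."""
    y_val = np.asarray(y_val)
    classes = np.unique(np.asarray(y_train))
    fitted = [fit_base(s, X_train, y_train) for s in specs]
    winners: list[ClassifierSpec] = []
    for c in classes:
        best, best_auc = None, -np.inf
        for spec, clf in zip(specs, fitted):
            col = list(clf.classes_).index(c)
            auc = auroc_ovr(clf.predict_proba(X_val)[:, col], y_val, c)
            if auc > best_auc:
                best, best_auc = spec, auc
        if best is not None and best not in winners:
            winners.append(best)
    if len(winners) < 2:  # stacking needs >= 2 bases; keep the runner-up kinds
        for spec in specs:
            if spec not in winners:
                winners.append(spec)
                break
    return winners


# ---------------------------------------------------------------------------
# repeated stratified hold-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    classes: list[str]
    auroc: dict[str, list[float]]  # per-class, one entry per repeat
    ca: dict[str, list[float]]
    confusions: list[np.ndarray]

    @property
    def mean_auroc(self) -> dict[str, float]:
        return {c: float(np.mean(v)) for c, v in self.auroc.items()}

    @property
    def mean_ca(self) -> dict[str, float]:
        return {c: float(np.mean(v)) for c, v in self.ca.items()}

    @property
    def macro_auroc(self) -> float:
        return float(np.mean(list(self.mean_auroc.values())))

    @property
    def macro_ca(self) -> float:
        return float(np.mean(list(self.mean_ca.values())))


def _stratified_record_split(records, train_frac: float, rng: np.random.Generator):
    """Record-level stratified shuffle split; returns (train_idx, test_idx)."""
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec.severity, []).append(i)
    train, test = [], []
    for cls, idxs in sorted(by_class.items()):
        if len(idxs) < 2:
            raise SampleSizeError(f"class {cls!r} has < 2 records; cannot stratify")
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n_train = int(round(train_frac * len(idxs)))
        n_train = min(max(n_train, 1), len(idxs) - 1)  # both sides non-empty per class
        train.extend(idxs[:n_train])
        test.extend(idxs[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


def _records_to_xy(records, record_idx):
    rows, labels, rec_ids = [], [], []
    for i in record_idx:
        rec = records[i]
        for s in rec.spectra:
            rows.append(s.absorbance)
            labels.append(rec.severity)
            rec_ids.append(i)
    return np.stack(rows), np.array(labels), np.array(rec_ids)


def repeated_holdout(
    cohort: CohortSet,
    layer: str = "SubMC",
    base_specs: Sequence[ClassifierSpec] | None = None,
    n_repeats: int = 10,
    train_frac: float = 0.7,
    variance_target: float = 0.95,
    inner_folds: int = 5,
    select_bases: bool = True,
    seeds: Sequence[int] | None = None,
) -> EvalReport:
    """Repeated stratified 70/30 hold-outs of the stacked severity model.

    Splits are stratified by severity at the SampleRecord level so that all
    representative spectra of one section stay on one side; PCA and all
    learners are fitted on the training side only.
    """
    sub = cohort.subset(layer=None if layer == LAYER_ALL else layer)
    records = sub.records
    classes = sub.severities_present()
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ConfigError("seeds must have one entry per repeat")
    auroc: dict[str, list[float]] = {c: [] for c in classes}
    ca: dict[str, list[float]] = {c: [] for c in classes}
    confusions: list[np.ndarray] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        tr_idx, te_idx = _stratified_record_split(records, train_frac, rng)
        X_tr, y_tr, _ = _records_to_xy(records, tr_idx)
        X_te, y_te, _ = _records_to_xy(records, te_idx)
        Z_tr, pca = reduce(X_tr, variance_target)
        Z_te = pca.transform(X_te)
        specs = list(base_specs) if base_specs is not None else default_base_specs(seed)
        if select_bases and len(specs) > 1:
            inner_tr, inner_val = _stratified_record_split(
                [records[i] for i in tr_idx], 0.75, rng
            )
            Xi_tr, yi_tr, _ = _records_to_xy([records[i] for i in tr_idx], inner_tr)
            Xi_va, yi_va, _ = _records_to_xy([records[i] for i in tr_idx], inner_val)
            specs = select_best_bases(specs, pca.transform(Xi_tr), yi_tr,
                                      pca.transform(Xi_va), yi_va)
        model = stack(specs, Z_tr, y_tr, inner_folds=inner_folds, seed=seed)
        probs = model.predict_proba(Z_te)
        pred = model.predict(Z_te)
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        cls_index = {c: i for i, c in enumerate(classes)}
        for t, p in zip(y_te, pred):
            cm[cls_index[t], cls_index[p]] += 1
        confusions.append(cm)
        for c in classes:
            col = list(model.classes_).index(c)
            auroc[c].append(auroc_ovr(probs[:, col], y_te, c))
            # per-class CA: one-vs-rest classification accuracy
            ca[c].append(float(np.mean((pred == c) == (y_te == c))))
    return EvalReport(classes=classes, auroc=auroc, ca=ca, confusions=confusions)


# ---------------------------------------------------------------------------
# hyperspectral layer segmentation
# ---------------------------------------------------------------------------

@dataclass
class LayerSegmenter:
    classifier: ProbabilisticClassifier
    axis_values: np.ndarray
    preprocess_cfg: PreprocessConfig


def layer_segmenter_train(
    image: HyperspectralImage,
    cfg: PreprocessConfig | None = None,
    n_per_class: int = 10,
    iterations: int = 100,
    seed: int = 0,
) -> LayerSegmenter:
    """Train a one-hidden-layer perceptron on a few labelled pixels per layer.

    Exactly ``n_per_class`` preprocessed (second-derivative, SNV) pixel
    spectra per bowel layer are used, for ``iterations`` training epochs.
    """
    if image.labels is None:
        raise ShapeError("training image carries no layer labels")
    cfg = cfg or PreprocessConfig()
    processed = preprocess_image(image, cfg, "classification")
    rng = np.random.default_rng(seed)
    X_rows, y_rows = [], []
    for layer in LAYERS:
        code = LAYER_CODES[layer]
        pix = np.argwhere(processed.labels == code)
        if len(pix) < n_per_class:
            raise SampleSizeError(f"layer {layer} has {len(pix)} pixels < {n_per_class}")
        chosen = pix[rng.choice(len(pix), size=n_per_class, replace=False)]
        for i, j in chosen:
            X_rows.append(processed.cube[i, j])
            y_rows.append(layer)
    spec = ClassifierSpec(
        "ann", {"hidden_layer_sizes": (15,), "max_iter": iterations}, seed=seed
    )
    clf = fit_base(spec, np.stack(X_rows), np.array(y_rows))
    return LayerSegmenter(clf, processed.axis.values.copy(), cfg)


def segment_image(segmenter: LayerSegmenter, image: HyperspectralImage) -> np.ndarray:
    """Per-pixel argmax layer labels; background pixels pass through as -1.

    When the image already carries labels, their background flags are
    honoured; otherwise background is detected by amide-I thresholding.
    """
    from .preprocess import _crop_image, preprocess_spectrum, remove_background
    from .spectral_core import Spectrum

    cfg = segmenter.preprocess_cfg
    cropped = _crop_image(image, cfg)
    if not np.array_equal(cropped.axis.values, segmenter.axis_values):
        raise AxisError("image axis incompatible with the trained segmenter")
    if cropped.labels is None:
        cropped = remove_background(cropped, cfg)
    rows, cols = cropped.shape
    out = np.full((rows, cols), BACKGROUND, dtype=np.int8)
    tissue = [(i, j) for i in range(rows) for j in range(cols)
              if cropped.labels[i, j] != BACKGROUND]
    if tissue:
        X = np.stack(
            [
                snv(
                    savitzky_golay(
                        Spectrum(cropped.axis, cropped.cube[i, j]),
                        cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv,
                    )
                ).absorbance
                for i, j in tissue
            ]
        )
        pred = segmenter.classifier.predict(X)
        for (i, j), layer in zip(tissue, pred):
            out[i, j] = LAYER_CODES[layer]
    return out
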