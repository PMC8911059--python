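"""PCA, PLS-DA with venetian-blind cross-validation, and VIP biomarkers.

The discriminant model is NIPALS PLS1 on mean-centered second-derivative
spectra with the two classes coded -1 / +1 and a sign threshold at 0.  The
variable-importance-in-projection score for wavenumber j is

    VIP_j = sqrt( p * sum_a SSY_a * (w_aj / ||w_a||)^2 / sum_a SSY_a )

where ``SSY_a = q_a^2 * t_a.t_a`` is the y-variance captured by component a
and ``w_a`` the x-weight vector; the mean of squared VIP scores is exactly 1,
and scores above 1 are conventionally significant.

Cross-validation uses venetian blinds: samples are ordered by class (then
original index) and fold f takes every ``n_blinds``-th sample starting at f,
which keeps folds class-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .band_quant import WelchResult, integrate_band, welch_test
from .errors import (
    ClassAbsentError,
    ConfigError,
    DegenerateError,
    FoldError,
    SampleSizeError,
    ShapeError,
)
from .preprocess import BandDefinition
from .spectral_core import LAYER_ALL, CohortSet, WavenumberAxis


@dataclass
class SpectraMatrix:
    """Preprocessed spectra as rows, with per-row labels and provenance."""

    X: np.ndarray  # n_samples x n_wavenumbers
    y: np.ndarray  # n_samples, string labels
    sample_meta: list[tuple[str, str, str]]  # (animal, section, layer)
    axis: WavenumberAxis | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ShapeError("X rows and labels must match")
        if not np.all(np.isfinite(self.X)):
            raise ShapeError("X contains non-finite values")
        if len(self.y) == 0:
            raise ShapeError("empty matrix")


def cohort_to_matrix(
    cohort: CohortSet, layer: str = LAYER_ALL, severities=None
) -> SpectraMatrix:
    """Stack a (preprocessed) cohort's representative spectra into a matrix."""
    sub = cohort.subset(layer=None if layer == LAYER_ALL else layer, severities=severities)
    rows, labels, meta = [], [], []
    for rec in sub.records:
        for s in rec.spectra:
            rows.append(s.absorbance)
            labels.append(rec.severity)
            meta.append((rec.animal_id, rec.section_id, rec.layer))
    return SpectraMatrix(np.stack(rows), np.array(labels), meta, axis=sub.axis)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # n_components x p, orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings + self.mean


def pca_fit(X: np.ndarray, variance_target: float = 0.95) -> PCAModel:
    """Mean-centered PCA keeping the fewest components reaching the target."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ShapeError("PCA needs at least 2 samples")
    if not (0.0 < variance_target <= 1.0):
        raise ConfigError("variance_target must be in (0, 1]")
    if np.allclose(X, X[0]):
        raise DegenerateError("constant matrix has no principal components")
    max_k = min(X.shape[0] - 1, X.shape[1])
    sk = _SKPCA(n_components=max_k, svd_solver="full").fit(X)
    cum = np.cumsum(sk.explained_variance_ratio_)
    # rounding can leave cum slightly under 1 even for exact low rank
    k = int(np.searchsorted(np.minimum(cum, 1.0), variance_target - 1e-12) + 1)
    k = min(k, max_k)
    return PCAModel(
        mean=sk.mean_,
        loadings=sk.components_[:k],
        explained_variance_ratio=sk.explained_variance_ratio_[:k],
        n_components=k,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # n_lv x p, unit rows (W)
    x_loadings: np.ndarray  # n_lv x p (P)
    x_scores: np.ndarray  # n x n_lv (T)
    y_loadings: np.ndarray  # n_lv (Q)
    coef: np.ndarray  # p, maps centered spectrum to score (B)
    classes: tuple[str, str]  # (negative, positive)
    vip: np.ndarray = field(default=None)  # per-wavenumber VIP scores

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.coef + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X) >= 0.0, self.classes[1], self.classes[0])


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Returns (W, P, T, Q) for mean-centered X and y."""
    n, p = Xc.shape
    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    T = np.zeros((n, n_lv))
    Q = np.zeros(n_lv)
    Xa = Xc.copy()
    ya = yc.astype(float).copy()
    for a in range(n_lv):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0.0:
            raise DegenerateError("y carries no covariance with X at component "
                                  f"{a + 1}; reduce n_lv")
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt == 0.0:
            raise DegenerateError(f"zero-variance score at component {a + 1}")
        p_load = (Xa.T @ t) / tt
        q = float(ya @ t) / tt
        Xa -= np.outer(t, p_load)
        ya -= q * t
        W[a], P[a], T[:, a], Q[a] = w, p_load, t, q
    return W, P, T, Q


def _pls_coef(W: np.ndarray, P: np.ndarray, Q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector using the first k components: B = W (P' W)^-1 Q."""
    Wk, Pk, Qk = W[:k].T, P[:k].T, Q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, Qk)


def plsda_fit(X: np.ndarray, y, n_lv: int, positive_class: str | None = None) -> PLSDAModel:
    """Fit a binary PLS-DA model; class labels are taken from ``y``.

    The positive (+1-coded) class defaults to the lexicographically larger
    label, which puts "severe" positive against "control".
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ClassAbsentError(f"binary PLS-DA needs exactly 2 classes, got {classes}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise ClassAbsentError(f"positive class {positive_class!r} not in {classes}")
    negative_class = classes[0] if positive_class == classes[1] else classes[1]
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_lv <= max_lv):
        raise ConfigError(f"n_lv must be in [1, {max_lv}]")
    y_num = np.where(y == positive_class, 1.0, -1.0)
    x_mean = X.mean(axis=0)
    y_mean = float(y_num.mean())
    W, P, T, Q = _nipals_pls1(X - x_mean, y_num - y_mean, n_lv)
    model = PLSDAModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=Q,
        coef=_pls_coef(W, P, Q, n_lv),
        classes=(negative_class, positive_class),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection; mean of squares is exactly 1."""
    ssy = model.y_loadings**2 * np.einsum("ia,ia->a", model.x_scores, model.x_scores)
    total = float(ssy.sum())
    if total <= 0.0:
        raise DegenerateError("model explains no y-variance; VIP undefined")
    p = model.weights.shape[1]
    # weight rows are unit vectors, so w_aj / ||w_a|| is just w_aj
    return np.sqrt(p * (ssy @ model.weights**2) / total)


# ---------------------------------------------------------------------------
# venetian-blind cross-validation and LV selection
# ---------------------------------------------------------------------------

def venetian_blind_folds(y, n_blinds: int) -> list[np.ndarray]:
    """Interleaved folds over a class-sorted ordering (class-balanced blinds)."""
    y = np.asarray(y)
    if n_blinds < 2:
        raise ConfigError("n_blinds must be >= 2")
    order = np.lexsort((np.arange(len(y)), y))
    return [order[f::n_blinds] for f in range(n_blinds)]


def venetian_cv(
    X: np.ndarray, y, max_lv: int, n_blinds: int = 10,
    positive_class: str | None = None,
) -> list[tuple[int, float]]:
    """Pooled misclassification rate for every LV count 1..max_lv."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = venetian_blind_folds(y, n_blinds)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ClassAbsentError("venetian_cv handles the binary task")
    errors = np.zeros(max_lv)
    for fold in folds:
        test_mask = np.zeros(len(y), dtype=bool)
        test_mask[fold] = True
        y_train = y[~test_mask]
        if len(np.unique(y_train)) < 2 or len(np.unique(y[test_mask])) < 1:
            raise FoldError("a fold lost an entire class; reduce n_blinds")
        Xtr, Xte = X[~test_mask], X[test_mask]
        cap = min(max_lv, Xtr.shape[0] - 1, Xtr.shape[1])
        if cap < max_lv:
            raise ConfigError(f"max_lv {max_lv} too large for fold of {Xtr.shape[0]} samples")
        full = plsda_fit(Xtr, y_train, max_lv, positive_class=positive_class)
        for k in range(1, max_lv + 1):
            coef_k = _pls_coef(full.weights, full.x_loadings, full.y_loadings, k)
            scores = (Xte - full.x_mean) @ coef_k + full.y_mean
            pred = np.where(scores >= 0, full.classes[1], full.classes[0])
            errors[k - 1] += int(np.sum(pred != y[test_mask]))
    errors /= len(y)
    return [(k + 1, float(errors[k])) for k in range(max_lv)]


def select_n_lv(cv_curve) -> int:
    """Smallest LV count achieving the global minimum CV error."""
    if not cv_curve:
        raise ShapeError("empty CV curve")
    errs = [e for _, e in cv_curve]
    best = min(errs)
    for n_lv, e in cv_curve:
        if e == best:
            return n_lv
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryEval:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def evaluate_binary(model: PLSDAModel, X_test, y_test, positive_class: str | None = None) -> BinaryEval:
    """Confusion, sensitivity and specificity with colitis as positive."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise SampleSizeError("empty test set")
    if positive_class is None:
        positive_class = model.classes[1]
    pred = model.predict(np.asarray(X_test, dtype=float))
    pos = y_test == positive_class
    pred_pos = pred == positive_class
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return BinaryEval(tp, fn, tn, fp, sens, spec)


# ---------------------------------------------------------------------------
# follow-up Welch tests on VIP-significant bands
# ---------------------------------------------------------------------------

def vip_significant_runs(vip: np.ndarray, threshold: float = 1.0) -> list[np.ndarray]:
    """Contiguous index runs where VIP exceeds the threshold."""
    above = np.asarray(vip) > threshold
    runs: list[np.ndarray] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append(np.arange(start, i))
            start = None
    if start is not None:
        runs.append(np.arange(start, len(above)))
    return runs


def vip_band_tests(
    cohort: CohortSet,
    vip: np.ndarray,
    axis: WavenumberAxis,
    class_a: str = "severe",
    class_b: str = "control",
    layer: str = LAYER_ALL,
    threshold: float = 1.0,
) -> list[tuple[BandDefinition | float, WelchResult]]:
    """Welch tests on every VIP-significant wavenumber run.

    Runs of >= 2 points become integration bands (area per record); isolated
    points are compared at peak intensity.  The cohort must be preprocessed
    in quantification mode.  Returns an empty list when nothing exceeds the
    threshold.
    """
    vip = np.asarray(vip)
    if len(vip) != len(axis):
        raise ShapeError("VIP vector does not align with the axis")
    sub_a = cohort.subset(layer=None if layer == LAYER_ALL else layer, severities=[class_a])
    sub_b = cohort.subset(layer=None if layer == LAYER_ALL else layer, severities=[class_b])
    results: list[tuple[BandDefinition | float, WelchResult]] = []
    for run in vip_significant_runs(vip, threshold):
        nus = axis.values[run]
        if len(run) >= 2:
            band = BandDefinition(f"vip_{nus.min():.0f}_{nus.max():.0f}", float(nus.max()), float(nus.min()))
            a_vals = [
                float(np.mean([integrate_band(s, band) for s in rec.spectra]))
                for rec in sub_a.records
            ]
            b_vals = [
                float(np.mean([integrate_band(s, band) for s in rec.spectra]))
                for rec in sub_b.records
            ]
            results.append((band, welch_test(a_vals, b_vals)))
        else:
            idx = int(run[0])
            a_vals = [float(np.mean([s.absorbance[idx] for s in rec.spectra])) for rec in sub_a.records]
            b_vals = [float(np.mean([s.absorbance[idx] for s in rec.spectra])) for rec in sub_b.records]
            results.append((float(nus[0]), welch_test(a_vals, b_vals)))
    return results
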