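"""Classification, cross-validation and the shift-evaluation protocol.

LDA — class means with a pooled, ridge-stabilized within-class covariance —
is the workhorse classifier for CSP, TD and TDAR features; variogram
features pair with an RBF-kernel SVM.  The shift protocol trains the entire
pipeline (CSP filters, classifier, and any FLD used for RCS) on the training
channel partition only and evaluates on the congruent, one-pitch-displaced
test partition of the same recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import DataError, InvalidArgumentError, NumericalError
from .extract import FeatureSpec, make_pipeline
from .features import FeatureMatrix, segment
from .grid import ShiftScheme
from .io import LabeledRecording
from .rcs import compute_rcs, fit_fld

__all__ = [
    "LDAModel",
    "SVMModel",
    "ClassifierSpec",
    "WindowingConfig",
    "CVResult",
    "ShiftEvaluation",
    "fit_lda",
    "fit_svm",
    "make_classifier",
    "cross_validate",
    "evaluate_shift",
]

LDA_RIDGE = 1e-6


@dataclass
class WindowingConfig:
    """Analysis-window geometry (defaults: ~200 ms / ~50 ms at 2048 Hz)."""

    win_samples: int = 408
    inc_samples: int = 102


@dataclass
class ClassifierSpec:
    """Classifier choice and hyperparameters.

    ``kind=None`` defers to the feature family's conventional pairing
    (SVM for variogram features, LDA otherwise).  SVM defaults are C=1 with
    the 1/(d * feature variance) kernel width; no grid search is run unless
    asked for explicitly.
    """

    kind: "str | None" = None
    ridge: float = LDA_RIDGE
    priors: str = "empirical"  # or "equal"
    C: float = 1.0
    gamma: "str | float" = "scale"


@dataclass
class LDAModel:
    """Gaussian LDA with pooled within-class covariance."""

    class_means: np.ndarray          # (N, d)
    pooled_covariance: np.ndarray    # (d, d)
    priors: np.ndarray               # (N,)
    class_labels: np.ndarray         # (N,)
    _coef: np.ndarray = field(repr=False, default=None)       # (N, d)
    _intercept: np.ndarray = field(repr=False, default=None)  # (N,)

    def predict(self, values: np.ndarray) -> np.ndarray:
        scores = values @ self._coef.T + self._intercept
        # argmax takes the first maximum: ties break to the lowest class index
        return self.class_labels[np.argmax(scores, axis=1)]


def fit_lda(features: FeatureMatrix, ridge: float = LDA_RIDGE,
            priors: str = "empirical") -> LDAModel:
    """Fit LDA with ``1/(n - N)`` pooled covariance plus a trace-scaled ridge.

    Discriminant scores are ``x' S^{-1} m_k - m_k' S^{-1} m_k / 2 +
    log pi_k`` with empirical (default) or equal priors; prediction takes
    the highest score, ties to the lowest class index.
    """
    x, labels = features.values, np.asarray(features.labels)
    classes = np.unique(labels)
    n, d = x.shape
    if len(classes) < 2:
        raise DataError("LDA needs at least 2 classes")
    means = np.empty((len(classes), d))
    pooled = np.zeros((d, d))
    counts = np.empty(len(classes))
    for i, c in enumerate(classes):
        xc = x[labels == c]
        if xc.shape[0] < 2:
            raise DataError(f"class {c} has fewer than 2 windows")
        means[i] = xc.mean(axis=0)
        cen = xc - means[i]
        pooled += cen.T @ cen
        counts[i] = xc.shape[0]
    pooled /= n - len(classes)
    pooled += (ridge * np.trace(pooled) / d) * np.eye(d)
    if priors == "empirical":
        pi = counts / n
    elif priors == "equal":
        pi = np.full(len(classes), 1.0 / len(classes))
    else:
        raise InvalidArgumentError(f"unknown priors mode {priors!r}")
    try:
        cho = scipy.linalg.cho_factor(pooled)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            "pooled covariance singular; raise the LDA ridge"
        ) from exc
    coef = scipy.linalg.cho_solve(cho, means.T).T  # (N, d)
    intercept = -0.5 * np.sum(coef * means, axis=1) + np.log(pi)
    return LDAModel(class_means=means, pooled_covariance=pooled, priors=pi,
                    class_labels=classes, _coef=coef, _intercept=intercept)


@dataclass
class SVMModel:
    """RBF-kernel SVM satisfying the same predict contract as LDA."""

    svc: "Pipeline" = field(repr=False)
    class_labels: np.ndarray = None

    def predict(self, values: np.ndarray) -> np.ndarray:
        return self.svc.predict(values)


def fit_svm(features: FeatureMatrix, C: float = 1.0,
            gamma: "str | float" = "scale") -> SVMModel:
    """Fit a multiclass soft-margin RBF SVM (deterministic given the data).

    Features are standardized to zero mean / unit variance on the training
    set before the kernel, the conventional preprocessing for RBF SVMs on
    heterogeneous-scale features.
    """
    x, labels = features.values, np.asarray(features.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError("SVM needs at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise DataError(f"class {c} has fewer than 2 windows")
    svc = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=C, gamma=gamma, random_state=0)),
    ])
    svc.fit(x, labels)
    return SVMModel(svc=svc, class_labels=classes)


def svm_grid_search(features: FeatureMatrix,
                    C_grid=(0.1, 1.0, 10.0, 100.0),
                    gamma_grid=("scale", 0.01, 0.1, 1.0),
                    k: int = 3, seed: int = 0) -> ClassifierSpec:
    """Small exhaustive CV search for SVM hyperparameters (off by default)."""
    best, best_acc = None, -1.0
    for C in C_grid:
        for gamma in gamma_grid:
            spec = ClassifierSpec(kind="svm", C=C, gamma=gamma)
            acc = cross_validate(features, k=k, seed=seed,
                                 classifier=spec).mean_accuracy
            if acc > best_acc:
                best, best_acc = spec, acc
    return best


def make_classifier(spec: ClassifierSpec, feature_kind: str):
    """Bind a classifier spec to a fit function; resolves ``kind=None``."""
    kind = spec.kind or ("svm" if feature_kind == "Variog" else "lda")
    if kind == "lda":
        return lambda fm: fit_lda(fm, ridge=spec.ridge, priors=spec.priors)
    if kind == "svm":
        return lambda fm: fit_svm(fm, C=spec.C, gamma=spec.gamma)
    raise InvalidArgumentError(f"unknown classifier kind {kind!r}")


@dataclass
class CVResult:
    mean_accuracy: float
    fold_accuracies: np.ndarray
    confusion: np.ndarray
    class_labels: np.ndarray


def cross_validate(
    features: FeatureMatrix,
    k: int = 5,
    grouping: str = "window",
    seed: int = 0,
    classifier: "ClassifierSpec | None" = None,
) -> CVResult:
    """Stratified k-fold cross-validation over analysis windows.

    ``grouping="window"`` assigns windows to folds at random (the
    conventional protocol, though overlapping windows make it optimistic);
    ``grouping="trial"`` keeps each trial's windows inside one fold,
    preventing adjacent-window leakage.  Deterministic under ``seed``.
    """
    if k < 2:
        raise InvalidArgumentError(f"k must be >= 2, got {k}")
    classifier = classifier or ClassifierSpec()
    labels = np.asarray(features.labels)
    classes = np.unique(labels)
    fit = make_classifier(classifier, features.feature_kind)
    if grouping == "window":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(features.values, labels)
    elif grouping == "trial":
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        splits = splitter.split(features.values, labels, features.trial_ids)
    else:
        raise InvalidArgumentError(f"unknown grouping {grouping!r}")

    accs = []
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for train_idx, test_idx in splits:
        if len(np.unique(labels[train_idx])) < len(classes):
            raise DataError("a class is absent from a training fold")
        model = fit(_subset(features, train_idx))
        pred = model.predict(features.values[test_idx])
        truth = labels[test_idx]
        accs.append(float(np.mean(pred == truth)))
        pooled += confusion_matrix(truth, pred, labels=classes)
    return CVResult(
        mean_accuracy=float(np.mean(accs)),
        fold_accuracies=np.asarray(accs),
        confusion=pooled,
        class_labels=classes,
    )


def _subset(features: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=features.values[idx],
        labels=np.asarray(features.labels)[idx],
        trial_ids=np.asarray(features.trial_ids)[idx],
        feature_names=features.feature_names,
        feature_kind=features.feature_kind,
    )


@dataclass
class ShiftEvaluation:
    """Outcome of one (feature set x shift scheme) evaluation."""

    feature_kind: str
    scheme: str
    accuracy: float
    confusion: np.ndarray
    class_labels: np.ndarray
    n_train: int
    n_test: int
    rcs: "float | None" = None
    fold_accuracies: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        total = int(self.confusion.sum())
        if total != self.n_test:
            raise InvalidArgumentError(
                f"confusion total {total} != n_test {self.n_test}"
            )


def evaluate_shift(
    recording: LabeledRecording,
    scheme: ShiftScheme,
    feature_spec: FeatureSpec,
    classifier_spec: "ClassifierSpec | None" = None,
    windowing: "WindowingConfig | None" = None,
    cv_folds: int = 5,
    cv_grouping: str = "window",
    seed: int = 0,
    with_rcs: bool = True,
    window_cache: "dict | None" = None,
) -> ShiftEvaluation:
    """Evaluate one feature set under one shift configuration.

    Shifted schemes: the pipeline (CSP filters included), the classifier and
    the FLD projection are fitted on training-partition windows only; test
    windows come from the displaced partition over the same time segments.
    Control schemes (identical partitions) are scored by stratified k-fold
    cross-validation instead, and carry no RCS.

    RCS is reported for every feature family except the variogram, whose
    SVM pairing has no LDA-compatible discriminant geometry to project with.

    ``window_cache`` (a plain dict) memoizes segmented windows per channel
    partition across repeated calls on the same recording.
    """
    windowing = windowing or WindowingConfig()
    classifier_spec = classifier_spec or ClassifierSpec()
    max_chan = max(max(scheme.train_channels), max(scheme.test_channels))
    if max_chan >= recording.n_channels:
        raise InvalidArgumentError(
            "recording does not cover the scheme's channel partitions"
        )

    def _windows(channels):
        if window_cache is None:
            return segment(recording, windowing.win_samples,
                           windowing.inc_samples, channels)
        key = (channels, windowing.win_samples, windowing.inc_samples)
        if key not in window_cache:
            window_cache[key] = segment(recording, windowing.win_samples,
                                        windowing.inc_samples, channels)
        return window_cache[key]

    train_ws = _windows(scheme.train_channels)
    pipeline = make_pipeline(feature_spec, recording.grid)
    if scheme.is_control:
        pipeline.fit(train_ws)
        fm = pipeline.transform(train_ws)
        cv = cross_validate(fm, k=cv_folds, grouping=cv_grouping, seed=seed,
                            classifier=classifier_spec)
        return ShiftEvaluation(
            feature_kind=feature_spec.kind,
            scheme=scheme.name,
            accuracy=cv.mean_accuracy,
            confusion=cv.confusion,
            class_labels=cv.class_labels,
            n_train=fm.values.shape[0],
            n_test=int(cv.confusion.sum()),
            rcs=None,
            fold_accuracies=cv.fold_accuracies,
        )

    if len(scheme.train_channels) != len(scheme.test_channels):
        raise InvalidArgumentError("train/test partitions differ in size")
    test_ws = _windows(scheme.test_channels)
    pipeline.fit(train_ws)
    fm_train = pipeline.transform(train_ws)
    fm_test = pipeline.transform(test_ws)
    model = make_classifier(classifier_spec, feature_spec.kind)(fm_train)
    pred = model.predict(fm_test.values)
    truth = np.asarray(fm_test.labels)
    classes = np.unique(np.asarray(fm_train.labels))
    conf = confusion_matrix(truth, pred, labels=classes)
    rcs_value = None
    if with_rcs and feature_spec.kind != "Variog":
        fld = fit_fld(fm_train)
        rcs_value = compute_rcs(fm_train, fm_test, fld).value
    return ShiftEvaluation(
        feature_kind=feature_spec.kind,
        scheme=scheme.name,
        accuracy=float(np.mean(pred == truth)),
        confusion=conf,
        class_labels=classes,
        n_train=fm_train.values.shape[0],
        n_test=fm_test.values.shape[0],
        rcs=rcs_value,
    )
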