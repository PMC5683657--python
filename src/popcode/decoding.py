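"""Stimulus-identity decoders for single-trial population responses.

Three population decoding strategies are provided, all template-style
classifiers that assign a test response to the stimulus whose training-set
mean is nearest:

- ``lda``:    PCA (components retaining >= 90% training variance) followed
              by linear discriminant analysis; distance measured to class
              means in the discriminant space.
- ``tmpeuc``: template matching with Euclidean distance in the raw rate
              space.
- ``tmpcos``: template matching with angular distance
              1 - <a, b> / (||a|| ||b||), scale-invariant.

A single-neuron variant decodes from scalar rates with absolute-difference
template matching.  Cross-validation follows a 4-fold scheme (contiguous
blocks of trials per stimulus, 15 train / 5 test with 20 trials) or random
15/5 splits repeated many times.

Ties at equal distance resolve to the lowest stimulus index.  A test
vector with zero norm under the angular metric is assigned distance 1 to
every template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import SpikeTrainSet, ValidationError, Window, population_response

__all__ = [
    "METHODS",
    "DecoderModel",
    "DecodingResult",
    "fit_template",
    "fit_lda",
    "fit_decoder",
    "classify",
    "cross_validated_accuracy",
    "random_split_accuracy",
    "single_neuron_accuracy",
    "cv_accuracy_from_responses",
    "responses_by_trial",
]

METHODS = ("lda", "tmpeuc", "tmpcos")


@dataclass
class DecoderModel:
    """A fitted decoder: per-stimulus templates plus an optional projection."""

    method: str
    classes: np.ndarray  # stimulus ids, ascending
    templates: np.ndarray  # (n_classes, d) in decoder space
    pca: PCA | None = None
    lda: LinearDiscriminantAnalysis | None = None
    degenerate: bool = False  # training data had no variance

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.pca is not None:
            X = self.pca.transform(X)
        if self.lda is not None:
            X = self.lda.transform(X)
        return X


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy with per-fold detail."""

    accuracy: float
    fold_accuracies: np.ndarray
    confusion: np.ndarray  # (n_classes, n_classes): true x predicted counts
    n_test: int
    method: str
    window: Window | None = None


def _check_training_set(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (n_trials, d) aligned with y")
    return X


def fit_template(X: np.ndarray, y: np.ndarray, method: str = "tmpeuc") -> DecoderModel:
    """Per-stimulus mean-response templates (Euclidean or angular matching)."""
    X = _check_training_set(X, y)
    classes = np.unique(y)
    templates = np.vstack([X[y == c].mean(axis=0) for c in classes])
    return DecoderModel(method=method, classes=classes, templates=templates)


def fit_lda(X: np.ndarray, y: np.ndarray, var_frac: float = 0.9) -> DecoderModel:
    """PCA (>= ``var_frac`` cumulative variance) then LDA; nearest class mean.

    The PCA is centred on the training data only; test samples must be
    pushed through the same stored transforms.  If the training matrix has
    (numerically) no variance the model degenerates to constant templates,
    which classify every sample to the lowest stimulus index.
    """
    X = _check_training_set(X, y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("LDA needs at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError("LDA needs at least 2 training trials per class")
    total_var = X.var(axis=0).sum()
    if total_var <= 1e-12:
        templates = np.vstack([X[y == c].mean(axis=0) for c in classes])
        return DecoderModel(
            method="lda", classes=classes, templates=templates, degenerate=True
        )
    max_rank = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=min(var_frac, 1.0), svd_solver="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = pca.fit_transform(X)
        n_disc = min(classes.size - 1, Z.shape[1])
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_disc)
        lda.fit(Z, y)
        D = lda.transform(Z)
    templates = np.vstack([D[y == c].mean(axis=0) for c in classes])
    return DecoderModel(
        method="lda", classes=classes, templates=templates, pca=pca, lda=lda
    )


def fit_decoder(X: np.ndarray, y: np.ndarray, method: str) -> DecoderModel:
    if method == "lda":
        return fit_lda(X, y)
    if method in ("tmpeuc", "tmpcos", "single"):
        return fit_template(X, y, method=method)
    raise ValidationError(f"unknown decoding method {method!r}")


def _distances(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Distance of each row of X to each template, (n, n_classes)."""
    T = model.templates
    if model.method in ("lda", "tmpeuc", "single") or model.degenerate:
        diff = X[:, None, :] - T[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if model.method == "tmpcos":
        xn = np.linalg.norm(X, axis=1)
        tn = np.linalg.norm(T, axis=1)
        denom = xn[:, None] * tn[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = (X @ T.T) / denom
        cos = np.where(denom > 0, cos, 0.0)  # zero-norm vector: distance 1 everywhere
        return 1.0 - cos
    raise ValidationError(f"unknown decoding method {model.method!r}")


def classify(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Predicted stimulus id for each response vector (row of X).

    Ties at equal distance resolve to the lowest stimulus index (argmin
    returns the first minimum).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.method == "lda" and not model.degenerate:
        X = model.transform(X)
    d = _distances(model, X)
    return model.classes[np.argmin(d, axis=1)]


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------


def responses_by_trial(data: SpikeTrainSet, window: Window) -> np.ndarray:
    """Single-trial population rate vectors, shape (n_stimuli, n_trials, n_neurons)."""
    X, _ = population_response(data, window)
    return X.reshape(data.stimuli.n_stimuli, data.n_trials, data.n_neurons)


def cv_accuracy_from_responses(
    R: np.ndarray, method: str, n_folds: int = 4, window: Window | None = None
) -> DecodingResult:
    """4-fold cross-validated accuracy from an (S, T, d) response array.

    Folds are contiguous blocks of trials per stimulus (trials 0-4, 5-9,
    ... with 20 trials and 4 folds); each fold is tested with a decoder
    trained on the remaining trials.
    """
    S, T, d = R.shape
    if T < n_folds:
        raise ValidationError(f"need at least {n_folds} trials, got {T}")
    if T % n_folds:
        raise ValidationError(f"{T} trials do not divide into {n_folds} folds")
    block = T // n_folds
    fold_acc = np.empty(n_folds)
    confusion = np.zeros((S, S), dtype=np.int64)
    labels = np.repeat(np.arange(S), T - block)
    test_labels = np.repeat(np.arange(S), block)
    for k in range(n_folds):
        test_idx = np.arange(k * block, (k + 1) * block)
        train_idx = np.setdiff1d(np.arange(T), test_idx)
        Xtr = R[:, train_idx, :].reshape(S * (T - block), d)
        Xte = R[:, test_idx, :].reshape(S * block, d)
        model = fit_decoder(Xtr, labels, method)
        pred = classify(model, Xte)
        fold_acc[k] = float((pred == test_labels).mean())
        np.add.at(confusion, (test_labels, pred), 1)
    return DecodingResult(
        accuracy=float(fold_acc.mean()),
        fold_accuracies=fold_acc,
        confusion=confusion,
        n_test=S * T,
        method=method,
        window=window,
    )


def cross_validated_accuracy(
    data: SpikeTrainSet, window: Window, method: str, n_folds: int = 4
) -> DecodingResult:
    """4-fold cross-validated population decoding accuracy in one window."""
    R = responses_by_trial(data, window)
    return cv_accuracy_from_responses(R, method, n_folds=n_folds, window=window)


def random_split_accuracy(
    data: SpikeTrainSet,
    window: Window,
    method: str,
    n_runs: int = 1000,
    n_train: int = 15,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Accuracy over repeated random train/test splits (15/5 per stimulus).

    Returns (mean, sd, per-run accuracies).  Runs are seeded and
    reproducible; note that splits of the same data set are not
    independent measurements.
    """
    R = responses_by_trial(data, window)
    S, T, d = R.shape
    if not (0 < n_train < T):
        raise ValidationError("n_train must be strictly between 0 and n_trials")
    rng = np.random.default_rng(seed)
    n_test = T - n_train
    labels_tr = np.repeat(np.arange(S), n_train)
    labels_te = np.repeat(np.arange(S), n_test)
    accs = np.empty(n_runs)
    for r in range(n_runs):
        perm = np.argsort(rng.random((S, T)), axis=1)
        tr, te = perm[:, :n_train], perm[:, n_train:]
        Xtr = np.concatenate([R[s, tr[s]] for s in range(S)])
        Xte = np.concatenate([R[s, te[s]] for s in range(S)])
        model = fit_decoder(Xtr, labels_tr, method)
        accs[r] = float((classify(model, Xte) == labels_te).mean())
    return float(accs.mean()), float(accs.std(ddof=1)), accs


def single_neuron_accuracy(
    data: SpikeTrainSet, neuron: int, window: Window, n_folds: int = 4
) -> DecodingResult:
    """Template decoding from one neuron's scalar rates (absolute difference)."""
    idx = data.neurons.index(neuron)
    counts = data.count_matrix([window])[idx, :, :, 0]  # (S, T)
    R = (counts * (1000.0 / window.length))[:, :, None]  # (S, T, 1)
    res = cv_accuracy_from_responses(R, "single", n_folds=n_folds, window=window)
    res.method = "single"
    return res
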