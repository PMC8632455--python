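"""Fully connected neural-network classification of preprocessed spectra.

The classifier is a small multilayer perceptron — input layer on the
1,201-point fingerprint grid, two hidden layers of 64 relu units with
dropout, and a 2-unit softmax output — trained by mini-batch Adam on the
cross-entropy loss until the training loss falls below an error threshold
(1% by default) or a maximum epoch count is reached. Training, splitting
and cross-validation are all deterministic given the configured seed, and
every split keeps all replicates of a biological sample on one side.

Evaluation follows three protocols: a stratified 4:1 hold-out with a
confusion matrix and per-class precision/sensitivity/F1, leave-one-out
cross-validation, and five-fold cross-validation summarized by ROC AUC,
sensitivity and specificity at the 0.5 probability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from ramanff.errors import TrainingError, ValidationError
from ramanff.spectra import SampleMeta, SpectrumSet, average_replicates
from ramanff.zones import resolve_positive_class


@dataclass(frozen=True)
class ANNConfig:
    """Architecture and training hyperparameters of the classifier.

    ``error_threshold`` stops training when the full-training-set
    cross-entropy drops to or below it (``threshold_mode="loss"``), or,
    alternatively, when the training misclassification rate does
    (``threshold_mode="error_rate"``).
    """

    hidden_sizes: tuple[int, ...] = (64, 64)
    dropout_rate: float = 0.2
    activation: str = "relu"
    learning_rate: float = 0.001
    batch_size: int = 16
    max_epochs: int = 500
    error_threshold: float = 0.01
    threshold_mode: str = "loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.error_threshold <= 0:
            raise ValidationError("error_threshold must be > 0")
        if self.activation != "relu":
            raise ValidationError("only relu activation is supported")
        if self.threshold_mode not in ("loss", "error_rate"):
            raise ValidationError("threshold_mode must be 'loss' or 'error_rate'")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValidationError("hidden sizes must be >= 1")


@dataclass
class TrainedModel:
    """Trained MLP: layer weights, the config used, and the loss history."""

    weights: list[tuple[np.ndarray, np.ndarray]]
    config: ANNConfig
    input_width: int
    classes: tuple[str, str]  # (negative, positive); proba column 1 = positive
    training_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts for a designated positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassReport:
    """Per-class precision/sensitivity/F1 plus overall accuracy.

    ``per_class`` maps each class label to a dict with keys ``precision``,
    ``sensitivity`` and ``f1``; an undefined (0/0) metric is ``None``.
    """

    per_class: dict[str, dict[str, float | None]]
    accuracy: float


@dataclass(frozen=True)
class CVSummary:
    auc_mean: float
    auc_sd: float
    sens_mean: float
    sens_sd: float
    spec_mean: float
    spec_sd: float
    n_folds: int


# ---------------------------------------------------------------------------
# MLP internals

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, X, *, dropout_rate=0.0, rng=None):
    """Forward pass; returns activations per layer (with dropout masks applied)."""
    acts = [X]
    h = X
    n_hidden = len(weights) - 1
    for i, (W, b) in enumerate(weights):
        z = h @ W + b
        if i < n_hidden:
            h = np.maximum(z, 0.0)
            if dropout_rate > 0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                h = h * mask
        else:
            h = _softmax(z)
        acts.append(h)
    return acts


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(y.size), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def _init_weights(rng, sizes):
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return weights


def _fit_mlp(X: np.ndarray, y: np.ndarray, config: ANNConfig):
    """Train the MLP on (X, y in {0,1}); returns (weights, loss history)."""
    n, width = X.shape
    rng = np.random.default_rng(config.seed)
    sizes = (width, *config.hidden_sizes, 2)
    weights = _init_weights(rng, sizes)
    m_adam = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v_adam = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            acts = _forward(weights, Xb, dropout_rate=config.dropout_rate, rng=rng)
            grads = []
            delta = acts[-1].copy()
            delta[np.arange(yb.size), yb] -= 1.0
            delta /= yb.size
            for layer in range(len(weights) - 1, -1, -1):
                a_prev = acts[layer]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                grads.append((gW, gb))
                if layer > 0:
                    delta = (delta @ weights[layer][0].T) * (acts[layer] > 0)
            grads.reverse()
            step += 1
            for layer, (gW, gb) in enumerate(grads):
                W, b = weights[layer]
                mW, mb = m_adam[layer]
                vW, vb = v_adam[layer]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m_adam[layer] = (mW, mb)
                v_adam[layer] = (vW, vb)
                mW_hat = mW / (1 - beta1**step)
                mb_hat = mb / (1 - beta1**step)
                vW_hat = vW / (1 - beta2**step)
                vb_hat = vb / (1 - beta2**step)
                weights[layer] = (
                    W - config.learning_rate * mW_hat / (np.sqrt(vW_hat) + eps),
                    b - config.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps),
                )
        probs = _forward(weights, X)[-1]
        loss = _cross_entropy(probs, y)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch + 1}")
        history.append(loss)
        if config.threshold_mode == "loss":
            if loss <= config.error_threshold:
                break
        else:
            err = float(np.mean(probs.argmax(axis=1) != y))
            if err <= config.error_threshold:
                break
    return weights, history


def _design(dataset: SpectrumSet, task: str, positive: str | None = None):
    """Replicate-averaged design matrix + binary labels for one task."""
    collapsed = dataset if dataset.replicates_per_sample == 1 else average_replicates(dataset)
    labels = collapsed.labels(task)
    if np.any(labels == "NA"):
        raise ValidationError(f"task {task!r} label missing for some samples")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes for training, got {classes.tolist()}")
    pos = resolve_positive_class(classes, positive)
    neg = next(c for c in classes if c != pos)
    X = collapsed.intensity_matrix()
    y = (labels == pos).astype(int)
    return X, y, (str(neg), str(pos))


def train_ann(train: SpectrumSet, config: ANNConfig, task: str, positive: str | None = None) -> TrainedModel:
    """Train the classifier on a preprocessed (cropped, normalized) cohort."""
    X, y, classes = _design(train, task, positive)
    weights, history = _fit_mlp(X, y, config)
    return TrainedModel(
        weights=weights,
        config=config,
        input_width=X.shape[1],
        classes=classes,
        training_history=history,
    )


def predict_proba(model: TrainedModel, spectra: SpectrumSet | np.ndarray) -> np.ndarray:
    """Class-probability pairs, columns ordered as ``model.classes``."""
    if isinstance(spectra, SpectrumSet):
        collapsed = spectra if spectra.replicates_per_sample == 1 else average_replicates(spectra)
        X = collapsed.intensity_matrix()
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.input_width:
        raise ValidationError(
            f"input width {X.shape[1]} does not match model input width {model.input_width}"
        )
    # training encodes the positive class as 1, so columns are (neg, pos)
    return _forward(model.weights, X)[-1]


def predict_labels(model: TrainedModel, spectra: SpectrumSet | np.ndarray) -> np.ndarray:
    probs = predict_proba(model, spectra)
    return np.where(probs[:, 1] >= 0.5, model.classes[1], model.classes[0])


# ---------------------------------------------------------------------------
# splitting and evaluation

def split_train_test(
    dataset: SpectrumSet,
    task: str,
    seed: int = 0,
    test_fraction: float = 0.2,
    train_per_class: dict[str, int] | None = None,
) -> tuple[SpectrumSet, SpectrumSet]:
    """Stratified random split by sample id (replicates never straddle).

    By default one fifth of each class is held out (a 4:1 split). Passing
    ``train_per_class`` instead fixes the training count of each class and
    sends the remainder to the test set — e.g. ``{"success": 50,
    "failure": 50}`` reproduces an unbalanced-cohort protocol where the
    training set is balanced and the test set is not.
    """
    labels = dataset.labels(task)
    classes = np.unique(labels[labels != "NA"])
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in classes:
        ids = [m.sample_id for m, lab in zip(dataset.samples, labels) if lab == cls]
        if len(ids) < 5:
            raise ValidationError(f"class {cls!r} has fewer than 5 samples")
        ids = list(rng.permutation(ids))
        if train_per_class is not None:
            n_train = int(train_per_class[str(cls)])
            if not 0 < n_train < len(ids):
                raise ValidationError(f"train count {n_train} invalid for class {cls!r} (n={len(ids)})")
        else:
            n_train = len(ids) - int(round(len(ids) * test_fraction))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return dataset.subset(train_ids), dataset.subset(test_ids)


def confusion_and_report(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class: str
) -> tuple[ConfusionMatrix, ClassReport]:
    """Confusion matrix for the positive class plus a per-class report.

    precision = tp/(tp+fp); sensitivity = tp/(tp+fn); F1 is their harmonic
    mean; accuracy = (tp+tn)/total. The complementary class's metrics are
    obtained by swapping the positive class. A 0/0 metric is reported as
    ``None`` with a warning rather than as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must be non-empty and equal-length")
    classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    if positive_class not in classes:
        raise ValidationError(f"positive class {positive_class!r} not among labels")

    def counts(pos: str) -> ConfusionMatrix:
        is_pos_true = y_true == pos
        is_pos_pred = y_pred == pos
        return ConfusionMatrix(
            tp=int(np.sum(is_pos_true & is_pos_pred)),
            fn=int(np.sum(is_pos_true & ~is_pos_pred)),
            fp=int(np.sum(~is_pos_true & is_pos_pred)),
            tn=int(np.sum(~is_pos_true & ~is_pos_pred)),
        )

    def metrics(cm: ConfusionMatrix, cls: str) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name, num, den in (
            ("precision", cm.tp, cm.tp + cm.fp),
            ("sensitivity", cm.tp, cm.tp + cm.fn),
        ):
            if den == 0:
                warnings.warn(f"{name} undefined (0/0) for class {cls!r}", stacklevel=3)
                out[name] = None
            else:
                out[name] = num / den
        p, s = out["precision"], out["sensitivity"]
        if p is None or s is None or p + s == 0:
            if p is not None and s is not None:
                warnings.warn(f"F1 undefined for class {cls!r}", stacklevel=3)
            out["f1"] = None
        else:
            out["f1"] = 2 * p * s / (p + s)
        return out

    cm = counts(positive_class)
    per_class = {cls: metrics(counts(cls), cls) for cls in classes}
    report = ClassReport(per_class=per_class, accuracy=(cm.tp + cm.tn) / cm.total)
    return cm, report


def report_from_counts(tp: int, fn: int, fp: int, tn: int, positive_class: str = "pos") -> tuple[ConfusionMatrix, ClassReport]:
    """Confusion-matrix metrics directly from the four counts."""
    other = "neg" if positive_class == "pos" else f"not-{positive_class}"
    y_true = np.array([positive_class] * (tp + fn) + [other] * (fp + tn))
    y_pred = np.array(
        [positive_class] * tp + [other] * fn + [positive_class] * fp + [other] * tn
    )
    return confusion_and_report(y_true, y_pred, positive_class)


def roc_curve_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) from a threshold sweep, and the trapezoid AUC.

    The AUC equals the Mann-Whitney pairwise-concordance statistic
    (ties counted half).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValidationError("ROC needs both classes present in y_true")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def five_fold_cv(dataset: SpectrumSet, config: ANNConfig, task: str) -> CVSummary:
    """Stratified five-fold cross-validation summarized by ROC AUC.

    Per fold: train on four parts, score the fifth; AUC from the full ROC
    sweep, sensitivity and specificity at the 0.5 probability threshold.
    Fold assignment and training are deterministic given ``config.seed``.
    """
    collapsed = dataset if dataset.replicates_per_sample == 1 else average_replicates(dataset)
    labels = collapsed.labels(task)
    ids = np.array([m.sample_id for m in collapsed.samples])
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=config.seed)
    aucs, senss, specs = [], [], []
    for train_idx, test_idx in skf.split(ids, labels):
        train = collapsed.subset(ids[train_idx])
        test = collapsed.subset(ids[test_idx])
        model = train_ann(train, config, task)
        probs = predict_proba(model, test)[:, 1]
        y = (test.labels(task) == model.classes[1]).astype(int)
        _, auc_val = roc_curve_auc(y, probs)
        pred = (probs >= 0.5).astype(int)
        tp = int(np.sum((y == 1) & (pred == 1)))
        fn = int(np.sum((y == 1) & (pred == 0)))
        fp = int(np.sum((y == 0) & (pred == 1)))
        tn = int(np.sum((y == 0) & (pred == 0)))
        aucs.append(auc_val)
        senss.append(tp / (tp + fn) if tp + fn else np.nan)
        specs.append(tn / (tn + fp) if tn + fp else np.nan)
    return CVSummary(
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)),
        sens_mean=float(np.nanmean(senss)),
        sens_sd=float(np.nanstd(senss, ddof=1)),
        spec_mean=float(np.nanmean(specs)),
        spec_sd=float(np.nanstd(specs, ddof=1)),
        n_folds=5,
    )


def loocv(dataset: SpectrumSet, config: ANNConfig, task: str) -> dict:
    """Leave-one-out cross-validation: each sample predicted by the rest.

    Returns predicted labels, positive-class probabilities and accuracy.
    """
    collapsed = dataset if dataset.replicates_per_sample == 1 else average_replicates(dataset)
    labels = collapsed.labels(task)
    for cls, n in zip(*np.unique(labels, return_counts=True)):
        if n < 3:
            raise ValidationError(f"class {cls!r} has fewer than 3 samples")
    ids = [m.sample_id for m in collapsed.samples]
    preds, probs = [], []
    for held_out in ids:
        train = collapsed.subset([i for i in ids if i != held_out])
        model = train_ann(train, config, task)
        p = predict_proba(model, collapsed.subset([held_out]))[0, 1]
        probs.append(float(p))
        preds.append(model.classes[1] if p >= 0.5 else model.classes[0])
    preds_arr = np.array(preds)
    return {
        "sample_ids": ids,
        "predicted": preds_arr,
        "proba_positive": np.array(probs),
        "accuracy": float(np.mean(preds_arr == labels)),
    }


def pregnancy_rate_summary(samples) -> dict[str, dict]:
    """Clinical pregnancy rate per blastocyst-quality stratum.

    Accepts a SpectrumSet, a sequence of SampleMeta, or (blastocyst,
    pregnancy) pairs; both labels must be present per sample. Rates are
    percentages rounded to the nearest integer; an empty stratum reports a
    ``None`` rate with a warning.
    """
    if isinstance(samples, SpectrumSet):
        samples = samples.samples
    pairs = []
    for s in samples:
        if isinstance(s, SampleMeta):
            pairs.append((s.blastocyst, s.pregnancy))
        else:
            pairs.append((s[0], s[1]))
    out: dict[str, dict] = {}
    for stratum in ("HQ", "LQ"):
        members = [p for p in pairs if p[0] == stratum]
        n = len(members)
        successes = sum(1 for p in members if p[1] == "success")
        if n == 0:
            warnings.warn(f"empty blastocyst stratum {stratum!r}: rate undefined", stacklevel=2)
            rate = None
        else:
            rate = int(round(100.0 * successes / n))
        out[stratum] = {"n": n, "successes": successes, "rate_percent": rate}
    return out
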