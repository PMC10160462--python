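"""Two-layer feed-forward network classification with confusion reporting.

The classifier is the classic pattern-recognition network: one hidden layer
of logistic-sigmoid units and a softmax output layer, trained by full-batch
adaptive gradient descent (Adam) on the cross-entropy of one-hot targets.
Samples are split 70/15/15 into training, validation and test partitions;
the validation partition halts training when generalization stops improving
(early stopping with a patience window, returning the weights of the best
validation epoch), and the test partition is never touched during training.

Class-order conventions for one-hot coding: binary bruise detection uses
``("bruised", "no_bruise")`` so a bruised sample is coded [1, 0]; the
three-class severity task uses ``("drop_60", "drop_100", "no_drop")`` so a
60 cm drop is [1, 0, 0].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, ShapeError

__all__ = [
    "DETECTION_ORDER",
    "SEVERITY_ORDER",
    "OneHotTargets",
    "SplitSpec",
    "AnnModel",
    "ConfusionReport",
    "one_hot",
    "split",
    "train_ann",
    "predict",
    "evaluate",
]

#: One-hot column order for binary bruise detection ([1 0] = bruised).
DETECTION_ORDER = ("bruised", "no_bruise")
#: One-hot column order for the three-class severity task ([1 0 0] = 60 cm drop).
SEVERITY_ORDER = ("drop_60", "drop_100", "no_drop")


class TrainingError(RuntimeError):
    """Training failed (non-finite loss or degenerate partition)."""


@dataclass
class OneHotTargets:
    """Dummy binary-coded target matrix: one row per sample, one column per class."""

    matrix: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.class_order):
            raise ShapeError("target matrix shape does not match the class order")
        row_sums = self.matrix.sum(axis=1)
        if not (np.all(np.isin(self.matrix, (0.0, 1.0))) and np.all(row_sums == 1.0)):
            raise ConfigurationError("each target row must have exactly one 1")

    @property
    def labels(self) -> list[str]:
        return [self.class_order[i] for i in np.argmax(self.matrix, axis=1)]


def one_hot(labels: list[str], class_order: tuple[str, ...] | list[str]) -> OneHotTargets:
    """Encode class labels as a one-hot matrix in the given column order."""
    class_order = tuple(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    unknown = sorted(set(labels) - set(class_order))
    if unknown:
        raise ConfigurationError(f"labels not in class order: {unknown}")
    M = np.zeros((len(labels), len(class_order)))
    for r, lab in enumerate(labels):
        M[r, index[lab]] = 1.0
    return OneHotTargets(M, class_order)


@dataclass
class SplitSpec:
    """Random 70/15/15 partition into train / validation / test index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(allidx)) != len(allidx):
            raise ConfigurationError("split partitions overlap")


def _apportion(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Round-half-to-even on train and validation; test takes the remainder."""
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    n_test = n - n_train - n_val
    return n_train, n_val, n_test


def _stratified_counts(
    class_sizes: list[int], total_take: int, fraction: float
) -> list[int]:
    """Largest-remainder allocation of ``total_take`` across classes."""
    exact = [fraction * s for s in class_sizes]
    base = [int(np.floor(e)) for e in exact]
    remainder = total_take - sum(base)
    order = sorted(range(len(class_sizes)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def split(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    labels: list[str] | None = None,
    stratify: bool = True,
) -> SplitSpec:
    """Randomly partition ``n`` samples into train / validation / test sets.

    Sizes follow round(0.70 n) / round(0.15 n) / remainder (90 samples give
    63 / 14 / 13).  With ``labels`` and ``stratify=True`` (the default) the
    class proportions are preserved per partition while keeping exactly
    those global sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    n_train, n_val, n_test = _apportion(n, fractions)
    if min(n_train, n_val, n_test) < 1:
        raise ConfigurationError(f"partition would be empty for n={n}")
    rng = np.random.default_rng(seed)

    if labels is None or not stratify:
        perm = rng.permutation(n)
        tr, va, te = perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
    else:
        if len(labels) != n:
            raise ShapeError("labels length must equal n")
        classes = sorted(set(labels))
        by_class = {c: np.flatnonzero(np.asarray(labels) == c) for c in classes}
        sizes = [len(by_class[c]) for c in classes]
        tr_counts = _stratified_counts(sizes, n_train, fractions[0])
        va_counts = _stratified_counts(sizes, n_val, fractions[1])
        tr_list, va_list, te_list = [], [], []
        for c, n_tr, n_va in zip(classes, tr_counts, va_counts):
            idx = rng.permutation(by_class[c])
            tr_list.append(idx[:n_tr])
            va_list.append(idx[n_tr : n_tr + n_va])
            te_list.append(idx[n_tr + n_va :])
        tr = np.concatenate(tr_list)
        va = np.concatenate(va_list)
        te = np.concatenate(te_list)
    return SplitSpec(np.sort(tr), np.sort(va), np.sort(te), fractions, seed)


@dataclass
class AnnModel:
    """A trained sigmoid-hidden / softmax-output network with its history."""

    w_hidden: np.ndarray  # (n_features, hidden_width)
    b_hidden: np.ndarray
    w_out: np.ndarray  # (hidden_width, n_classes)
    b_out: np.ndarray
    class_order: tuple[str, ...]
    x_mean: np.ndarray  # input standardization learned on the training set
    x_scale: np.ndarray
    history: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.w_hidden.shape[0]

    def to_dict(self) -> dict:
        return {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "class_order": list(self.class_order),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "history": {k: list(v) if isinstance(v, (list, np.ndarray)) else v
                        for k, v in self.history.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(
            np.asarray(d["w_hidden"], dtype=float),
            np.asarray(d["b_hidden"], dtype=float),
            np.asarray(d["w_out"], dtype=float),
            np.asarray(d["b_out"], dtype=float),
            tuple(d["class_order"]),
            np.asarray(d["x_mean"], dtype=float),
            np.asarray(d["x_scale"], dtype=float),
            dict(d.get("history", {})),
            int(d.get("seed", 0)),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _forward(model_params: tuple, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w1, b1, w2, b2 = model_params
    hidden = _sigmoid(X @ w1 + b1)
    probs = _softmax(hidden @ w2 + b2)
    return hidden, probs


def _cross_entropy(probs: np.ndarray, Y: np.ndarray) -> float:
    return float(-np.mean(np.sum(Y * np.log(np.clip(probs, 1e-12, None)), axis=1)))


def train_ann(
    X: np.ndarray,
    targets: OneHotTargets,
    split_spec: SplitSpec,
    hidden_width: int = 10,
    max_epochs: int = 1000,
    patience: int = 6,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> AnnModel:
    """Train the two-layer network with early stopping on the validation loss.

    Full-batch Adam minimizes the training cross-entropy from small seeded
    random initial weights; training halts after ``patience`` consecutive
    epochs without validation improvement (or at ``max_epochs``), and the
    weights of the best validation epoch are returned.  Inputs are
    standardized with training-set statistics stored on the model.  The test
    partition is never consulted.
    """
    X = np.asarray(X, dtype=float)
    Y = targets.matrix
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("features and targets must be row-aligned")
    if hidden_width < 1:
        raise ConfigurationError("hidden_width must be >= 1")
    tr, va = split_spec.train, split_spec.validation
    if len(np.unique(np.argmax(Y[tr], axis=1))) < 2:
        raise TrainingError("training partition contains a single class")

    x_mean = X[tr].mean(axis=0)
    x_scale = X[tr].std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale
    Xtr, Ytr = Xs[tr], Y[tr]
    Xva, Yva = Xs[va], Y[va]

    rng = np.random.default_rng(seed)
    n_feat, n_cls = X.shape[1], Y.shape[1]
    w1 = rng.normal(0, 1.0 / np.sqrt(n_feat), (n_feat, hidden_width))
    b1 = np.zeros(hidden_width)
    w2 = rng.normal(0, 1.0 / np.sqrt(hidden_width), (hidden_width, n_cls))
    b2 = np.zeros(n_cls)

    params = [w1, b1, w2, b2]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = 0
    stall = 0
    train_losses: list[float] = []
    val_losses: list[float] = []

    n_tr = len(tr)
    for epoch in range(1, max_epochs + 1):
        hidden, probs = _forward(tuple(params), Xtr)
        loss = _cross_entropy(probs, Ytr)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")

        # backprop of mean cross-entropy through softmax and sigmoid
        delta_out = (probs - Ytr) / n_tr
        grad_w2 = hidden.T @ delta_out
        grad_b2 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ params[2].T) * hidden * (1.0 - hidden)
        grad_w1 = Xtr.T @ delta_hid
        grad_b1 = delta_hid.sum(axis=0)
        grads = [grad_w1, grad_b1, grad_w2, grad_b2]

        for i, g in enumerate(grads):
            m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * g
            v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * g * g
            m_hat = m_adam[i] / (1 - beta1**epoch)
            v_hat = v_adam[i] / (1 - beta2**epoch)
            params[i] = params[i] - learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        _, val_probs = _forward(tuple(params), Xva)
        val_loss = _cross_entropy(val_probs, Yva)
        train_losses.append(loss)
        val_losses.append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break

    return AnnModel(
        best_params[0],
        best_params[1],
        best_params[2],
        best_params[3],
        targets.class_order,
        x_mean,
        x_scale,
        history={
            "train_loss": train_losses,
            "val_loss": val_losses,
            "best_epoch": best_epoch,
            "stopped_epoch": len(train_losses),
        },
        seed=seed,
    )


def predict(model: AnnModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Class labels and softmax probabilities for a feature matrix.

    Ties in the probability vector resolve to the earlier class in the
    model's class order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ShapeError(
            f"feature dimension {X.shape} does not match model input {model.n_features}"
        )
    Xs = (X - model.x_mean) / model.x_scale
    _, probs = _forward((model.w_hidden, model.b_hidden, model.w_out, model.b_out), Xs)
    labels = [model.class_order[i] for i in np.argmax(probs, axis=1)]
    return labels, probs


@dataclass
class ConfusionReport:
    """True-class x predicted-class counts with derived accuracy metrics.

    ``accuracy`` is 100 * trace / total (in %); ``class_error`` is its
    complement; ``per_class_accuracy`` is the diagonal count over the true
    class size, per class.
    """

    matrix: np.ndarray  # rows: true class, cols: predicted class
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.class_order)
        if self.matrix.shape != (k, k):
            raise ShapeError("confusion matrix must be square on the class order")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        return 100.0 * float(np.trace(self.matrix)) / self.total if self.total else float("nan")

    @property
    def class_error(self) -> float:
        return 100.0 - self.accuracy

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for i, c in enumerate(self.class_order):
            row = self.matrix[i].sum()
            out[c] = 100.0 * self.matrix[i, i] / row if row else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "matrix": self.matrix.tolist(),
            "total": self.total,
            "accuracy_pct": self.accuracy,
            "class_error_pct": self.class_error,
            "per_class_accuracy_pct": self.per_class_accuracy,
        }


def evaluate(
    truth: list[str], predicted: list[str], class_order: tuple[str, ...] | list[str]
) -> ConfusionReport:
    """Build the confusion matrix of true vs predicted labels."""
    if len(truth) != len(predicted):
        raise ShapeError("truth and prediction lengths differ")
    class_order = tuple(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    bad = sorted({t for t in truth if t not in index} | {p for p in predicted if p not in index})
    if bad:
        raise ConfigurationError(f"labels outside the class order: {bad}")
    k = len(class_order)
    M = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        M[index[t], index[p]] += 1
    return ConfusionReport(M, class_order)
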