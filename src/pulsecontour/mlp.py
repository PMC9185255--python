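"""From-scratch multilayer perceptron trained by error backpropagation.

A single hidden layer maps the 21-element multiparametric feature vector to
condition-class scores.  Weights are corrected by propagating the output
error backwards layer by layer (classical delta rule); the loss is the sum
of squared errors by default, with cross-entropy as an option.  Features
are z-scored per column before training because anthropometric and timing
features differ by orders of magnitude; the scaling statistics are stored
with the model so prediction is self-contained.  Models persist as plain
JSON for auditability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ACTIVATIONS = ("logistic", "tanh")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, a: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation value ``a``."""
    if name == "logistic":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a**2
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class MLPNetwork:
    """A [input, hidden, output] perceptron.

    ``weights[l]`` has shape (fan_in, fan_out); activations are per-layer
    names from ``{"logistic", "tanh"}`` (the output layer is logistic so
    scores live in (0, 1)).  ``classes`` and the z-score statistics are
    filled in by training.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: tuple[str, ...]
    seed: int = 0
    classes: Optional[tuple[str, ...]] = None
    feature_means: Optional[np.ndarray] = None
    feature_stds: Optional[np.ndarray] = None

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Backpropagation hyperparameters."""

    learning_rate: float = 0.1
    epochs: int = 200
    batch_mode: str = "per-sample"  # or "full-batch"
    shuffle_seed: int = 0
    early_stop_tolerance: float = 0.0  # 0 disables early stopping
    loss: str = "sse"  # or "cross_entropy"

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_mode not in ("per-sample", "full-batch"):
            raise ValueError("batch_mode must be 'per-sample' or 'full-batch'")
        if self.loss not in ("sse", "cross_entropy"):
            raise ValueError("loss must be 'sse' or 'cross_entropy'")


def init_network(
    hidden_size: int,
    n_classes: int,
    seed: int = 0,
    input_size: int = 21,
    activation: str = "logistic",
) -> MLPNetwork:
    """Initialize a [input, hidden, output] network.

    Weights are drawn uniformly from ``[-1/sqrt(fan_in), 1/sqrt(fan_in)]``
    (a small symmetric scale that keeps initial pre-activations of order
    one); biases start at zero.  Reproducible from ``seed``.
    """
    if hidden_size < 1 or n_classes < 1 or input_size < 1:
        raise ValueError("layer sizes must be positive")
    if activation not in ACTIVATIONS:
        raise ValueError(f"activation must be one of {ACTIVATIONS}")
    sizes = (input_size, hidden_size, n_classes)
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-scale, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPNetwork(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        activations=(activation, "logistic"),
        seed=seed,
    )


def _standardize(net: MLPNetwork, X: np.ndarray) -> np.ndarray:
    if net.feature_means is None:
        return X
    return (X - net.feature_means) / net.feature_stds


def _forward_pass(net: MLPNetwork, X: np.ndarray) -> list[np.ndarray]:
    """All layer activations for (n, d) standardized input."""
    acts = [X]
    a = X
    for W, b, name in zip(net.weights, net.biases, net.activations):
        a = _act(name, a @ W + b)
        acts.append(a)
    return acts


def forward(net: MLPNetwork, x: np.ndarray) -> np.ndarray:
    """Class scores for one feature vector (or an (n, d) batch).

    Applies the stored z-score scaling when present.  Scores are finite and,
    with the logistic output layer, lie in (0, 1).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != net.n_inputs:
        raise ValueError(f"expected {net.n_inputs} inputs, got {X.shape[1]}")
    out = _forward_pass(net, _standardize(net, X))[-1]
    return out[0] if single else out


def _loss_value(Y: np.ndarray, A: np.ndarray, loss: str) -> float:
    if loss == "sse":
        return float(np.mean(np.sum((A - Y) ** 2, axis=1)))
    eps = 1e-12
    return float(
        -np.mean(np.sum(Y * np.log(A + eps) + (1 - Y) * np.log(1 - A + eps), axis=1))
    )


def _gradients(
    net: MLPNetwork, X: np.ndarray, Y: np.ndarray, loss: str
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Mean-over-samples gradients of the loss w.r.t. weights and biases."""
    acts = _forward_pass(net, X)
    A = acts[-1]
    n = X.shape[0]
    if loss == "sse":
        delta = 2.0 * (A - Y) * _act_deriv(net.activations[-1], A)
    else:  # cross-entropy with logistic output: the derivative telescopes
        delta = A - Y
    gW: list[np.ndarray] = [np.empty(0)] * len(net.weights)
    gb: list[np.ndarray] = [np.empty(0)] * len(net.biases)
    for l in range(len(net.weights) - 1, -1, -1):
        gW[l] = acts[l].T @ delta / n
        gb[l] = delta.mean(axis=0)
        if l > 0:
            delta = (delta @ net.weights[l].T) * _act_deriv(
                net.activations[l - 1], acts[l]
            )
    return gW, gb, _loss_value(Y, A, loss)


def _encode_labels(labels: Sequence, n_outputs: int) -> tuple[np.ndarray, tuple]:
    classes = tuple(sorted(set(map(str, labels))))
    idx = np.array([classes.index(str(l)) for l in labels])
    if n_outputs == 1:
        if len(classes) != 2:
            raise ValueError("a single output neuron needs exactly 2 classes")
        Y = idx.reshape(-1, 1).astype(float)
    else:
        if len(classes) > n_outputs:
            raise ValueError(
                f"{len(classes)} classes but only {n_outputs} output neurons"
            )
        Y = np.zeros((len(labels), n_outputs))
        Y[np.arange(len(labels)), idx] = 1.0
    return Y, classes


def train_backprop(
    net: MLPNetwork,
    X: np.ndarray,
    labels: Sequence,
    config: TrainConfig = TrainConfig(),
    standardize: bool = True,
) -> tuple[MLPNetwork, np.ndarray]:
    """Train by error backpropagation; returns (trained net, loss trace).

    The output-layer error is computed first, then propagated backwards to
    correct every layer's weights against its current values.  In
    ``per-sample`` mode the update runs after every (shuffled) sample; in
    ``full-batch`` mode once per epoch on the mean gradient.  The loss trace
    holds the full-dataset loss after each epoch; training stops early when
    its decrease drops below ``early_stop_tolerance``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise ValueError(f"X must be (n, {net.n_inputs})")
    uniq = set(map(str, labels))
    if len(uniq) < 2:
        raise ValueError("training data must contain at least 2 classes")
    Y, classes = _encode_labels(labels, net.n_outputs)
    net.classes = classes

    if standardize:
        net.feature_means = X.mean(axis=0)
        stds = X.std(axis=0)
        net.feature_stds = np.where(stds > 0, stds, 1.0)
    Xs = _standardize(net, X)

    rng = np.random.default_rng(config.shuffle_seed)
    trace: list[float] = []
    for epoch in range(config.epochs):
        if config.batch_mode == "per-sample":
            for i in rng.permutation(X.shape[0]):
                gW, gb, _ = _gradients(net, Xs[i : i + 1], Y[i : i + 1], config.loss)
                for l in range(len(net.weights)):
                    net.weights[l] -= config.learning_rate * gW[l]
                    net.biases[l] -= config.learning_rate * gb[l]
        else:
            gW, gb, _ = _gradients(net, Xs, Y, config.loss)
            for l in range(len(net.weights)):
                net.weights[l] -= config.learning_rate * gW[l]
                net.biases[l] -= config.learning_rate * gb[l]

        loss = _loss_value(Y, _forward_pass(net, Xs)[-1], config.loss)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        trace.append(loss)
        if (
            config.early_stop_tolerance > 0
            and len(trace) > 1
            and trace[-2] - trace[-1] < config.early_stop_tolerance
        ):
            break
    return net, np.asarray(trace)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-class diagnostic performance of a trained network."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows: true class, columns: predicted
    sensitivity: dict[str, float]  # TP / (TP + FN)
    specificity: dict[str, float]  # TN / (TN + FP)
    accuracy: float


def _predict_indices(net: MLPNetwork, X: np.ndarray) -> np.ndarray:
    scores = forward(net, X)
    if net.n_outputs == 1:
        return (scores[:, 0] > 0.5).astype(int)
    return np.argmax(scores, axis=1)


def evaluate(net: MLPNetwork, X: np.ndarray, labels: Sequence) -> EvaluationResult:
    """Per-class sensitivity/specificity and the confusion matrix.

    Samples are assigned to the highest-scoring output; each confusion-matrix
    row sums to that true class's sample count.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("evaluate: empty data")
    if net.classes is None:
        raise ValueError("network has not been trained (no class labels)")
    classes = net.classes
    true_idx = np.array([classes.index(str(l)) for l in labels])
    pred_idx = _predict_indices(net, X)
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_idx, pred_idx):
        confusion[t, p] += 1
    sens, spec = {}, {}
    total = confusion.sum()
    for i, name in enumerate(classes):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[name] = tp / (tp + fn) if tp + fn else float("nan")
        spec[name] = tn / (tn + fp) if tn + fp else float("nan")
    accuracy = float(np.trace(confusion) / total)
    return EvaluationResult(
        classes=classes, confusion=confusion,
        sensitivity=sens, specificity=spec, accuracy=accuracy,
    )


def confusion_rates(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """Sensitivity and specificity from raw 2x2 confusion counts."""
    return tp / (tp + fn), tn / (tn + fp)


def _stratified_folds(
    labels: Sequence, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns test-index arrays."""
    labels = np.asarray([str(l) for l in labels])
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.sort(np.asarray(f)) for f in folds]


def select_hidden_size(
    X: np.ndarray,
    labels: Sequence,
    candidate_sizes: Sequence[int],
    config: TrainConfig = TrainConfig(),
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated sensitivity/specificity per hidden-layer size.

    Rational sizing of the hidden layer is an open empirical question; this
    helper reports the per-output diagnostics for each candidate and makes
    no selection itself.  Rows: one per (size, class) with mean
    cross-validated sensitivity, specificity and accuracy.
    """
    candidate_sizes = list(candidate_sizes)
    if len(candidate_sizes) < 2:
        raise ValueError("need at least 2 candidate sizes")
    X = np.asarray(X, dtype=float)
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    n_classes = len(classes)
    folds = _stratified_folds(labels, n_folds, seed)
    rows = []
    for size in candidate_sizes:
        per_class = {c: {"sens": [], "spec": []} for c in classes}
        accs = []
        for f, test_idx in enumerate(folds):
            mask = np.zeros(len(labels), dtype=bool)
            mask[test_idx] = True
            net = init_network(size, n_classes, seed=seed + f,
                              input_size=X.shape[1])
            net, _ = train_backprop(
                net, X[~mask], [l for l, m in zip(labels, mask) if not m], config
            )
            res = evaluate(net, X[mask], [l for l, m in zip(labels, mask) if m])
            accs.append(res.accuracy)
            for c in classes:
                per_class[c]["sens"].append(res.sensitivity[c])
                per_class[c]["spec"].append(res.specificity[c])
        for c in classes:
            rows.append(
                dict(
                    hidden_size=size,
                    output_class=c,
                    sensitivity=float(np.nanmean(per_class[c]["sens"])),
                    specificity=float(np.nanmean(per_class[c]["spec"])),
                    accuracy=float(np.mean(accs)),
                )
            )
    return pd.DataFrame.from_records(rows)


def save_model(net: MLPNetwork, path) -> None:
    """Persist a network as plain JSON (architecture, scaling, weights)."""
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "activations": list(net.activations),
        "seed": net.seed,
        "classes": list(net.classes) if net.classes else None,
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "feature_means": net.feature_means.tolist()
        if net.feature_means is not None else None,
        "feature_stds": net.feature_stds.tolist()
        if net.feature_stds is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> MLPNetwork:
    with open(path) as fh:
        p = json.load(fh)
    return MLPNetwork(
        layer_sizes=tuple(p["layer_sizes"]),
        weights=[np.asarray(w) for w in p["weights"]],
        biases=[np.asarray(b) for b in p["biases"]],
        activations=tuple(p["activations"]),
        seed=p["seed"],
        classes=tuple(p["classes"]) if p["classes"] else None,
        feature_means=np.asarray(p["feature_means"])
        if p["feature_means"] is not None else None,
        feature_stds=np.asarray(p["feature_stds"])
        if p["feature_stds"] is not None else None,
    )
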