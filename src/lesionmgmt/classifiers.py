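"""Class-weighted, class-balanced multi-task softmax classifiers.

The training objective is the class-weighted categorical cross-entropy

    L = -(1/|b|) * sum_i sum_j w_j * y_j^(i) * log phi(x^(i))_j

averaged over mini-batches b, with inverse-frequency class weights
w_j = N / (K * n_j), summed across prediction tasks for the multi-task
model (seven dermoscopic criteria + diagnosis + management = 9 heads over
a shared input representation). Mini-batches are drawn class-balanced on a
primary task's labels: a class uniformly at random, then an instance of
that class, with replacement. Both the balanced sampling and the class
weighting are applied together.

Models are per-task affine (softmax regression) blocks over the
concatenated modality representation, optionally preceded by a per-task
tanh hidden layer, optimized by mini-batch gradient descent with momentum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

PROB_FLOOR = 1e-12  # floor inside logs; keeps the loss finite

MANAGEMENT_TASK = "management"
DIAGNOSIS_TASK = "diagnosis"
ALL_TASKS: tuple[str, ...] = tuple(f"criterion_{k}" for k in range(1, 8)) + (
    DIAGNOSIS_TASK,
    MANAGEMENT_TASK,
)


@dataclass(frozen=True)
class ClassWeights:
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or (w <= 0).any():
            raise ValueError("class weights must be a vector of positive reals")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 120
    tolerance: float = 1e-6
    hidden_dim: int = 16  # 0 = linear softmax heads
    seed: int = 0
    task_list: tuple[str, ...] = (MANAGEMENT_TASK,)
    balance_task: str | None = None  # defaults to the primary task (last listed)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")
        if self.tolerance < 0 or self.hidden_dim < 0:
            raise ValueError("invalid training configuration")
        if not self.task_list:
            raise ValueError("task_list must be non-empty")
        unknown = set(self.task_list) - set(ALL_TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")

    @property
    def primary_task(self) -> str:
        if self.balance_task is not None:
            return self.balance_task
        # management when present, else diagnosis, else the first criterion task
        for task in (MANAGEMENT_TASK, DIAGNOSIS_TASK):
            if task in self.task_list:
                return task
        return self.task_list[0]


@dataclass
class ModelParameters:
    """Per-task parameter blocks (optional tanh hidden layer + affine head)
    plus the modality mask recording which input blocks the model saw."""

    task_weights: dict[str, np.ndarray]  # d_in (or hidden) x K_task
    task_biases: dict[str, np.ndarray]
    hidden_weights: dict[str, np.ndarray] | None  # d_in x hidden, per task
    hidden_biases: dict[str, np.ndarray] | None
    modalities: str
    config: TrainingConfig
    final_epoch_loss: float = float("nan")
    n_epochs_run: int = 0

    @property
    def input_dim(self) -> int:
        if self.hidden_weights is not None:
            return next(iter(self.hidden_weights.values())).shape[0]
        return next(iter(self.task_weights.values())).shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "modalities": self.modalities,
            "config": asdict(self.config),
            "final_epoch_loss": self.final_epoch_loss,
            "n_epochs_run": self.n_epochs_run,
            "hidden_weights": None
            if self.hidden_weights is None
            else {t: W.tolist() for t, W in self.hidden_weights.items()},
            "hidden_biases": None
            if self.hidden_biases is None
            else {t: b.tolist() for t, b in self.hidden_biases.items()},
            "task_weights": {t: W.tolist() for t, W in self.task_weights.items()},
            "task_biases": {t: b.tolist() for t, b in self.task_biases.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["task_list"] = tuple(cfg["task_list"])
        return cls(
            task_weights={t: np.asarray(W) for t, W in payload["task_weights"].items()},
            task_biases={t: np.asarray(b) for t, b in payload["task_biases"].items()},
            hidden_weights=None
            if payload["hidden_weights"] is None
            else {t: np.asarray(W) for t, W in payload["hidden_weights"].items()},
            hidden_biases=None
            if payload["hidden_biases"] is None
            else {t: np.asarray(b) for t, b in payload["hidden_biases"].items()},
            modalities=payload["modalities"],
            config=TrainingConfig(**cfg),
            final_epoch_loss=payload["final_epoch_loss"],
            n_epochs_run=payload["n_epochs_run"],
        )


def compute_class_weights(labels: np.ndarray, n_classes: int) -> ClassWeights:
    """Inverse-frequency weights w_j = N / (K * n_j).

    The count-weighted mean sum_j n_j * w_j / N equals 1, so the weighting
    rescales, rather than inflates, the average loss.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels outside 0..n_classes-1")
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        absent = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"classes {absent} absent; weights undefined")
    return ClassWeights(labels.size / (n_classes * counts.astype(float)))


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def weighted_cross_entropy(
    pred_probs: np.ndarray, targets: np.ndarray, weights: ClassWeights
) -> float:
    """Batch-mean class-weighted categorical cross-entropy (natural log)."""
    P = np.asarray(pred_probs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if P.shape != Y.shape or P.shape[1] != weights.weights.size:
        raise ValueError("shape mismatch between predictions, targets and weights")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("prediction rows must sum to 1")
    logp = np.log(np.maximum(P, PROB_FLOOR))
    return float(-(weights.weights * Y * logp).sum() / P.shape[0])


def multi_task_loss(
    preds_by_task: dict[str, np.ndarray],
    targets_by_task: dict[str, np.ndarray],
    weights_by_task: dict[str, ClassWeights],
) -> float:
    """Sum of per-task weighted cross-entropies over the given task heads."""
    if set(preds_by_task) != set(targets_by_task) or set(preds_by_task) != set(weights_by_task):
        raise ValueError("task keys differ between predictions, targets and weights")
    if not preds_by_task:
        raise ValueError("no tasks given")
    return sum(
        weighted_cross_entropy(preds_by_task[t], targets_by_task[t], weights_by_task[t])
        for t in preds_by_task
    )


def sample_balanced_minibatch(
    labels: np.ndarray, batch_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a class uniformly, then an instance of that class uniformly,
    ``batch_size`` times with replacement."""
    labels = np.asarray(labels, dtype=np.int64)
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    classes = np.unique(labels)
    by_class = [np.flatnonzero(labels == c) for c in classes]
    picked = rng.integers(0, classes.size, size=batch_size)
    return np.array(
        [by_class[c][rng.integers(0, by_class[c].size)] for c in picked], dtype=np.int64
    )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: ModelParameters, X: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    if X.shape[1] != model.input_dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model input {model.input_dim}")
    hidden: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    for t in model.task_weights:
        H = X
        if model.hidden_weights is not None:
            H = np.tanh(X @ model.hidden_weights[t] + model.hidden_biases[t])
        hidden[t] = H
        probs[t] = softmax(H @ model.task_weights[t] + model.task_biases[t])
    return hidden, probs


def predict_proba(model: ModelParameters, X: np.ndarray) -> dict[str, np.ndarray]:
    """Per-task softmax probability matrices; rows sum to 1."""
    return _forward(model, np.asarray(X, dtype=float))[1]


def n_task_classes(task: str) -> int:
    if task == DIAGNOSIS_TASK:
        return 5
    if task == MANAGEMENT_TASK:
        return 3
    return 3  # criteria default to 3 score categories (0, 1, 2)


def train_model(
    features: np.ndarray,
    targets_by_task: dict[str, np.ndarray],
    config: TrainingConfig,
    modalities: str = "CDM",
    n_classes_by_task: dict[str, int] | None = None,
) -> ModelParameters:
    """Fit the (single- or multi-task) weighted cross-entropy objective by
    class-balanced mini-batch gradient descent with momentum.

    Balancing is keyed to the primary task's labels (management for the
    management and multi-task models, diagnosis for the diagnosis model).
    Raises on non-finite features or a diverging (NaN) loss.
    """
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    n, d = X.shape
    tasks = [t for t in ALL_TASKS if t in config.task_list]
    for t in tasks:
        if t not in targets_by_task:
            raise ValueError(f"missing targets for task {t!r}")
        if np.asarray(targets_by_task[t]).size != n:
            raise ValueError(f"target length mismatch for task {t!r}")
    if config.batch_size > n:
        raise ValueError("batch_size exceeds the training-set size")

    n_classes = {
        t: (n_classes_by_task or {}).get(t, max(n_task_classes(t), int(np.max(targets_by_task[t])) + 1))
        for t in tasks
    }
    weights = {t: compute_class_weights(targets_by_task[t], n_classes[t]) for t in tasks}
    onehots = {t: one_hot(targets_by_task[t], n_classes[t]) for t in tasks}

    rng = np.random.default_rng(config.seed)
    hidden = config.hidden_dim
    if hidden > 0:
        Wh = {t: rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden)) for t in tasks}
        bh = {t: np.zeros(hidden) for t in tasks}
        head_in = hidden
    else:
        Wh, bh = None, None
        head_in = d
    Wt = {t: np.zeros((head_in, n_classes[t])) for t in tasks}
    bt = {t: np.zeros(n_classes[t]) for t in tasks}
    model = ModelParameters(Wt, bt, Wh, bh, modalities, config)

    velocity = {f"W_{t}": np.zeros_like(Wt[t]) for t in tasks}
    velocity.update({f"b_{t}": np.zeros_like(bt[t]) for t in tasks})
    if hidden > 0:
        velocity.update({f"Wh_{t}": np.zeros_like(Wh[t]) for t in tasks})
        velocity.update({f"bh_{t}": np.zeros_like(bh[t]) for t in tasks})

    balance_labels = np.asarray(targets_by_task[config.primary_task], dtype=np.int64)
    n_batches = max(1, int(np.ceil(n / config.batch_size)))
    prev_epoch_loss = np.inf
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        epoch_loss = 0.0
        for _ in range(n_batches):
            idx = sample_balanced_minibatch(balance_labels, config.batch_size, rng)
            Xb = X[idx]
            Hb, probs = _forward(model, Xb)
            B = idx.size
            loss = 0.0
            for t in tasks:
                Yb = onehots[t][idx]
                w_row = (Yb * weights[t].weights).sum(axis=1, keepdims=True)
                logp = np.log(np.maximum(probs[t], PROB_FLOOR))
                loss += float(-(w_row * Yb * logp).sum() / B)
                # d(weighted CE)/d(logits) = w_{y_i} * (p_i - y_i) / B
                dlogits = w_row * (probs[t] - Yb) / B
                gW = Hb[t].T @ dlogits
                gb = dlogits.sum(axis=0)
                velocity[f"W_{t}"] = config.momentum * velocity[f"W_{t}"] - config.learning_rate * gW
                velocity[f"b_{t}"] = config.momentum * velocity[f"b_{t}"] - config.learning_rate * gb
                if hidden > 0:
                    dZ = (dlogits @ model.task_weights[t].T) * (1.0 - Hb[t] ** 2)  # tanh'
                    gWh = Xb.T @ dZ
                    gbh = dZ.sum(axis=0)
                    velocity[f"Wh_{t}"] = (
                        config.momentum * velocity[f"Wh_{t}"] - config.learning_rate * gWh
                    )
                    velocity[f"bh_{t}"] = (
                        config.momentum * velocity[f"bh_{t}"] - config.learning_rate * gbh
                    )
                model.task_weights[t] += velocity[f"W_{t}"]
                model.task_biases[t] += velocity[f"b_{t}"]
                if hidden > 0:
                    model.hidden_weights[t] += velocity[f"Wh_{t}"]
                    model.hidden_biases[t] += velocity[f"bh_{t}"]
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged (NaN/inf) at epoch {epoch}")
            epoch_loss += loss
        epoch_loss /= n_batches
        if abs(prev_epoch_loss - epoch_loss) < config.tolerance:
            break
        prev_epoch_loss = epoch_loss

    model.final_epoch_loss = epoch_loss
    model.n_epochs_run = epoch
    return model


def write_predictions_csv(
    path: str | Path,
    case_ids: list[str],
    probs_by_task: dict[str, np.ndarray],
    class_names_by_task: dict[str, tuple[str, ...]],
) -> None:
    """Predictions CSV: case_id + one probability column per class per task."""
    import pandas as pd

    data = {"case_id": case_ids}
    for task, P in probs_by_task.items():
        for j, name in enumerate(class_names_by_task[task]):
            data[f"{task}_{name}"] = np.round(P[:, j], 8)
    pd.DataFrame(data).to_csv(path, index=False)
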