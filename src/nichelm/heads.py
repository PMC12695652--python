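"""Linear probing and fine-tuning heads for the downstream task families.

Three task families share one pattern — a head on top of frozen (probing)
or jointly trained (fine-tuning) cell embeddings:

* label classification (cell type / niche / region) — linear layer,
  cross-entropy, softmax certainty, no class-imbalance handling;
* neighborhood composition — linear layer + softmax output under MSE;
* neighborhood density — scalar linear regression under MSE;

plus a shared-hidden multitask MLP predicting composition at several
neighborhood sizes jointly, trained on the unweighted mean of per-size MSEs.

All heads are trained with AdamW at the configured learning rate, batch size
and epoch count, on the train split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score, mean_absolute_error, r2_score

from .model import EncoderModel, _gelu, _gelu_grad
from .schedule import TrainSchedule, lr_at_step
from .tokenizer import N_CONTEXT, TokenizedBatch
from .train import AdamW, clip_by_global_norm

__all__ = [
    "ProbeConfig",
    "FineTuneConfig",
    "LabeledPrediction",
    "train_linear_classifier",
    "predict_labels",
    "train_composition_probe",
    "train_density_probe",
    "train_multitask_mlp",
    "fine_tune",
    "evaluate",
]


@dataclass(frozen=True)
class ProbeConfig:
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("probe config values must be positive")


@dataclass(frozen=True)
class FineTuneConfig:
    lr_max: float = 1e-4
    lr_min: float = 1e-5
    epochs: int = 1
    batch_size: int = 9
    grad_accumulation: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_max >= self.lr_min > 0:
            raise ValueError("require lr_max >= lr_min > 0")


@dataclass(frozen=True)
class LabeledPrediction:
    """Predicted labels with softmax certainty and full class probabilities."""

    labels: np.ndarray
    certainty: np.ndarray  # probability of the predicted label, in [0, 1]
    probabilities: np.ndarray  # (n, classes), rows sum to 1
    classes: tuple


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class LinearHead:
    """A single linear map with AdamW training; subclasses define the loss.

    Input features are standardized with train-split statistics (stored on
    the head) so probe convergence does not depend on the embedding scale.
    """

    def __init__(self, d_in: int, d_out: int, seed: int):
        # zero init: the probe starts at the uniform predictor and follows
        # the loss gradient immediately (no random-hyperplane bias); the
        # seed only drives the minibatch order during fit
        self.seed = seed
        self.params = {
            "W": np.zeros((d_in, d_out)),
            "b": np.zeros(d_out),
        }
        self.x_mean = np.zeros(d_in)
        self.x_std = np.ones(d_in)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.x_mean) / self.x_std

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.params["W"] + self.params["b"]

    def loss_and_dlogits(self, z, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def grads(self, Xt, dz):
        return {"W": Xt.T @ dz, "b": dz.sum(axis=0)}

    def fit(self, X: np.ndarray, y: np.ndarray, config: ProbeConfig) -> "LinearHead":
        X = np.asarray(X, dtype=np.float64)
        self.x_mean = X.mean(axis=0)
        self.x_std = X.std(axis=0)
        self.x_std[self.x_std == 0] = 1.0
        Xt = self.transform(X)
        rng = np.random.default_rng(config.seed)
        opt = AdamW(self.params, weight_decay=0.0)
        n = X.shape[0]
        for _ in range(config.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                z = Xt[idx] @ self.params["W"] + self.params["b"]
                _, dz = self.loss_and_dlogits(z, y[idx])
                opt.step(self.grads(Xt[idx], dz), config.lr)
        return self


class LinearClassifier(LinearHead):
    """Linear layer under cross-entropy; no class weighting or resampling."""

    def __init__(self, d_in, classes, seed=0):
        super().__init__(d_in, len(classes), seed)
        self.classes = tuple(classes)

    def loss_and_dlogits(self, z, y):
        p = _softmax(z)
        n = z.shape[0]
        loss = float(-np.log(p[np.arange(n), y] + 1e-300).mean())
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        return loss, dz / n


class CompositionProbe(LinearHead):
    """Linear layer + softmax output under MSE; predictions are always
    row-stochastic."""

    def __init__(self, d_in, categories, seed=0):
        super().__init__(d_in, len(categories), seed)
        self.categories = tuple(categories)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(X))

    def loss_and_dlogits(self, z, y):
        p = _softmax(z)
        diff = p - y
        loss = float((diff**2).mean())
        dp = 2.0 * diff / diff.size
        dz = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        return loss, dz


class DensityProbe(LinearHead):
    """Scalar linear regression under MSE."""

    def __init__(self, d_in, seed=0):
        super().__init__(d_in, 1, seed)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.logits(X).ravel()

    def loss_and_dlogits(self, z, y):
        diff = z.ravel() - y
        loss = float((diff**2).mean())
        return loss, (2.0 * diff / diff.size)[:, None]


def train_linear_classifier(
    embeddings: np.ndarray, labels, config: ProbeConfig = ProbeConfig()
) -> LinearClassifier:
    """Train the label-prediction probe on the given (train-split) cells."""
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    y = np.searchsorted(np.asarray(classes), labels)
    clf = LinearClassifier(embeddings.shape[1], classes, seed=config.seed)
    clf.fit(embeddings, y, config)
    return clf


def predict_labels(classifier: LinearClassifier, embeddings: np.ndarray) -> LabeledPrediction:
    """Argmax prediction (ties break to the lowest class index) with softmax
    certainty."""
    probs = _softmax(classifier.logits(embeddings))
    pred = probs.argmax(axis=1)
    labels = np.asarray(classifier.classes)[pred]
    certainty = probs[np.arange(len(pred)), pred]
    return LabeledPrediction(labels, certainty, probs, classifier.classes)


def train_composition_probe(
    embeddings: np.ndarray, targets: np.ndarray, config: ProbeConfig = ProbeConfig(),
    categories=None,
) -> CompositionProbe:
    targets = np.asarray(targets, dtype=np.float64)
    if not np.allclose(targets.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("composition targets must be row-stochastic")
    cats = tuple(categories) if categories is not None else tuple(range(targets.shape[1]))
    probe = CompositionProbe(embeddings.shape[1], cats, seed=config.seed)
    probe.fit(embeddings, targets, config)
    return probe


def train_density_probe(
    embeddings: np.ndarray, densities: np.ndarray, config: ProbeConfig = ProbeConfig()
) -> DensityProbe:
    densities = np.asarray(densities, dtype=np.float64)
    if np.unique(densities).size < 2:
        raise ValueError("density targets are constant")
    probe = DensityProbe(embeddings.shape[1], seed=config.seed)
    probe.fit(embeddings, densities, config)
    return probe


class MultitaskMLP:
    """Shared-hidden MLP with one softmax composition head per neighborhood
    size; optimized on the unweighted mean of per-size MSE losses."""

    def __init__(self, d_in: int, n_classes: int, sizes, d_hidden: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        lim1 = np.sqrt(6.0 / (d_in + d_hidden))
        self.sizes = tuple(sizes)
        self.params = {
            "W1": rng.uniform(-lim1, lim1, size=(d_in, d_hidden)),
            "b1": np.zeros(d_hidden),
        }
        self.x_mean = np.zeros(d_in)
        self.x_std = np.ones(d_in)
        lim2 = np.sqrt(6.0 / (d_hidden + n_classes))
        for s in self.sizes:
            self.params[f"W_{s}"] = rng.uniform(-lim2, lim2, size=(d_hidden, n_classes))
            self.params[f"b_{s}"] = np.zeros(n_classes)

    def _hidden(self, X):
        X = (np.asarray(X, dtype=np.float64) - self.x_mean) / self.x_std
        z = X @ self.params["W1"] + self.params["b1"]
        return z, _gelu(z)

    def predict(self, X: np.ndarray) -> dict:
        _, h = self._hidden(X)
        return {
            s: _softmax(h @ self.params[f"W_{s}"] + self.params[f"b_{s}"]) for s in self.sizes
        }

    def loss(self, X: np.ndarray, targets: dict) -> float:
        preds = self.predict(X)
        return float(np.mean([((preds[s] - targets[s]) ** 2).mean() for s in self.sizes]))

    def fit(self, X: np.ndarray, targets: dict, config: ProbeConfig) -> "MultitaskMLP":
        X = np.asarray(X, dtype=np.float64)
        self.x_mean = X.mean(axis=0)
        self.x_std = X.std(axis=0)
        self.x_std[self.x_std == 0] = 1.0
        rng = np.random.default_rng(config.seed)
        opt = AdamW(self.params, weight_decay=0.0)
        n = X.shape[0]
        for _ in range(config.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                Xb = X[idx]
                z, h = self._hidden(Xb)
                grads = {k: np.zeros_like(v) for k, v in self.params.items()}
                dh = np.zeros_like(h)
                for s in self.sizes:
                    zs = h @ self.params[f"W_{s}"] + self.params[f"b_{s}"]
                    p = _softmax(zs)
                    diff = p - targets[s][idx]
                    dp = 2.0 * diff / diff.size / len(self.sizes)
                    dz = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
                    grads[f"W_{s}"] = h.T @ dz
                    grads[f"b_{s}"] = dz.sum(axis=0)
                    dh += dz @ self.params[f"W_{s}"].T
                dz1 = dh * _gelu_grad(z)
                Xt = (Xb - self.x_mean) / self.x_std
                grads["W1"] = Xt.T @ dz1
                grads["b1"] = dz1.sum(axis=0)
                opt.step(grads, config.lr)
        return self


def train_multitask_mlp(
    embeddings: np.ndarray,
    targets_by_size: dict,
    config: ProbeConfig = ProbeConfig(),
    d_hidden: int = 256,
) -> MultitaskMLP:
    """Train the multitask composition MLP across neighborhood sizes.

    All sizes must provide a target matrix over the same cells.
    """
    n = embeddings.shape[0]
    shapes = {s: np.asarray(t).shape for s, t in targets_by_size.items()}
    if any(shape[0] != n for shape in shapes.values()):
        raise ValueError("all neighborhood sizes must cover the same cells")
    n_classes = next(iter(shapes.values()))[1]
    targets = {s: np.asarray(t, dtype=np.float64) for s, t in targets_by_size.items()}
    mlp = MultitaskMLP(embeddings.shape[1], n_classes, targets.keys(), d_hidden, config.seed)
    mlp.fit(embeddings, targets, config)
    return mlp


def fine_tune(
    model: EncoderModel,
    head: LinearHead,
    batch: TokenizedBatch,
    targets: np.ndarray,
    config: FineTuneConfig = FineTuneConfig(),
) -> tuple[EncoderModel, LinearHead]:
    """Jointly update encoder and head for the configured number of epochs.

    The head consumes the mean of last-layer gene-token outputs; its loss
    gradient is backpropagated through the pooling into the encoder. The
    learning rate follows a cosine decay from ``lr_max`` to ``lr_min`` over
    the run. The model and head are updated in place and returned.
    """
    n = batch.n_cells
    cells_per_step = config.batch_size * config.grad_accumulation
    total_steps = (n * config.epochs) // cells_per_step
    if total_steps == 0:  # too little data for even one optimizer step
        return model, head
    sched = TrainSchedule(
        total_steps=total_steps, warmup_steps=0,
        lr_min=config.lr_min, lr_max=config.lr_max, seed=config.seed,
        batch_size=config.batch_size, grad_accumulation=config.grad_accumulation,
    )
    rng = np.random.default_rng(config.seed)
    enc_opt = AdamW(model.params, betas=sched.betas, weight_decay=sched.weight_decay)
    head_opt = AdamW(head.params, weight_decay=0.0)
    is_classifier = isinstance(head, LinearClassifier)
    if is_classifier:
        y_all = np.searchsorted(np.asarray(head.classes), np.asarray(targets))
    else:
        y_all = np.asarray(targets, dtype=np.float64)

    order = rng.permutation(n)
    cursor = 0
    for step in range(total_steps):
        enc_grads = model.zero_grads()
        head_grads = {k: np.zeros_like(v) for k, v in head.params.items()}
        for _ in range(config.grad_accumulation):
            if cursor + config.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            idx = order[cursor : cursor + config.batch_size]
            cursor += config.batch_size
            hidden, _, _, cache = model.forward(batch.tokens[idx], need_cache=True)
            B = len(idx)
            pooled = np.stack(
                [hidden[i, N_CONTEXT : batch.n_real[idx[i]]].mean(axis=0) for i in range(B)]
            )
            z = head.logits(pooled)
            _, dz = head.loss_and_dlogits(z, y_all[idx])
            hg = head.grads(head.transform(pooled), dz)
            for k in head_grads:
                head_grads[k] += hg[k]
            d_pooled = (dz @ head.params["W"].T) / head.x_std
            d_hidden = np.zeros_like(hidden)
            for i in range(B):
                span = slice(N_CONTEXT, batch.n_real[idx[i]])
                d_hidden[i, span] = d_pooled[i] / (batch.n_real[idx[i]] - N_CONTEXT)
            g = model.backward(cache, d_hidden=d_hidden)
            for k in enc_grads:
                enc_grads[k] += g[k]
        for k in enc_grads:
            enc_grads[k] /= config.grad_accumulation
        for k in head_grads:
            head_grads[k] /= config.grad_accumulation
        lr = lr_at_step(sched, step)
        clip_by_global_norm(enc_grads, 1.0)
        enc_opt.step(enc_grads, lr)
        head_opt.step(head_grads, lr)
    return model, head


def evaluate(predictions, truth, task: str) -> float:
    """Task metric: ``label`` -> macro-F1, ``composition`` -> MAE,
    ``density`` -> R².

    Macro-F1 averages per-class F1 over classes present in either the truth
    or the predictions; classes absent from both are excluded.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0:
        raise ValueError("empty input")
    if task == "label":
        labels = np.union1d(np.unique(truth), np.unique(predictions))
        return float(f1_score(truth, predictions, labels=labels, average="macro", zero_division=0))
    if task == "composition":
        return float(mean_absolute_error(truth, predictions))
    if task == "density":
        return float(r2_score(truth, predictions))
    raise ValueError(f"unknown task {task!r}")
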