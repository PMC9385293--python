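"""Recurrent classification of spectral feature sequences.

Each specimen becomes a sequence with one time step per selected wavelength
(the wavelength axis is the only ordered axis available), the step features
being the masked mean and masked SD of that wavelength's image.  An Elman
cell (``h_t = tanh(W_ih x_t + W_hh h_{t-1} + b_h)``) followed by a softmax
readout of the final hidden state assigns cancer/normal labels; training is
full-batch gradient descent on cross-entropy with backpropagation through
time, global gradient-norm clipping, and an exponentially decaying learning
rate ``lr(t) = lr0 * exp(-decay_rate * t)`` (a multiply-by-``decay_rate``
step schedule is selectable instead).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RnnConfig",
    "RnnModel",
    "stack_to_sequence",
    "lr_schedule",
    "rnn_forward",
    "rnn_train",
    "predict",
    "save_model",
    "load_model",
]

GRAD_CLIP = 5.0


@dataclass(frozen=True)
class RnnConfig:
    """Architecture and training hyperparameters.

    decay_mode ``"continuous"`` gives ``lr0 * exp(-decay_rate * epoch)``;
    ``"step"`` gives ``lr0 * decay_rate ** epoch``.
    """

    input_size: int = 2
    hidden_size: int = 32
    n_classes: int = 2
    lr0: float = 0.01
    decay_rate: float = 0.1
    decay_mode: str = "continuous"
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 < 0:
            raise ValueError("lr0 must be >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.decay_mode not in ("continuous", "step"):
            raise ValueError("decay_mode must be 'continuous' or 'step'")
        if self.input_size < 1 or self.hidden_size < 1 or self.n_classes < 2:
            raise ValueError("invalid architecture sizes")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class RnnModel:
    """Elman-cell weights plus training history and input standardisation."""

    w_ih: np.ndarray
    w_hh: np.ndarray
    b_h: np.ndarray
    w_ho: np.ndarray
    b_o: np.ndarray
    config: RnnConfig
    loss_history: list[float] = field(default_factory=list)
    accuracy_history: list[float] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def standardize(self, seq: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return seq
        return (seq - self.feature_mean) / self.feature_std


def init_model(config: RnnConfig) -> RnnModel:
    rng = np.random.default_rng(config.seed)
    h, d, c = config.hidden_size, config.input_size, config.n_classes
    return RnnModel(
        w_ih=rng.normal(0.0, 1.0 / np.sqrt(d), size=(h, d)),
        w_hh=rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, h)),
        b_h=np.zeros(h),
        w_ho=rng.normal(0.0, 1.0 / np.sqrt(h), size=(c, h)),
        b_o=np.zeros(c),
        config=config,
    )


def stack_to_sequence(
    stack: np.ndarray, mask: np.ndarray, selected: np.ndarray
) -> np.ndarray:
    """Sequence of (masked mean, masked SD) per selected wavelength, T x 2.

    Steps are ordered by wavelength index regardless of the order of
    ``selected``.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    selected = np.sort(np.unique(np.asarray(selected, dtype=int)))
    if mask.sum() == 0:
        raise ValueError("mask is empty; no lesion pixels to summarise")
    if selected.size == 0:
        raise ValueError("no wavelengths selected")
    if selected.min() < 0 or selected.max() >= stack.shape[2]:
        raise ValueError("selected wavelength index out of range")
    vals = stack[mask][:, selected]  # (n_pixels, T)
    return np.stack([vals.mean(axis=0), vals.std(axis=0)], axis=1)


def lr_schedule(epoch: int, config: RnnConfig) -> float:
    """Learning rate at a given epoch; strictly decreasing for decay_rate > 0."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.decay_mode == "step":
        return config.lr0 * config.decay_rate**epoch
    return config.lr0 * float(np.exp(-config.decay_rate * epoch))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def rnn_forward(
    sequence: np.ndarray, model: RnnModel, return_states: bool = False
):
    """Class-probability vector for one T x input_size sequence (h_0 = 0)."""
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.w_ih.shape[1]:
        raise ValueError(
            f"sequence must be T x {model.w_ih.shape[1]}, got {x.shape}"
        )
    h = np.zeros(model.w_hh.shape[0])
    states = [h]
    for t in range(x.shape[0]):
        h = np.tanh(model.w_ih @ x[t] + model.w_hh @ h + model.b_h)
        states.append(h)
    probs = _softmax(model.w_ho @ h + model.b_o)
    if return_states:
        return probs, states
    return probs


def _bptt_grads(
    x: np.ndarray, label: int, model: RnnModel
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss and gradients for one sequence, by unrolling."""
    probs, states = rnn_forward(x, model, return_states=True)
    loss = -float(np.log(probs[label] + 1e-300))
    dlogits = probs.copy()
    dlogits[label] -= 1.0

    g = {
        "w_ih": np.zeros_like(model.w_ih),
        "w_hh": np.zeros_like(model.w_hh),
        "b_h": np.zeros_like(model.b_h),
        "w_ho": np.outer(dlogits, states[-1]),
        "b_o": dlogits,
    }
    dh = model.w_ho.T @ dlogits
    for t in range(x.shape[0] - 1, -1, -1):
        da = dh * (1.0 - states[t + 1] ** 2)  # through tanh
        g["w_ih"] += np.outer(da, x[t])
        g["w_hh"] += np.outer(da, states[t])
        g["b_h"] += da
        dh = model.w_hh.T @ da
    return loss, g


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((v**2).sum()) for v in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for v in grads.values():
            v *= scale


def rnn_train(
    dataset: list[tuple[np.ndarray, int]], config: RnnConfig
) -> RnnModel:
    """Gradient descent with BPTT on (sequence, label) pairs.

    Updates are per example (shuffled each epoch with a seed derived from the
    config): with the aggressively decaying learning-rate schedule this gives
    each epoch n gradient steps' worth of progress, where a single full-batch
    step would leave the network near its initialisation.  Inputs are
    z-scored per feature over the whole training set (the scaler is stored on
    the model and applied at prediction time).  Per-epoch mean loss and
    training accuracy are recorded.
    """
    if len(dataset) < 2:
        raise ValueError("need at least two training examples")
    labels = np.asarray([int(lab) for _, lab in dataset])
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both classes")

    model = init_model(config)
    all_steps = np.concatenate([np.asarray(s, dtype=float) for s, _ in dataset], axis=0)
    model.feature_mean = all_steps.mean(axis=0)
    model.feature_std = all_steps.std(axis=0) + 1e-8
    seqs = [model.standardize(np.asarray(s, dtype=float)) for s, _ in dataset]

    n = len(dataset)
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    params = _param_dict(model)
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        order = order_rng.permutation(n)
        loss_sum = 0.0
        for i in order:
            loss, g = _bptt_grads(seqs[i], int(labels[i]), model)
            loss_sum += loss
            _clip_global_norm(g, GRAD_CLIP)
            for k in params:
                params[k] -= lr * g[k]
        correct = sum(
            int(np.argmax(rnn_forward(x, model)) == lab)
            for x, lab in zip(seqs, labels)
        )
        model.loss_history.append(loss_sum / n)
        model.accuracy_history.append(correct / n)
    return model


def _param_dict(model: RnnModel) -> dict[str, np.ndarray]:
    return {
        "w_ih": model.w_ih,
        "w_hh": model.w_hh,
        "b_h": model.b_h,
        "w_ho": model.w_ho,
        "b_o": model.b_o,
    }


def predict(
    sequences: list[np.ndarray], model: RnnModel
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (argmax; ties -> class 0) and probability matrix for sequences."""
    probs = np.stack(
        [rnn_forward(model.standardize(np.asarray(s, dtype=float)), model) for s in sequences]
    )
    return np.argmax(probs, axis=1), probs


def save_model(model: RnnModel, path: str | Path) -> None:
    """Serialise weights, scaler and history to a single JSON container."""
    path = Path(path)
    payload = {
        "config": model.config.__dict__,
        "params": {k: v.tolist() for k, v in _param_dict(model).items()},
        "feature_mean": None if model.feature_mean is None else model.feature_mean.tolist(),
        "feature_std": None if model.feature_std is None else model.feature_std.tolist(),
        "loss_history": model.loss_history,
        "accuracy_history": model.accuracy_history,
    }
    path.write_text(json.dumps(payload))


def load_model(path: str | Path) -> RnnModel:
    payload = json.loads(Path(path).read_text())
    config = RnnConfig(**payload["config"])
    p = {k: np.asarray(v) for k, v in payload["params"].items()}
    model = RnnModel(
        w_ih=p["w_ih"], w_hh=p["w_hh"], b_h=p["b_h"], w_ho=p["w_ho"], b_o=p["b_o"],
        config=config,
        loss_history=list(payload["loss_history"]),
        accuracy_history=list(payload["accuracy_history"]),
    )
    if payload["feature_mean"] is not None:
        model.feature_mean = np.asarray(payload["feature_mean"])
        model.feature_std = np.asarray(payload["feature_std"])
    return model
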