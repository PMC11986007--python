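"""Neural-network snapshot reconstruction.

A fully connected network maps the 882-component HG measurement vector
(real/imaginary parts of 441 mode amplitudes) to a 50 x 50 reconstructed
snapshot: layer widths 882-800-400-400-800-2500 with tanh on the first
hidden layer, ReLU on the remaining three and a sigmoid output, trained
with Adam (lr 1e-4, betas 0.9/0.999, no weight decay), batch size 32 and a
mean-squared-error loss against slightly smeared ground-truth labels.

The network is a compensator, not the physics: the damped-pseudoinverse
reconstructor in :mod:`hgiscan.hgi` is the default route, and on clean
simulated data the network should approach, not beat, it.  Everything here
is plain numpy (forward pass, backpropagation, Adam), seed-controlled and
CPU-sized: the package-scale defaults train on 2000 samples for 50 epochs,
with the full recipe (20000 samples, 5000 epochs, best-validation
checkpoint for widefield labels) available through the same interface.

``MLPReconstructor`` follows the scikit-learn estimator idiom: constructor
parameters mirror ``get_params``-style keywords, ``fit`` learns from
(measurements, labels) and fitted state lives in trailing-underscore
attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPSpec", "TrainConfig", "Model", "MLPReconstructor",
           "build_model", "train", "reconstruct"]

_ACTS = ("tanh", "relu", "relu", "relu", "sigmoid")


@dataclass(frozen=True)
class MLPSpec:
    """Layer stack of the reconstruction network."""

    layers: tuple[int, ...] = (882, 800, 400, 400, 800, 2500)
    activations: tuple[str, ...] = _ACTS

    def __post_init__(self) -> None:
        if len(self.activations) != len(self.layers) - 1:
            raise ValueError("one activation per non-input layer is required")
        for a in self.activations:
            if a not in ("tanh", "relu", "sigmoid", "linear"):
                raise ValueError(f"unknown activation {a!r}")


@dataclass
class TrainConfig:
    """Optimisation recipe (Adam, MSE).

    ``epoch_selection``: ``"best_val"`` restores the weights of the epoch
    with the lowest validation loss (the widefield recipe -- early
    overfitting); ``"final"`` keeps the last epoch (the scanning recipe).
    """

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    betas: tuple[float, float] = (0.9, 0.999)
    epoch_selection: str = "best_val"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_selection not in ("best_val", "final"):
            raise ValueError("epoch_selection must be 'best_val' or 'final'")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return z


def _act_grad(name: str, a: np.ndarray) -> np.ndarray:
    # gradients expressed through the activation value
    if name == "tanh":
        return 1.0 - a * a
    if name == "relu":
        return (a > 0).astype(a.dtype)
    if name == "sigmoid":
        return a * (1.0 - a)
    return np.ones_like(a)


class Model:
    """Weights + biases of the MLP, with forward/backward passes."""

    def __init__(self, spec: MLPSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(spec.layers[:-1], spec.layers[1:]):
            bound = np.sqrt(1.0 / fan_in)  # fan-in-scaled uniform init
            self.weights.append(rng.uniform(-bound, bound,
                                            (fan_in, fan_out)).astype(np.float32))
            self.biases.append(rng.uniform(-bound, bound,
                                           fan_out).astype(np.float32))

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, x: np.ndarray, keep: bool = False):
        a = np.asarray(x, dtype=np.float32)
        cache = [a]
        for w, b, name in zip(self.weights, self.biases, self.spec.activations):
            a = _act(name, a @ w + b)
            if keep:
                cache.append(a)
        return (a, cache) if keep else a

    def backward(self, cache: list[np.ndarray], grad_out: np.ndarray):
        grads_w, grads_b = [], []
        delta = grad_out
        for layer in range(len(self.weights) - 1, -1, -1):
            a_out = cache[layer + 1]
            delta = delta * _act_grad(self.spec.activations[layer], a_out)
            grads_w.append(cache[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer:
                delta = delta @ self.weights[layer].T
        return grads_w[::-1], grads_b[::-1]

    def state(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights] + [b.copy() for b in self.biases]

    def load_state(self, state: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [s.copy() for s in state[:k]]
        self.biases = [s.copy() for s in state[k:]]

    def save(self, path: str) -> None:
        """Self-describing checkpoint: layer sizes + flat parameter blocks."""
        np.savez(path, layers=np.array(self.spec.layers),
                 activations=np.array(self.spec.activations),
                 **{f"w{i}": w for i, w in enumerate(self.weights)},
                 **{f"b{i}": b for i, b in enumerate(self.biases)})

    @classmethod
    def load(cls, path: str) -> "Model":
        data = np.load(path, allow_pickle=False)
        spec = MLPSpec(tuple(int(v) for v in data["layers"]),
                       tuple(str(v) for v in data["activations"]))
        model = cls(spec, seed=0)
        model.weights = [data[f"w{i}"] for i in range(len(spec.layers) - 1)]
        model.biases = [data[f"b{i}"] for i in range(len(spec.layers) - 1)]
        return model


def build_model(spec: MLPSpec | None = None, seed: int = 0) -> Model:
    """Initialised network with the exact layer/activation stack."""
    return Model(spec or MLPSpec(), seed)


def train(model: Model, x: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None,
          x_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None,
          normalise: bool = True) -> dict:
    """Adam/MSE training loop; returns per-epoch train/validation losses.

    Inputs are scaled by the per-component standard deviation of the
    training set (stored in the returned dict and applied automatically by
    :func:`reconstruct` when passed along).  Data order is reshuffled each
    epoch from a seed-derived stream, so runs are reproducible.
    """
    cfg = config or TrainConfig()
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.shape[1] != model.spec.layers[0] or y.shape[1] != model.spec.layers[-1]:
        raise ValueError(
            f"data shapes {x.shape[1]}/{y.shape[1]} do not match the model "
            f"({model.spec.layers[0]} in, {model.spec.layers[-1]} out)")
    scale = x.std(axis=0)
    scale[scale < 1e-12] = 1.0
    if not normalise:
        scale = np.ones_like(scale)
    xn = x / scale
    xv = None if x_val is None else np.asarray(x_val, np.float32) / scale
    yv = None if y_val is None else np.asarray(y_val, np.float32)

    rng = np.random.default_rng(cfg.seed)
    b1, b2 = cfg.betas
    eps = 1e-8
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    step = 0
    train_curve, val_curve = [], []
    best = (np.inf, None, -1)
    n = len(xn)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb, yb = xn[idx], y[idx]
            out, cache = model.forward(xb, keep=True)
            err = out - yb
            epoch_loss += float((err**2).sum())
            grad = (2.0 / err.size) * err
            gw, gb = model.backward(cache, grad)
            step += 1
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            for i in range(len(model.weights)):
                m_w[i] = b1 * m_w[i] + (1 - b1) * gw[i]
                v_w[i] = b2 * v_w[i] + (1 - b2) * gw[i] ** 2
                model.weights[i] -= cfg.learning_rate * (m_w[i] / corr1) / (
                    np.sqrt(v_w[i] / corr2) + eps)
                m_b[i] = b1 * m_b[i] + (1 - b1) * gb[i]
                v_b[i] = b2 * v_b[i] + (1 - b2) * gb[i] ** 2
                model.biases[i] -= cfg.learning_rate * (m_b[i] / corr1) / (
                    np.sqrt(v_b[i] / corr2) + eps)
        train_curve.append(epoch_loss / (n * y.shape[1]))
        if xv is not None:
            pred = model.forward(xv)
            vloss = float(((pred - yv) ** 2).mean())
            val_curve.append(vloss)
            if vloss < best[0]:
                best = (vloss, model.state(), epoch)
    selected = cfg.epochs - 1
    if cfg.epoch_selection == "best_val" and best[1] is not None:
        model.load_state(best[1])
        selected = best[2]
    return {
        "train_loss": np.array(train_curve),
        "val_loss": np.array(val_curve),
        "input_scale": scale,
        "selected_epoch": selected,
    }


def reconstruct(model: Model, measurements: np.ndarray,
                input_scale: np.ndarray | None = None) -> np.ndarray:
    """Forward pass: measurement vector(s) -> 50 x 50 snapshot raster(s).

    Accepts a single vector or a batch (rows); order is preserved.
    """
    arr = np.asarray(measurements, dtype=np.float32)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != model.spec.layers[0]:
        raise ValueError(
            f"measurement length {arr.shape[1]} does not match the model "
            f"input ({model.spec.layers[0]})")
    if input_scale is not None:
        arr = arr / np.asarray(input_scale, dtype=np.float32)
    out = model.forward(arr)
    side = int(round(np.sqrt(model.spec.layers[-1])))
    imgs = out.reshape(-1, side, side)
    return imgs[0] if single else imgs


class MLPReconstructor:
    """Scikit-learn-style estimator wrapping :class:`Model` + :func:`train`.

    Parameters mirror :class:`TrainConfig`; after ``fit`` the trained
    network lives in ``model_`` with ``loss_curve_``, ``val_loss_curve_``,
    ``input_scale_`` and ``selected_epoch_``.
    """

    def __init__(self, spec: MLPSpec | None = None, learning_rate: float = 1e-4,
                 batch_size: int = 32, epochs: int = 50,
                 epoch_selection: str = "best_val", seed: int = 0) -> None:
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.epoch_selection = epoch_selection
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("spec", "learning_rate", "batch_size", "epochs",
                 "epoch_selection", "seed")}

    def set_params(self, **params) -> "MLPReconstructor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, x: np.ndarray, y: np.ndarray, split_index: int | None = None
            ) -> "MLPReconstructor":
        """Train on (measurements, labels); rows past ``split_index`` (default
        a 9:1 split) form the validation subset."""
        x = np.asarray(x, np.float32)
        y = np.asarray(y, np.float32).reshape(len(x), -1)
        if split_index is None:
            split_index = int(round(0.9 * len(x)))
        self.model_ = build_model(self.spec, self.seed)
        cfg = TrainConfig(self.learning_rate, self.batch_size, self.epochs,
                          epoch_selection=self.epoch_selection, seed=self.seed)
        result = train(self.model_, x[:split_index], y[:split_index], cfg,
                       x_val=x[split_index:] if split_index < len(x) else None,
                       y_val=y[split_index:] if split_index < len(x) else None)
        self.loss_curve_ = result["train_loss"]
        self.val_loss_curve_ = result["val_loss"]
        self.input_scale_ = result["input_scale"]
        self.selected_epoch_ = result["selected_epoch"]
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the reconstructor before predicting")
        return reconstruct(self.model_, x, self.input_scale_)
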