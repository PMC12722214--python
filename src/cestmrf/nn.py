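"""Fully connected regression networks for parameter decoding.

Small multilayer perceptrons (ReLU hidden layers, sigmoid output) trained
with Adam on mean squared error over min-max-scaled targets.  The sigmoid
output combined with per-parameter affine scaling guarantees every
prediction lies inside the training grid's parameter range.  Implemented
directly on NumPy (float32 compute) so training is bit-reproducible for a
given seed on a fixed BLAS.

Defaults follow the quantification setup used throughout the package:
learning rate 2e-4, minibatch 1024, two hidden layers of 300 neurons
(four for the combined amide/glutamate network), Gaussian noise injected
into the training trajectories for robustness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["NetworkSpec", "TrainingConfig", "MLP", "train_mlp"]

HIDDEN_WIDTH = 300


@dataclass
class NetworkSpec:
    """Architecture + output scaling of one quantification network."""

    input_size: int
    output_names: list[str]
    output_scaling: dict[str, tuple[float, float]]  # name -> (min, max)
    hidden_layers: list[int] = field(default_factory=lambda: [HIDDEN_WIDTH] * 2)
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"

    def validate(self) -> None:
        if self.input_size <= 0:
            raise ValueError("input_size must be positive")
        if set(self.output_names) != set(self.output_scaling):
            raise ValueError("output_scaling must cover exactly output_names")
        for name, (lo, hi) in self.output_scaling.items():
            if not hi > lo:
                raise ValueError(f"degenerate scaling range for {name!r}")

    def scale_targets(self, physical: np.ndarray) -> np.ndarray:
        """(n, n_out) physical values -> (0, 1) training targets."""
        out = np.empty_like(physical, dtype=float)
        for j, name in enumerate(self.output_names):
            lo, hi = self.output_scaling[name]
            out[:, j] = (physical[:, j] - lo) / (hi - lo)
        return out

    def unscale_outputs(self, scaled: np.ndarray) -> np.ndarray:
        out = np.empty_like(scaled, dtype=float)
        for j, name in enumerate(self.output_names):
            lo, hi = self.output_scaling[name]
            out[:, j] = lo + scaled[:, j] * (hi - lo)
        return out

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "output_names": list(self.output_names),
            "output_scaling": {k: [float(a), float(b)]
                               for k, (a, b) in self.output_scaling.items()},
            "hidden_layers": list(self.hidden_layers),
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["output_scaling"] = {k: (float(v[0]), float(v[1]))
                               for k, v in d["output_scaling"].items()}
        return cls(**d)


@dataclass
class TrainingConfig:
    learning_rate: float = 2e-4
    minibatch: int = 1024
    noise_sigma: float = 0.01  # fraction of M0, injected per epoch
    max_epochs: int = 200
    patience: int = 10  # early stopping on validation MSE
    validation_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


class MLP:
    """Weights + forward pass; see :func:`train_mlp` for optimization."""

    def __init__(self, spec: NetworkSpec, rng: Optional[np.random.Generator] = None):
        spec.validate()
        self.spec = spec
        sizes = [spec.input_size] + list(spec.hidden_layers) + [len(spec.output_names)]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        rng = rng or np.random.default_rng(0)
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack.
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(
                (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32))
            self.biases.append(np.zeros(fan_out, dtype=np.float32))
        self.schedule_hashes: dict[str, str] = {}
        self.training_log: dict = {}
        self.extras: dict = {}  # e.g. input assembly recipe, free-form JSON

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray, return_cache: bool = False):
        h = X.astype(np.float32, copy=False)
        cache = [h]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            cache.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        with np.errstate(over="ignore"):  # saturated sigmoid is fine
            y = 1.0 / (1.0 + np.exp(-logits))
        return (y, cache) if return_cache else y

    def _step_grads(self, X: np.ndarray, Y: np.ndarray):
        y, cache = self.forward(X, return_cache=True)
        n = X.shape[0]
        # MSE loss; d(loss)/d(logits) folds in the sigmoid derivative.
        delta = (2.0 / (n * y.shape[1])) * (y - Y) * y * (1.0 - y)
        gW, gb = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            gW.append(cache[i].T @ delta)
            gb.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (cache[i] > 0)
        loss = float(np.mean((y - Y) ** 2))
        return gW[::-1], gb[::-1], loss

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Physical-unit predictions for raw (already assembled) inputs."""
        return self.spec.unscale_outputs(self.forward(X).astype(float))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        meta = {"spec": self.spec.to_dict(),
                "schedule_hashes": self.schedule_hashes,
                "training_log": self.training_log,
                "extras": self.extras}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MLP":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            model = cls(NetworkSpec.from_dict(meta["spec"]))
            n_layers = len(model.weights)
            model.weights = [data[f"W{i}"].astype(np.float32) for i in range(n_layers)]
            model.biases = [data[f"b{i}"].astype(np.float32) for i in range(n_layers)]
            model.schedule_hashes = meta["schedule_hashes"]
            model.training_log = meta["training_log"]
            model.extras = meta.get("extras", {})
        return model


def train_mlp(model: MLP, sampler, config: TrainingConfig) -> dict:
    """Adam optimization with per-epoch noise resampling and early stopping.

    ``sampler(rng)`` must return the full epoch's ``(X, Y)`` (float32), with
    any noise injection already applied; it is called once per epoch so the
    network sees fresh noise realizations.  A fixed validation split (drawn
    once) monitors generalization; training stops when the validation MSE
    has not improved for ``patience`` epochs or at ``max_epochs``.

    Returns the training log (also stored on ``model.training_log``).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 777])
    X0, Y0 = sampler(rng)
    n = X0.shape[0]
    n_val = max(1, int(round(config.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    lr = np.float32(config.learning_rate)
    beta1, beta2, eps = np.float32(0.9), np.float32(0.999), np.float32(1e-8)
    mW = [np.zeros_like(W) for W in model.weights]
    vW = [np.zeros_like(W) for W in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    t = 0

    history = {"train_mse": [], "val_mse": []}
    best_val = np.inf
    best_weights = None
    stale = 0
    X, Y = X0, Y0
    for epoch in range(config.max_epochs):
        if epoch > 0:
            X, Y = sampler(rng)  # fresh noise realization
        Xtr, Ytr = X[train_idx], Y[train_idx]
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.minibatch):
            sel = order[start: start + config.minibatch]
            gW, gb, loss = model._step_grads(Xtr[sel], Ytr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            epoch_loss += loss
            n_batches += 1
            t += 1
            corr = np.float32(np.sqrt(1 - beta2**t) / (1 - beta1**t))
            for i in range(len(model.weights)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                model.weights[i] -= lr * corr * mW[i] / (np.sqrt(vW[i]) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                model.biases[i] -= lr * corr * mb[i] / (np.sqrt(vb[i]) + eps)
        val_pred = model.forward(X[val_idx])
        val_mse = float(np.mean((val_pred - Y[val_idx]) ** 2))
        history["train_mse"].append(epoch_loss / max(n_batches, 1))
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_weights = ([W.copy() for W in model.weights],
                            [b.copy() for b in model.biases])
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_weights is not None:
        model.weights, model.biases = best_weights
    log = {
        "epochs_run": len(history["val_mse"]),
        "best_val_mse": best_val,
        "train_mse": history["train_mse"],
        "val_mse": history["val_mse"],
        "config": {
            "learning_rate": config.learning_rate, "minibatch": config.minibatch,
            "noise_sigma": config.noise_sigma, "max_epochs": config.max_epochs,
            "patience": config.patience, "seed": config.seed,
            "validation_fraction": config.validation_fraction,
        },
    }
    model.training_log = log
    return log
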