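"""Empirical-risk minimization for the dipole-regression networks.

Plain stochastic gradient descent on the mean-squared error between
predicted and true normalized coordinates, with the protocol defaults
lr = 0.001 and batch size 32.  Data arrives either from an endless
on-the-fly simulation stream or from a fixed offline dataset cycled in
batches.  The whole loop is a pure function of the master seed on the
single-threaded reference path, so checkpoints are bit-reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .networks import (
    CoordinateScaler,
    NetworkSpec,
    forward_backward,
    init_params,
    normalize_inputs,
)

__all__ = ["TrainConfig", "TrainReport", "TrainedModel", "mse_loss", "sgd_step", "train"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    n_steps: int = 1000
    momentum: float = 0.0  # 0 = plain SGD (the reference protocol)
    master_seed: int = 0
    log_every: int = 50
    normalize_input: bool = True

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.n_steps < 1:
            raise ValueError("batch_size and n_steps must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class TrainReport:
    loss_history: list[tuple[int, float]]  # (step, minibatch loss)
    wall_time_s: float
    master_seed: int
    n_steps: int


@dataclass
class TrainedModel:
    """Everything needed for inference: architecture, weights, target scaler."""

    spec: NetworkSpec
    params: list[dict[str, np.ndarray]]
    scaler: CoordinateScaler
    normalize_input: bool = True


def mse_loss(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Mean over batch and coordinates of squared differences."""
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predicted.shape != labels.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {labels.shape}")
    return float(np.mean((predicted - labels) ** 2))


def sgd_step(
    params: list[dict[str, np.ndarray]],
    grads: list[dict[str, np.ndarray]],
    learning_rate: float,
) -> list[dict[str, np.ndarray]]:
    """In-place gradient-descent update theta <- theta - lr * g."""
    for i, (p, g) in enumerate(zip(params, grads)):
        for key in p:
            if not np.all(np.isfinite(g[key])):
                raise FloatingPointError(f"non-finite gradient in layer {i} ({key})")
            p[key] -= learning_rate * g[key]
    return params


def _offline_batches(
    x: np.ndarray, labels: np.ndarray, batch_size: int, rng: np.random.Generator
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    n = x.shape[0]
    while True:
        idx = rng.permutation(n)
        for start in range(0, n - batch_size + 1, batch_size):
            sel = idx[start : start + batch_size]
            yield x[sel], labels[sel]


def train(
    spec: NetworkSpec,
    config: TrainConfig,
    scaler: CoordinateScaler,
    data: Iterator[tuple[np.ndarray, np.ndarray]] | tuple[np.ndarray, np.ndarray],
) -> tuple[TrainedModel, TrainReport]:
    """Run SGD for ``config.n_steps`` minibatches.

    ``data`` is either an endless stream of ``(inputs, labels_m)``
    batches (labels in meters, shape (batch, Q, 3) or (batch, 3Q)) or an
    offline ``(X, labels_m)`` array pair that is shuffled and cycled.
    Labels are converted to normalized units through ``scaler`` inside
    the loop; the loss history is recorded in those units.
    """
    rng = np.random.default_rng(config.master_seed)
    params = init_params(spec, rng)
    velocity = None
    if config.momentum > 0:
        velocity = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]

    if isinstance(data, tuple):
        stream: Iterator = _offline_batches(data[0], data[1], config.batch_size, rng)
    else:
        stream = data

    history: list[tuple[int, float]] = []
    t0 = time.perf_counter()
    for step in range(config.n_steps):
        x, labels_m = next(stream)
        if config.normalize_input:
            x = normalize_inputs(x)
        labels_m = np.asarray(labels_m, dtype=float)
        if labels_m.ndim == 2:  # (batch, 3Q) meters
            labels_m = labels_m.reshape(labels_m.shape[0], spec.q, 3)
        targets = scaler.to_normalized(labels_m)
        loss, grads = forward_backward(spec, params, x, targets)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {step}: loss={loss}")
        if velocity is not None:
            for v, g, p in zip(velocity, grads, params):
                for key in p:
                    v[key] = config.momentum * v[key] + g[key]
                    p[key] -= config.learning_rate * v[key]
        else:
            sgd_step(params, grads, config.learning_rate)
        if step % config.log_every == 0 or step == config.n_steps - 1:
            history.append((step, loss))
    report = TrainReport(
        loss_history=history,
        wall_time_s=time.perf_counter() - t0,
        master_seed=config.master_seed,
        n_steps=config.n_steps,
    )
    model = TrainedModel(
        spec=spec, params=params, scaler=scaler, normalize_input=config.normalize_input
    )
    return model, report
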