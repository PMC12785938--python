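"""Training loop: AdamW on the L2-regularized MSE loss with seeded
mini-batching, an internal validation split and patience-based early
stopping (best-validation parameters restored)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..spectra_core import SpectraSet
from .autograd import Tensor, no_grad
from .layers import Module
from .models import NetConfig, build_network

__all__ = ["AdamW", "TrainedNet", "regularized_loss", "train", "predict_net"]


class AdamW:
    """Adam with decoupled weight decay (decay defaults to 0: by default the
    L2 penalty enters through the loss term instead)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def regularized_loss(predictions: Tensor, targets: np.ndarray,
                     network: Module, l2_lambda: float) -> Tensor:
    """Mean squared error plus ``l2_lambda`` times the sum of squared
    multiplicative weights (biases and batch-norm affines excluded)."""
    y = np.asarray(targets, dtype=float).reshape(-1)
    if y.size == 0:
        raise ValueError("empty batch")
    if predictions.data.size != y.size:
        raise ValueError("predictions and targets differ in length")
    err = predictions.reshape(-1) - Tensor(y)
    loss = (err * err).mean()
    if l2_lambda > 0:
        reg = None
        for w in network.weight_parameters():
            term = (w * w).sum()
            reg = term if reg is None else reg + term
        if reg is not None:
            loss = loss + l2_lambda * reg
    return loss


@dataclass
class TrainedNet:
    config: NetConfig
    network: Module
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    input_length: int = 0

    @property
    def train_losses(self) -> np.ndarray:
        return np.array([h["train_loss"] for h in self.history])


def _as_batch(X: np.ndarray) -> Tensor:
    return Tensor(X[:, None, :])  # (N, 1, L)


def train(network: Module, calibration: SpectraSet, config: NetConfig,
          val_fraction: float = 0.1, verbose: bool = False) -> TrainedNet:
    """Fit ``network`` on calibration spectra (already normalized).

    A seeded ``val_fraction`` split of the calibration rows drives early
    stopping; the best-validation parameter state is restored at the end.
    """
    X = calibration.absorbance
    y = calibration.target
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = AdamW(network.parameters(), lr=config.learning_rate)
    best_val, best_state, best_epoch = np.inf, network.copy_state(), -1
    history: list[dict] = []
    wait = 0
    for epoch in range(config.max_epochs):
        network.train()
        order = rng.permutation(len(tr_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size < 2:
                continue  # batch norm needs more than one row
            opt.zero_grad()
            pred = network(_as_batch(Xtr[batch]))
            loss = regularized_loss(pred, ytr[batch], network, config.l2_lambda)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        network.eval()
        with no_grad():
            val_pred = network(_as_batch(Xval)).data.reshape(-1)
        val_rmse = float(np.sqrt(np.mean((val_pred - yval) ** 2)))
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(epoch_losses)),
                        "val_rmse": val_rmse})
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch}: train {history[-1]['train_loss']:.5f} val {val_rmse:.5f}")
        if val_rmse < best_val - 1e-9:
            best_val, best_state, best_epoch = val_rmse, network.copy_state(), epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    network.load_state(best_state)
    network.eval()
    return TrainedNet(config=config, network=network, history=history,
                      best_epoch=best_epoch, input_length=X.shape[1])


def fit_net(calibration: SpectraSet, config: NetConfig,
            val_fraction: float = 0.1) -> TrainedNet:
    """Build + train in one call."""
    net = build_network(config, calibration.n_wavelengths)
    return train(net, calibration, config, val_fraction=val_fraction)


def predict_net(model: TrainedNet, data: SpectraSet) -> np.ndarray:
    """Deterministic inference (dropout off, batch norm in running-stats
    mode); one prediction per row."""
    if data.n_wavelengths != model.input_length:
        raise ValueError(
            f"model expects {model.input_length} wavelengths, got {data.n_wavelengths}"
        )
    model.network.eval()
    with no_grad():
        return model.network(_as_batch(data.absorbance)).data.reshape(-1)
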