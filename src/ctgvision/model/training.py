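"""Training loop: Adam, cross-entropy, early stopping with best-weight restore.

Defaults mirror the reported training regimen for the full-size model: Adam
with learning rate 1e-4, batch size 64, weight decay 1e-5, and early stopping
with a patience of 5 epochs on the validation loss (the best-epoch weights
are restored on stop).  Smoke-scale runs on scaled-down variants typically
override the learning rate; see the training-configuration notes in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, softmax_cross_entropy
from .layers import BatchNorm2d, Module


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    weight_decay: float = 1e-5
    early_stop_patience: int = 5
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay added to the
    gradient (the classic formulation)."""

    def __init__(self, params: list, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def early_stop_epoch(val_losses: list, patience: int) -> tuple[int, int]:
    """Patience bookkeeping on a completed loss sequence.

    Returns ``(stop_epoch, best_epoch)`` as 1-based epoch numbers: training
    stops after the first epoch at which the validation loss has failed to
    improve for ``patience`` consecutive epochs; the best epoch is restored.
    """
    best, best_epoch, since = np.inf, 0, 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, since = loss, epoch, 0
        else:
            since += 1
        if since >= patience:
            return epoch, best_epoch
    return len(val_losses), best_epoch


def reestimate_bn_stats(net: Module, X: np.ndarray,
                        batch_size: int = 64) -> None:
    """Replace BN running statistics with exact training-set averages.

    With few optimizer steps the exponentially averaged running statistics
    lag far behind the batch statistics, and the mismatch compounds across
    the network's many normalization layers, wrecking eval-mode outputs.
    Re-estimating the statistics with a cumulative average over the training
    data (precise-BN) removes that lag at the cost of one extra forward pass.
    """
    bns = [m for m in net.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for m in bns:
        m.running_mean[:] = 0.0
        m.running_var[:] = 0.0
    net.train()
    for t, start in enumerate(range(0, len(X), batch_size), start=1):
        for m in bns:
            m.momentum = 1.0 / t  # cumulative moving average
        net(Tensor(X[start:start + batch_size]))
    for m in bns:
        m.momentum = 0.1


def _forward_loss(net: Module, X: np.ndarray, y: np.ndarray,
                  batch_size: int) -> tuple[float, float]:
    """Mean loss and accuracy over a dataset in eval mode."""
    net.eval()
    losses, correct = [], 0
    for start in range(0, len(X), batch_size):
        xb = Tensor(X[start:start + batch_size])
        yb = y[start:start + batch_size]
        logits = net(xb)
        losses.append(float(softmax_cross_entropy(logits, yb).data) * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def predict_scores(net: Module, X: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    """Positive-class (non-reassuring) probabilities."""
    net.eval()
    out = []
    for start in range(0, len(X), batch_size):
        logits = net(Tensor(X[start:start + batch_size])).data
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        out.append((p / p.sum(axis=1, keepdims=True))[:, 1])
    return np.concatenate(out)


def train_model(net: Module, X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                cfg: TrainConfig | None = None) -> tuple[Module, dict]:
    """Train with Adam + cross-entropy and patience-based early stopping.

    Returns the network with the best-validation-epoch weights restored and
    a history dict with per-epoch train/validation losses and accuracies.
    """
    cfg = cfg or TrainConfig()
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    batch = min(cfg.batch_size, len(X_train))
    opt = Adam(net.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)

    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_loss, best_state, since = np.inf, None, 0
    for _epoch in range(cfg.max_epochs):
        net.train()
        order = rng.permutation(len(X_train))
        epoch_losses = []
        for start in range(0, len(order), batch):
            idx = order[start:start + batch]
            net.zero_grad()
            loss = softmax_cross_entropy(net(Tensor(X_train[idx])),
                                         y_train[idx])
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(idx))
        train_loss = float(np.sum(epoch_losses) / len(X_train))
        reestimate_bn_stats(net, X_train, batch)
        val_loss, val_acc = _forward_loss(net, X_val, y_val, batch)
        _, train_acc = _forward_loss(net, X_train, y_train, batch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)

        if val_loss < best_loss:
            best_loss, since = val_loss, 0
            best_state = net.state_dict()
        else:
            since += 1
        if since >= cfg.early_stop_patience:
            break

    if best_state is not None:
        net.load_state_dict(best_state)
    history["best_epoch"] = int(np.argmin(history["val_loss"])) + 1
    return net, history
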