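"""Training loop for the counting network: Adam, fixed learning rate,
pixel-wise squared-error loss on density maps, best-epoch selection by
validation mean counting error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..metrics import EvaluationBatch, mce, rmse
from .autograd import Tensor, sse_loss
from .model import MFCNN

__all__ = ["TrainingConfig", "TrainingHistory", "Adam", "train"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol: Adam at a fixed learning rate.

    The loss is squared error summed over pixels and averaged over the
    batch.  ``val_fraction`` carves a validation split off the training
    pairs; when it rounds to zero, validation metrics are computed on the
    training set itself.
    """

    batch_size: int = 8
    learning_rate: float = 1e-5
    epochs: int = 50
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch loss and validation metrics; ``best_epoch`` minimizes
    validation MCE."""

    train_loss: list[float] = field(default_factory=list)
    val_mce: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": range(len(self.train_loss)),
                "loss": self.train_loss,
                "mce": self.val_mce,
                "rmse": self.val_rmse,
            }
        )


class Adam:
    """Adam optimizer over the model's parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_density_array(target) -> np.ndarray:
    values = getattr(target, "values", target)
    return np.asarray(values, dtype=np.float32)


def train(
    model: MFCNN, pairs: list[tuple[np.ndarray, object]], tconfig: TrainingConfig
) -> tuple[MFCNN, TrainingHistory]:
    """Train on (image, density-map) pairs; return best-epoch weights.

    Each epoch shuffles the training split, steps Adam per mini-batch, and
    records training loss plus validation MCE/RMSE.  The weights of the
    epoch with minimum validation MCE are restored before returning.  Fully
    seeded: identical inputs give identical loss curves.
    """
    if not pairs:
        raise ValueError("training set must be non-empty")
    images, targets = [], []
    for img, target in pairs:
        arr = MFCNN._to_nchw(img)[0, 0]
        t = _as_density_array(target)
        if arr.shape != t.shape:
            raise ValueError(
                f"density map shape {t.shape} does not match image {arr.shape}"
            )
        images.append(arr)
        targets.append(t)

    rng = np.random.default_rng(tconfig.seed)
    n = len(pairs)
    n_val = int(round(tconfig.val_fraction * n))
    perm = rng.permutation(n)
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training data")
    if len(val_idx) == 0:
        val_idx = train_idx

    opt = Adam(model.params, lr=tconfig.learning_rate)
    history = TrainingHistory()
    best_state: dict[str, np.ndarray] | None = None
    best_mce = np.inf

    for _ in range(tconfig.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), tconfig.batch_size):
            batch = order[start : start + tconfig.batch_size]
            model.zero_grad()
            loss_val = _batch_step(model, images, targets, batch)
            opt.step()
            epoch_loss += loss_val * len(batch)
        history.train_loss.append(epoch_loss / len(order))

        gts, preds = [], []
        for i in val_idx:
            pred = model.forward(images[i])
            gts.append(float(targets[i].sum()))
            preds.append(pred.count)
        batch_eval = EvaluationBatch(tuple(gts), tuple(preds))
        m, r = mce(batch_eval), rmse(batch_eval)
        history.val_mce.append(m)
        history.val_rmse.append(r)
        if m < best_mce:
            best_mce = m
            best_state = model.state_dict()
            history.best_epoch = len(history.val_mce) - 1

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def _batch_step(model, images, targets, batch) -> float:
    """Forward/backward over one mini-batch; returns the mean loss.

    Same-shaped images are stacked into one tensor; mixed sizes fall back
    to per-image passes with gradient averaging.
    """
    shapes = {images[i].shape for i in batch}
    if len(shapes) == 1:
        x = Tensor(np.stack([images[i] for i in batch])[:, None])
        t = np.stack([targets[i] for i in batch])[:, None]
        loss = sse_loss(model.forward_tensor(x), t)
        loss.backward()
        return float(loss.data)
    total = 0.0
    scale = 1.0 / len(batch)
    for i in batch:
        x = Tensor(images[i][None, None])
        loss = sse_loss(model.forward_tensor(x), targets[i][None, None])
        loss.backward(np.asarray(scale, dtype=np.float32))
        total += float(loss.data)
    return total * scale
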