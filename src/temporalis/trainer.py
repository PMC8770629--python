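"""Training protocol: Adam, mini-batch 2, learning-rate grid search on
validation loss, early stopping with patience, best-epoch checkpointing.

"Improvement" means a strict decrease of the mean validation loss below the
best seen so far (no minimum delta); training stops once the validation
loss has failed to improve for ``patience`` consecutive epochs, and the
returned model carries the parameters of the *best* epoch, not the last.
Validation uses the same loss function as training, evaluated in inference
mode (dropout off, batch-norm running statistics).  No data augmentation
is applied; the loader is an extension point for it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .imaging_io import BinaryMask, Slice2D
from .losses import DEFAULT_LOSS_CONFIG, LossConfig, get_loss
from .unet import ModelHandle

DEFAULT_LR_CANDIDATES = (0.0001, 0.0005, 0.00075, 0.001, 0.01)


@dataclass(frozen=True)
class TrainConfig:
    loss_name: str = "dice"
    learning_rate: float = 1e-3
    lr_candidates: tuple[float, ...] = DEFAULT_LR_CANDIDATES
    batch_size: int = 2
    max_epochs: int = 50
    patience: int = 3
    seed: int = 0
    loss_config: LossConfig = DEFAULT_LOSS_CONFIG

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not self.lr_candidates:
            raise ValueError("lr_candidates must be non-empty")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    history: list[dict]  # per-epoch {"epoch", "train_loss", "val_loss"}
    best_epoch: int  # 1-based
    best_val_loss: float
    stopped_early: bool
    model: ModelHandle


class EarlyStopping:
    """Stateful early-stopping rule; epochs are 1-based.

    ``update(val_loss)`` returns True when training should stop, i.e. when
    the loss has not strictly improved for ``patience`` consecutive epochs.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


Pair = tuple[Slice2D, BinaryMask]


def _to_batch(pairs: list[Pair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.pixels for p, _ in pairs])[:, None].astype(np.float32)
    g = np.stack([m.labels for _, m in pairs])[:, None].astype(np.float32)
    return x, g


def _check_sets(model: ModelHandle, *sets: list[Pair]) -> None:
    size = model.config.input_size_px
    for s in sets:
        if not s:
            raise ValueError("training and validation sets must be non-empty")
        for sl, m in s:
            if sl.shape != (size, size) or m.shape != (size, size):
                raise ValueError(
                    f"sample shape {sl.shape} does not match model input {size}×{size}"
                )


def validation_loss(model: ModelHandle, val_set: list[Pair], cfg: TrainConfig) -> float:
    """Mean per-image loss over the validation set, in inference mode."""
    loss_fn = get_loss(cfg.loss_name)
    total = 0.0
    for sl, m in val_set:
        p = model.net.forward(sl.pixels[None, None].astype(np.float32), training=False)
        loss, _ = loss_fn(p[0, 0].astype(np.float64), m.labels.astype(np.float64),
                          cfg.loss_config, need_grad=False)
        total += loss
    return total / len(val_set)


def train(
    model: ModelHandle,
    train_set: list[Pair],
    val_set: list[Pair],
    cfg: TrainConfig,
) -> TrainResult:
    """Run the full training loop and return the best-epoch model.

    Mini-batches are reshuffled every epoch with a seeded generator, so two
    runs with the same seed and data produce identical histories.
    """
    _check_sets(model, train_set, val_set)
    loss_fn = get_loss(cfg.loss_name)
    optim = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    stopper = EarlyStopping(cfg.patience)

    history: list[dict] = []
    best_weights = model.net.get_weights()
    stopped_early = False
    n = len(train_set)
    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            x, g = _to_batch(batch)
            p = model.net.forward(x, training=True)
            batch_loss = 0.0
            gp = np.zeros_like(p)
            for b in range(len(batch)):
                loss_b, grad_b = loss_fn(
                    p[b, 0].astype(np.float64), g[b, 0].astype(np.float64), cfg.loss_config
                )
                batch_loss += loss_b
                gp[b, 0] = grad_b / len(batch)
            batch_loss /= len(batch)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite {cfg.loss_name} loss at epoch {epoch}, batch {n_batches + 1}"
                )
            optim.zero_grad()
            model.net.backward(gp)
            optim.step()
            epoch_loss += batch_loss
            n_batches += 1

        val = validation_loss(model, val_set, cfg)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_loss": val}
        )
        stop = stopper.update(val)
        if stopper.best_epoch == epoch:
            best_weights = model.net.get_weights()
        if stop:
            stopped_early = True
            break

    model.net.set_weights(best_weights)
    model.provenance = {
        "epochs_trained": len(history),
        "best_epoch": stopper.best_epoch,
        "best_val_loss": float(stopper.best),
        "loss": cfg.loss_name,
        "learning_rate": cfg.learning_rate,
    }
    return TrainResult(
        history=history,
        best_epoch=stopper.best_epoch,
        best_val_loss=float(stopper.best),
        stopped_early=stopped_early,
        model=model,
    )


def lr_search(
    model_factory,
    train_set: list[Pair],
    val_set: list[Pair],
    cfg: TrainConfig,
    train_fn=train,
) -> tuple[float, dict[float, TrainResult]]:
    """Grid search over ``cfg.lr_candidates``; one fresh seeded model each.

    Returns the learning rate whose best validation loss is minimal, ties
    broken toward the smaller rate.  ``train_fn`` is injectable for tests.
    """
    if not cfg.lr_candidates:
        raise ValueError("no learning-rate candidates")
    results: dict[float, TrainResult] = {}
    for lr in cfg.lr_candidates:
        model = model_factory()
        results[lr] = train_fn(model, train_set, val_set, replace(cfg, learning_rate=lr))
    best_lr = min(results, key=lambda lr: (results[lr].best_val_loss, lr))
    return best_lr, results


def write_history_csv(path, result: TrainResult) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "val_loss"])
        for row in result.history:
            w.writerow([row["epoch"], f"{row['train_loss']:.6f}", f"{row['val_loss']:.6f}"])
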