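"""Training protocol: splits, Adam/MSE fitting with early stopping, inference.

Two evaluation regimes are supported:

* calibration-based — each subject contributes 70% / 10% / 20% of its own
  windows to train / validation / test. Because neighbouring windows overlap
  almost entirely, the default split is chronologically contiguous within a
  subject (limits train/test leakage); ``TrainConfig.split_mode = "random"``
  gives the literal random split instead.
* calibration-free (LOSO) — every window of one held-out subject forms the
  test set; the remaining subjects are split 87.5% / 12.5% train / validation.

Optimization: Adam, learning rate 1e-3 with inverse-time decay 1e-4 per
update, MSE loss over the (SBP, DBP) pair, batch size 512, at most 50 epochs
with early stopping (patience 10 on validation MSE, best weights restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BPModel
from .nn import Adam, Tensor
from .preprocess import WindowedDataset

__all__ = ["TrainConfig", "TrainHistory", "EarlyStopping",
           "split_dataset", "fit", "predict", "mse_loss"]


@dataclass
class TrainConfig:
    train_frac: float = 0.70
    val_frac: float = 0.10
    test_frac: float = 0.20
    lr: float = 1e-3
    lr_decay: float = 1e-4
    max_epochs: int = 50
    early_stop_patience: int = 10
    batch_size: int = 512
    split_mode: str = "chronological"  # or "random"
    normalize_targets: bool = True
    seed: int = 0

    def validate(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.split_mode not in ("chronological", "random"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0    # 1-based
    stopped_epoch: int = 0

    def validate(self) -> None:
        assert self.best_epoch <= self.stopped_epoch


class EarlyStopping:
    """Stop after `patience` consecutive epochs without val-loss improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's loss; returns True if it set a new best."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.epochs_since_best = 0
            return True
        self.epochs_since_best += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.epochs_since_best >= self.patience


def _chrono_order(ds: WindowedDataset, idx: np.ndarray) -> np.ndarray:
    return idx[np.argsort(ds.t_end[idx], kind="stable")]


def _split_indices(n: int, fracs: tuple[float, ...]) -> list[np.ndarray]:
    cuts = np.cumsum([int(round(f * n)) for f in fracs[:-1]])
    return np.split(np.arange(n), cuts)


def split_dataset(ds: WindowedDataset, cfg: TrainConfig,
                  mode: str = "calibration", holdout_subject: str | None = None
                  ) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Partition a dataset into (train, val, test) per the chosen regime."""
    cfg.validate()
    if len(ds) == 0:
        raise ValueError("empty dataset")
    subjects = np.unique(ds.subject_id)
    rng = np.random.default_rng(cfg.seed)

    def per_subject(sub_idx: np.ndarray, fracs: tuple[float, ...]
                    ) -> list[np.ndarray]:
        if cfg.split_mode == "random":
            order = rng.permutation(sub_idx)
        else:
            order = _chrono_order(ds, sub_idx)
        return [order[part] for part in _split_indices(len(order), fracs)]

    if mode == "calibration":
        parts: list[list[np.ndarray]] = [[], [], []]
        for s in subjects:
            sub_idx = np.flatnonzero(ds.subject_id == s)
            for bucket, chunk in zip(parts, per_subject(
                    sub_idx, (cfg.train_frac, cfg.val_frac, cfg.test_frac))):
                bucket.append(chunk)
        tr, va, te = (np.concatenate(p) for p in parts)
    elif mode == "loso":
        if holdout_subject is None or holdout_subject not in subjects:
            raise ValueError(
                f"holdout_subject {holdout_subject!r} not in dataset "
                f"(subjects: {list(subjects)})")
        te = np.flatnonzero(ds.subject_id == holdout_subject)
        val_share = cfg.val_frac / (cfg.train_frac + cfg.val_frac)
        parts = [[], []]
        for s in subjects:
            if s == holdout_subject:
                continue
            sub_idx = np.flatnonzero(ds.subject_id == s)
            for bucket, chunk in zip(parts, per_subject(
                    sub_idx, (1.0 - val_share, val_share))):
                bucket.append(chunk)
        tr, va = (np.concatenate(p) for p in parts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if min(len(tr), len(va), len(te)) == 0:
        raise ValueError("dataset too small for a non-empty split")
    return ds.subset(tr), ds.subset(va), ds.subset(te)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2).mean()


def _eval_mse(model: BPModel, ds: WindowedDataset, batch_size: int) -> float:
    sbp, dbp, _ = predict(model, ds, batch_size=batch_size)
    err = np.column_stack([sbp - ds.y_sbp, dbp - ds.y_dbp])
    return float(np.mean(err**2))


def fit(model: BPModel, train: WindowedDataset, val: WindowedDataset,
        cfg: TrainConfig, val_loss_fn=None, verbose: bool = False
        ) -> tuple[BPModel, TrainHistory]:
    """Train with Adam + MSE and early stopping; restores best-val weights.

    `val_loss_fn(model, val) -> float` may be injected (e.g. for testing the
    stopping rule); it defaults to the validation MSE.
    """
    cfg.validate()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val splits must be non-empty")
    if val_loss_fn is None:
        val_loss_fn = lambda m, v: _eval_mse(m, v, cfg.batch_size)  # noqa: E731
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, decay=cfg.lr_decay)
    stopper = EarlyStopping(cfg.early_stop_patience)
    history = TrainHistory()
    y = np.column_stack([train.y_sbp, train.y_dbp])
    if cfg.normalize_targets:
        # optimize in standardized target units; model.predict de-normalizes
        model.target_mean = y.mean(axis=0)
        model.target_scale = np.maximum(y.std(axis=0), 1e-12)
    y_opt = (y - model.target_mean) / model.target_scale
    best_state = model.state_dict()

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(train))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = order[i:i + cfg.batch_size]
            pred, _ = model.forward(train.X[batch])
            loss = mse_loss(pred, y_opt[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        vloss = float(val_loss_fn(model, val))
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(vloss)
        if stopper.update(vloss, epoch):
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:3d}  train {history.train_loss[-1]:.4f}  "
                  f"val {vloss:.4f}")
        if stopper.should_stop:
            break
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = epoch
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict(model: BPModel, ds: WindowedDataset, batch_size: int = 512
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (sbp_hat, dbp_hat, attention), order-aligned with `ds`."""
    return model.predict(ds.X, batch_size=batch_size)
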