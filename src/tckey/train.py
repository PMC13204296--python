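"""Training and inference loop: minibatch cross-entropy with Adam, gradient
clipping, plateau learning-rate scheduling, and best-epoch model selection."""
from __future__ import annotations

import copy
import json
import random
from dataclasses import asdict, dataclass, field

import numpy as np

from .model import KeystrokeNet
from .nn import Adam, ReduceLROnPlateau, Tensor, clip_grad_norm, cross_entropy, global_grad_norm
from .signal_data import LabeledWindowSet

__all__ = [
    "TrainConfig",
    "History",
    "set_global_seed",
    "clip_gradients",
    "fit",
    "predict_with_confidence",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    lr: float = 1e-4
    epochs: int = 100
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    clip_max_norm: float = 1.0
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    seed: int = 42

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.clip_max_norm <= 0:
            raise ValueError("clip_max_norm must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "TrainConfig":
        d = json.loads(text)
        d["betas"] = tuple(d.get("betas", (0.9, 0.999)))
        return TrainConfig(**d)


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)  # post-clip, max per epoch
    best_epoch: int = -1

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i + 1,
                "train_loss": self.train_loss[i],
                "train_acc": self.train_acc[i],
                "val_loss": self.val_loss[i],
                "val_acc": self.val_acc[i],
                "lr": self.lr[i],
            }
            for i in range(len(self.train_loss))
        ]


def set_global_seed(seed: int) -> None:
    """Seed every random stream the pipeline touches."""
    random.seed(seed)
    np.random.seed(seed)


def clip_gradients(model_or_params, max_norm: float = 1.0) -> float:
    """Clip the global L2 gradient norm to ``max_norm``; returns the pre-clip
    norm.  Accepts a module or a parameter list."""
    params = model_or_params.parameters() if hasattr(model_or_params, "parameters") else list(model_or_params)
    return clip_grad_norm(params, max_norm)


def _evaluate_loss_acc(model: KeystrokeNet, X: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    was_training = model.training
    model.eval()
    total_loss, correct = 0.0, 0
    for start in range(0, len(X), batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        logits = model(Tensor(xb))
        total_loss += cross_entropy(logits, yb).item() * len(xb)
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    model.train(was_training)
    n = max(len(X), 1)
    return total_loss / n, correct / n


def fit(
    model: KeystrokeNet,
    train_set: LabeledWindowSet,
    val_set: LabeledWindowSet,
    cfg: TrainConfig = TrainConfig(),
    verbose: bool = False,
    _assert_clipped: bool = False,
) -> tuple[KeystrokeNet, History]:
    """Train for ``cfg.epochs`` epochs and return the weights of the epoch
    with the highest validation accuracy together with the metric trace."""
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if cfg.batch_size > len(train_set):
        raise ValueError("batch_size exceeds training set size")

    rng = np.random.default_rng(cfg.seed)
    model.reseed(cfg.seed)
    model.train()
    optimizer = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas, eps=cfg.eps)
    scheduler = ReduceLROnPlateau(optimizer, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience)
    history = History()
    best_acc, best_state = -1.0, None

    Xtr, ytr = train_set.data, train_set.labels
    Xva, yva = val_set.data, val_set.labels

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss, correct, max_postclip = 0.0, 0, 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            model.zero_grad()
            loss.backward()
            clip_gradients(model, cfg.clip_max_norm)
            post = global_grad_norm(model.parameters())
            max_postclip = max(max_postclip, post)
            if _assert_clipped:
                assert post <= cfg.clip_max_norm * (1 + 1e-9), "clipping contract violated"
            optimizer.step()
            epoch_loss += loss.item() * len(xb)
            correct += int((logits.data.argmax(axis=1) == yb).sum())

        tr_loss = epoch_loss / len(Xtr)
        tr_acc = correct / len(Xtr)
        va_loss, va_acc = (
            _evaluate_loss_acc(model, Xva, yva, cfg.batch_size) if len(Xva) else (float("nan"), float("nan"))
        )
        history.train_loss.append(tr_loss)
        history.train_acc.append(tr_acc)
        history.val_loss.append(va_loss)
        history.val_acc.append(va_acc)
        history.lr.append(optimizer.lr)
        history.grad_norms.append(max_postclip)
        if len(Xva) and va_acc > best_acc:
            best_acc = va_acc
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
        if len(Xva):
            scheduler.step(va_loss)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  train_loss {tr_loss:.4f}  train_acc {tr_acc:.4f}"
                f"  val_loss {va_loss:.4f}  val_acc {va_acc:.4f}  lr {optimizer.lr:.2e}"
            )

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict_with_confidence(
    model: KeystrokeNet, ws: LabeledWindowSet, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per window: (argmax class, max softmax probability, full probability
    row).  Dropout is disabled; repeated calls are identical."""
    if ws.n_channels != model.cfg.input_channels or ws.window_len != model.cfg.window_len:
        raise ValueError(
            f"window shape ({ws.n_channels}, {ws.window_len}) does not match model "
            f"input ({model.cfg.input_channels}, {model.cfg.window_len})"
        )
    proba = model.predict_proba(ws.data, batch_size=batch_size)
    pred = proba.argmax(axis=1)
    conf = proba.max(axis=1)
    return pred, conf, proba
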