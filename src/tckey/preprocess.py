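"""Segmentation, filtering, augmentation, normalization, and splitting."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal_data import LabeledWindowSet, Recording

__all__ = [
    "AugmentationConfig",
    "SplitIndices",
    "SegmentationResult",
    "segment_recording",
    "bandpass_filter",
    "augment_window_set",
    "normalize_windows",
    "stratified_split",
]

#: std floor below which a channel is treated as constant and left at zero
NORM_EPS = 1e-8


@dataclass(frozen=True)
class AugmentationConfig:
    """Settings for window augmentation.

    ``factor`` counts total copies per original, originals included: factor 3
    keeps the original and adds two synthetic copies.  Each synthetic copy is
    the band-passed original plus zero-mean Gaussian noise (sigma 0.01) with
    ``dropout_channels`` channels zeroed to mimic transient electrode loss.
    """

    factor: int = 3
    noise_sigma: float = 0.01
    band: tuple[float, float] = (50.0, 450.0)
    filter_order: int = 4
    dropout_channels: int = 1
    dropout_scope: str = "all-channels"  # or "per-arm-group"
    apply_to_original: bool = False
    seed: int = 42

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")
        if self.dropout_channels < 0:
            raise ValueError("dropout_channels must be >= 0")
        if self.dropout_scope not in ("all-channels", "per-arm-group"):
            raise ValueError(f"unknown dropout_scope {self.dropout_scope!r}")


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "train", np.asarray(self.train, dtype=np.int64))
        object.__setattr__(self, "val", np.asarray(self.val, dtype=np.int64))
        if np.intersect1d(self.train, self.val).size:
            raise ValueError("train and val indices overlap")


@dataclass(frozen=True)
class SegmentationResult:
    windows: LabeledWindowSet
    n_dropped: int
    dropped_onsets: tuple[int, ...] = field(default_factory=tuple)


def segment_recording(rec: Recording, window_s: float = 0.2) -> SegmentationResult:
    """Cut one half-open window [onset, onset + T) per keypress event.

    T = round(window_s * fs).  Events whose window would overrun the end of
    the recording are dropped and reported in the result.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    T = int(round(window_s * rec.fs))
    kept, labels, dropped = [], [], []
    for ev in rec.events:
        if ev.onset + T <= rec.n_samples:
            kept.append(rec.signal[:, ev.onset : ev.onset + T])
            labels.append(ev.label)
        else:
            dropped.append(ev.onset)
    data = np.stack(kept) if kept else np.zeros((0, rec.n_channels, T))
    ws = LabeledWindowSet(
        data=data,
        labels=np.asarray(labels, dtype=np.int64),
        subject_ids=np.array([rec.subject_id] * len(kept), dtype=str),
        session_ids=np.array([rec.session_id] * len(kept), dtype=str),
        fs=rec.fs,
        window_s=window_s,
    )
    return SegmentationResult(windows=ws, n_dropped=len(dropped), dropped_onsets=tuple(dropped))


def _bandpass_sos(band: tuple[float, float], order: int, fs: float):
    low, high = band
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _filter_tensor(data: np.ndarray, band, order, fs) -> np.ndarray:
    sos = _bandpass_sos(band, order, fs)
    return sosfiltfilt(sos, data, axis=-1)


def bandpass_filter(ws: LabeledWindowSet, band: tuple[float, float] = (50.0, 450.0), order: int = 4) -> LabeledWindowSet:
    """Zero-phase (forward-backward) Butterworth band-pass per channel."""
    out = _filter_tensor(ws.data, band, order, ws.fs)
    return LabeledWindowSet(
        data=out,
        labels=ws.labels,
        subject_ids=ws.subject_ids,
        session_ids=ws.session_ids,
        fs=ws.fs,
        window_s=ws.window_s,
        n_classes=ws.n_classes,
    )


def _dropout_mask(rng: np.random.Generator, n_channels: int, cfg: AugmentationConfig) -> np.ndarray:
    """Boolean mask of channels to zero for one sample."""
    mask = np.zeros(n_channels, dtype=bool)
    if cfg.dropout_channels == 0:
        return mask
    if cfg.dropout_scope == "per-arm-group":
        # one channel from each consecutive 8-channel electrode group
        for start in range(0, n_channels, 8):
            group = np.arange(start, min(start + 8, n_channels))
            picks = rng.choice(group, size=min(cfg.dropout_channels, len(group)), replace=False)
            mask[picks] = True
    else:
        picks = rng.choice(n_channels, size=cfg.dropout_channels, replace=False)
        mask[picks] = True
    return mask


def augment_window_set(ws: LabeledWindowSet, cfg: AugmentationConfig = AugmentationConfig()) -> LabeledWindowSet:
    """Expand the set by ``cfg.factor``: originals retained verbatim (unless
    ``apply_to_original``) plus factor-1 synthetic copies per original.

    Synthetic copy = band-pass(original) + N(0, sigma) with exactly
    ``dropout_channels`` channels zeroed.  Bit-identical under a fixed seed.
    """
    if cfg.dropout_channels > ws.n_channels:
        raise ValueError(
            f"dropout_channels={cfg.dropout_channels} exceeds channel count {ws.n_channels}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = len(ws)
    filtered = _filter_tensor(ws.data, cfg.band, cfg.filter_order, ws.fs) if n else ws.data

    chunks, labels, subjects, sessions = [], [], [], []
    for i in range(n):
        if cfg.apply_to_original:
            base = filtered[i] + rng.normal(0.0, cfg.noise_sigma, size=filtered[i].shape)
            base[_dropout_mask(rng, ws.n_channels, cfg)] = 0.0
            chunks.append(base)
        else:
            chunks.append(ws.data[i].copy())
        for _ in range(cfg.factor - 1):
            copy = filtered[i] + rng.normal(0.0, cfg.noise_sigma, size=filtered[i].shape)
            copy[_dropout_mask(rng, ws.n_channels, cfg)] = 0.0
            chunks.append(copy)
        labels.extend([ws.labels[i]] * cfg.factor)
        subjects.extend([ws.subject_ids[i]] * cfg.factor)
        sessions.extend([ws.session_ids[i]] * cfg.factor)

    data = np.stack(chunks) if chunks else np.zeros((0, ws.n_channels, ws.window_len))
    return LabeledWindowSet(
        data=data,
        labels=np.asarray(labels, dtype=np.int64),
        subject_ids=np.array(subjects, dtype=str) if subjects else ws.subject_ids,
        session_ids=np.array(sessions, dtype=str) if sessions else ws.session_ids,
        fs=ws.fs,
        window_s=ws.window_s,
        n_classes=ws.n_classes,
    )


def normalize_windows(ws: LabeledWindowSet) -> LabeledWindowSet:
    """Per-window, per-channel z-scoring; constant channels (e.g. dropped to
    zero) are left at zero instead of producing NaNs."""
    mu = ws.data.mean(axis=-1, keepdims=True)
    sd = ws.data.std(axis=-1, keepdims=True)
    constant = sd < NORM_EPS
    out = np.where(constant, 0.0, (ws.data - mu) / np.where(constant, 1.0, sd))
    return LabeledWindowSet(
        data=out,
        labels=ws.labels,
        subject_ids=ws.subject_ids,
        session_ids=ws.session_ids,
        fs=ws.fs,
        window_s=ws.window_s,
        n_classes=ws.n_classes,
    )


def stratified_split(ws: LabeledWindowSet, train_frac: float = 0.8, seed: int = 42) -> SplitIndices:
    """Per-class partition into train/validation at ``train_frac``.

    Deterministic under ``seed``; each class contributes
    round(train_frac * n_class) windows to train, so the stratification
    error is at most one window per class.
    """
    if not 0 < train_frac <= 1.0:
        raise ValueError("train_frac must be in (0, 1]")
    if train_frac == 1.0:
        warnings.warn("train_frac=1.0 leaves the validation set empty", stacklevel=2)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for c in np.unique(ws.labels):
        idx = np.where(ws.labels == c)[0]
        if len(idx) < 2 and train_frac < 1.0:
            raise ValueError(f"class {int(c)} has only {len(idx)} window(s); cannot stratify")
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) if train_frac == 1.0 else len(idx) - 1)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return SplitIndices(train=np.sort(train_idx), val=np.sort(val_idx))


def session_split(ws: LabeledWindowSet, val_sessions: list[str]) -> SplitIndices:
    """Alternative split: validation drawn from held-out session blocks."""
    val_mask = np.isin(ws.session_ids, np.asarray(val_sessions, dtype=str))
    return SplitIndices(train=np.where(~val_mask)[0], val=np.where(val_mask)[0])
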