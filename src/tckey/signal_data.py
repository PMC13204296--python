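"""Core data model: recordings, keypress events, labeled window sets, and
lossless container I/O (NPZ or HDF5, chosen by file extension, with a JSON
manifest sidecar)."""
from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_ALPHABET: tuple[str, ...] = tuple(string.ascii_uppercase)

_STORE_KEYS = ("data", "labels", "subject_ids", "session_ids", "fs", "window_s")


class SchemaError(ValueError):
    """Raised when a window-store file violates the container schema."""


@dataclass(frozen=True)
class KeypressEvent:
    """A labeled keypress onset within a recording."""

    onset: int
    label: int  # index into the alphabet

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if not 0 <= self.label < len(DEFAULT_ALPHABET):
            raise ValueError(f"label {self.label} outside the 26-symbol alphabet")

    @property
    def char(self) -> str:
        return DEFAULT_ALPHABET[self.label]


@dataclass
class Recording:
    """One subject/session of raw multichannel signal plus its event log."""

    signal: np.ndarray  # (channels, samples)
    fs: float
    subject_id: str
    session_id: str
    events: list[KeypressEvent] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        n = self.signal.shape[1]
        for ev in self.events:
            if not 0 <= ev.onset < n:
                raise ValueError(f"event onset {ev.onset} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class LabeledWindowSet:
    """The unit exchanged by every pipeline stage: an (n, C, T) tensor of
    signal windows with per-window labels and provenance tokens."""

    data: np.ndarray  # (n, C, T)
    labels: np.ndarray  # (n,) int
    subject_ids: np.ndarray  # (n,) str
    session_ids: np.ndarray  # (n,) str
    fs: float
    window_s: float
    n_classes: int = len(DEFAULT_ALPHABET)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        self.session_ids = np.asarray(self.session_ids, dtype=str)
        if self.data.ndim != 3:
            raise ValueError("data must be an (n, C, T) tensor")
        violations = validate_window_set(self)
        if violations:
            raise ValueError("invalid window set: " + "; ".join(violations))

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def window_len(self) -> int:
        return self.data.shape[2]

    def select(self, idx) -> "LabeledWindowSet":
        idx = np.asarray(idx)
        return LabeledWindowSet(
            data=self.data[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            session_ids=self.session_ids[idx],
            fs=self.fs,
            window_s=self.window_s,
            n_classes=self.n_classes,
        )


def validate_window_set(ws) -> list[str]:
    """Report every invariant violation; an empty list means the set is valid.

    Operates on attribute access only so that deliberately broken objects
    (wrong lengths, NaNs, out-of-range labels) can be inspected without
    tripping constructor checks.
    """
    violations: list[str] = []
    data = np.asarray(ws.data)
    labels = np.asarray(ws.labels)
    n = data.shape[0] if data.ndim == 3 else -1
    if data.ndim != 3:
        violations.append(f"data: expected 3 dims, got {data.ndim}")
        return violations
    if len(labels) != n:
        violations.append(f"labels: length {len(labels)} != n windows {n}")
    if len(np.asarray(ws.subject_ids)) != n:
        violations.append(f"subject_ids: length {len(np.asarray(ws.subject_ids))} != n windows {n}")
    if len(np.asarray(ws.session_ids)) != n:
        violations.append(f"session_ids: length {len(np.asarray(ws.session_ids))} != n windows {n}")
    if ws.fs <= 0:
        violations.append(f"fs: must be positive, got {ws.fs}")
    expected_t = int(round(ws.window_s * ws.fs))
    if n > 0 and data.shape[2] != expected_t:
        violations.append(
            f"data: T={data.shape[2]} != round(window_s * fs)={expected_t}"
        )
    bad = np.where(~np.isfinite(data).all(axis=(1, 2)))[0]
    for i in bad:
        violations.append(f"data: non-finite values in window {int(i)}")
    n_classes = getattr(ws, "n_classes", len(DEFAULT_ALPHABET))
    for i in np.where((labels < 0) | (labels >= n_classes))[0]:
        violations.append(f"labels: label {int(labels[i])} at window {int(i)} outside [0, {n_classes})")
    return violations


def empty_window_set(n_channels: int, fs: float, window_s: float, n_classes: int = 26) -> LabeledWindowSet:
    t = int(round(window_s * fs))
    return LabeledWindowSet(
        data=np.zeros((0, n_channels, t)),
        labels=np.zeros(0, dtype=np.int64),
        subject_ids=np.zeros(0, dtype=str),
        session_ids=np.zeros(0, dtype=str),
        fs=fs,
        window_s=window_s,
        n_classes=n_classes,
    )


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


def save_window_store(ws: LabeledWindowSet, path) -> None:
    """Write a window set to ``path`` (.npz, .h5, or .hdf5) losslessly."""
    violations = validate_window_set(ws)
    if violations:
        raise ValueError("refusing to save invalid window set: " + "; ".join(violations))
    path = Path(path)
    arrays = {
        "data": ws.data,
        "labels": ws.labels,
        "subject_ids": ws.subject_ids.astype("U"),
        "session_ids": ws.session_ids.astype("U"),
        "fs": np.asarray(ws.fs, dtype=np.float64),
        "window_s": np.asarray(ws.window_s, dtype=np.float64),
        "n_classes": np.asarray(ws.n_classes, dtype=np.int64),
    }
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            for key, arr in arrays.items():
                if arr.dtype.kind == "U":
                    f.create_dataset(key, data=arr.astype(object), dtype=h5py.string_dtype())
                else:
                    f.create_dataset(key, data=arr)
    else:
        with open(path, "wb") as f:
            np.savez(f, **arrays)
    manifest = {
        "format": "h5" if path.suffix in (".h5", ".hdf5") else "npz",
        "n_windows": len(ws),
        "n_channels": ws.n_channels,
        "window_len": ws.window_len,
        "fs": ws.fs,
        "window_s": ws.window_s,
        "n_classes": ws.n_classes,
        "alphabet": list(DEFAULT_ALPHABET)[: ws.n_classes],
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=2))


def load_window_store(path) -> LabeledWindowSet:
    """Read a window store written by :func:`save_window_store`.

    Re-checks all invariants; schema problems raise :class:`SchemaError`
    naming the offending field rather than returning silent garbage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: dict[str, np.ndarray] = {}
    try:
        if path.suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(path, "r") as f:
                for key in f.keys():
                    arr = f[key][()]
                    raw[key] = arr
        else:
            with np.load(path, allow_pickle=False) as npz:
                for key in npz.files:
                    raw[key] = npz[key]
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot parse window store {path}: {exc}") from exc
    missing = [k for k in _STORE_KEYS if k not in raw]
    if missing:
        raise SchemaError(f"window store missing keys: {missing}")

    def _decode(arr):
        arr = np.asarray(arr)
        if arr.dtype.kind in ("O", "S"):
            return np.asarray([x.decode() if isinstance(x, bytes) else str(x) for x in arr], dtype=str)
        return arr.astype(str)

    try:
        ws = LabeledWindowSet(
            data=raw["data"],
            labels=raw["labels"],
            subject_ids=_decode(raw["subject_ids"]),
            session_ids=_decode(raw["session_ids"]),
            fs=float(raw["fs"]),
            window_s=float(raw["window_s"]),
            n_classes=int(raw.get("n_classes", len(DEFAULT_ALPHABET))),
        )
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc
    return ws
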