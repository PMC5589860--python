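"""Shared data containers for epoched EEG, ERPs, montages and source geometry.

Arrays are plain numpy; metadata travels in dataclass fields.  Voltage data
are in microvolts throughout.  Epoch/ERP time axes follow a half-open
``[t0, t1)`` convention: the first sample sits exactly at ``window_ms[0]``
and the sample count is ``floor((t1 - t0) * fs / 1000)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "n_window_samples",
    "window_times",
    "EpochSet",
    "Erp",
    "Montage",
]


def n_window_samples(window_ms: tuple[float, float], fs: float) -> int:
    """Sample count of a half-open window ``[t0, t1)`` at rate ``fs``."""
    t0, t1 = window_ms
    if not t1 > t0:
        raise ValueError(f"empty window {window_ms}")
    return int(np.floor((t1 - t0) * fs / 1000.0))


def window_times(window_ms: tuple[float, float], fs: float) -> np.ndarray:
    """Nominal sample times (ms); first sample at exactly ``window_ms[0]``."""
    n = n_window_samples(window_ms, fs)
    return window_ms[0] + np.arange(n) * (1000.0 / fs)


@dataclass
class EpochSet:
    """Epoched multichannel data, ``data`` shaped (channels, samples, epochs).

    ``blocks`` carries the task block of every epoch (used by trial-count
    matching); ``labels`` an optional per-epoch outcome/condition tag.
    """

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    blocks: np.ndarray | None = None
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be (channels, samples, epochs)")
        expected = n_window_samples(self.window_ms, self.fs)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"sample count {self.data.shape[1]} inconsistent with window "
                f"{self.window_ms} at fs={self.fs} (expected {expected})"
            )
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks)
            if self.blocks.shape[0] != self.n_epochs:
                raise ValueError("blocks length must match epoch count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_epochs:
                raise ValueError("labels length must match epoch count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return window_times(self.window_ms, self.fs)

    def select(self, idx: np.ndarray) -> "EpochSet":
        """Subset of epochs, preserving order of ``idx``."""
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[:, :, idx],
            blocks=None if self.blocks is None else self.blocks[idx],
            labels=None if self.labels is None else self.labels[idx],
            meta=dict(self.meta),
        )

    def save(self, path: str | Path) -> None:
        import h5py

        def _writable(x: np.ndarray) -> np.ndarray:
            return x if x.dtype.kind in "iuf" else np.asarray(x, dtype="S")

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            if self.blocks is not None:
                f.create_dataset("blocks", data=_writable(self.blocks))
            if self.labels is not None:
                f.create_dataset("labels", data=_writable(self.labels))
            f.attrs["fs"] = self.fs
            f.attrs["window_ms"] = list(self.window_ms)
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        import h5py

        def _readable(ds) -> np.ndarray:
            arr = ds[()]
            return arr.astype(str) if arr.dtype.kind == "S" else arr

        with h5py.File(path, "r") as f:
            blocks = _readable(f["blocks"]) if "blocks" in f else None
            labels = _readable(f["labels"]) if "labels" in f else None
            return cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                window_ms=tuple(f.attrs["window_ms"]),
                blocks=blocks,
                labels=labels,
                meta=json.loads(f.attrs["meta"]),
            )


@dataclass
class Erp:
    """Trial-averaged evoked response, ``data`` shaped (channels, samples)."""

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    n_epochs: int
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Erp.data must be (channels, samples)")
        expected = n_window_samples(self.window_ms, self.fs)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"sample count {self.data.shape[1]} inconsistent with window "
                f"{self.window_ms} at fs={self.fs} (expected {expected})"
            )
        if self.n_epochs < 1:
            raise ValueError("Erp requires n_epochs >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return window_times(self.window_ms, self.fs)


@dataclass
class Montage:
    """Electrode labels with 3-D head-centered positions (mm)."""

    labels: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    def save_sfp(self, path: str | Path) -> None:
        with open(path, "w") as f:
            for lab, (x, y, z) in zip(self.labels, self.positions):
                f.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")

    @classmethod
    def load_sfp(cls, path: str | Path) -> "Montage":
        labels: list[str] = []
        pos: list[list[float]] = []
        with open(path) as f:
            for line in f:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 4:
                    raise ValueError(f"malformed .sfp line: {line!r}")
                labels.append(parts[0])
                pos.append([float(v) for v in parts[1:]])
        return cls(labels=labels, positions=np.asarray(pos))
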