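"""Core containers shared across the pipeline.

All containers are thin dataclasses around numpy arrays; they carry just
enough metadata (sampling rate, window geometry) for the downstream stages
to be self-describing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RawSignal",
    "MultiChannelSignal",
    "EventTrain",
    "DiffusionTrajectory",
    "EntropyCurve",
    "ScalingEstimate",
    "ScalingTrack",
]


@dataclass
class RawSignal:
    """A uniformly sampled, single-channel continuous signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples,)
        Signal samples in acquisition units.
    fs : float
        Sampling rate in samples per second.
    name : str
        Channel label.
    """

    data: np.ndarray
    fs: float = 1.0
    name: str = "ch1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("RawSignal.data must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.data.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.fs


@dataclass
class MultiChannelSignal:
    """Several channels sampled on a common uniform clock."""

    data: np.ndarray  # (n_samples, n_channels)
    fs: float
    channels: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("MultiChannelSignal.data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel names do not match data columns")
        self.channels = list(self.channels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> RawSignal:
        try:
            j = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return RawSignal(self.data[:, j], fs=self.fs, name=name)

    def __iter__(self):
        for j, name in enumerate(self.channels):
            yield RawSignal(self.data[:, j], fs=self.fs, name=name)


@dataclass
class EventTrain:
    """Ordered, strictly increasing integer sample indices of discrete events."""

    indices: np.ndarray
    length: int
    fs: float = 1.0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("event indices must be strictly increasing")
        if self.indices.size and (self.indices[0] < 0 or self.indices[-1] >= self.length):
            raise ValueError("event indices must lie in [0, length)")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def n_events(self) -> int:
        return self.indices.size

    @property
    def waits(self) -> np.ndarray:
        """Inter-event waiting times in samples."""
        return np.diff(self.indices).astype(float)

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds."""
        return self.indices / self.fs


@dataclass
class DiffusionTrajectory:
    """Cumulative walker position X(t), one value per source sample."""

    samples: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def is_integer_valued(self) -> bool:
        return bool(np.allclose(self.samples, np.round(self.samples)))


@dataclass
class EntropyCurve:
    """Diffusion entropy S(w) on a grid of window sizes.

    ``entropy`` is NaN where fewer than the minimum number of sub-windows
    were available.  Entropies are differential (nats): the histogram
    estimate is corrected by +ln(bin width), so curves computed with
    different bin widths are directly comparable.
    """

    window_sizes: np.ndarray
    entropy: np.ndarray
    n_subwindows: np.ndarray

    def __post_init__(self) -> None:
        self.window_sizes = np.asarray(self.window_sizes, dtype=float)
        self.entropy = np.asarray(self.entropy, dtype=float)
        self.n_subwindows = np.asarray(self.n_subwindows, dtype=np.int64)
        if np.any(np.diff(self.window_sizes) <= 0):
            raise ValueError("window sizes must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.entropy)


@dataclass
class ScalingEstimate:
    """Result of fitting S(w) = const + delta * ln(w)."""

    delta: float
    stderr: float
    fit_range: tuple
    r2: float
    n_points: int
    admissible: bool = True  # False when delta falls outside (0, 1) or slope < 0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            self.admissible = False


@dataclass
class ScalingTrack:
    """Windowed scaling-index series delta(t) for one channel."""

    times: np.ndarray  # window-centre times, seconds
    delta: np.ndarray  # NaN where the window was rejected
    stderr: np.ndarray
    n_events: np.ndarray
    window_len: float = np.nan  # seconds
    step: float = np.nan  # seconds
    name: str = "ch1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        self.n_events = np.asarray(self.n_events, dtype=float)
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.delta)
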