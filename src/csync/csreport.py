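"""Complexity-synchronization report.

Quantifies the covariation of windowed scaling tracks delta(t) across
channels: zero-lag Pearson cross-correlations over pairwise-complete
windows, channel-group averaging (e.g. the 64-channel EEG mean track), and
the per-channel range of variation Delta-delta = max - min, a flexibility
summary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mfscan import align_tracks
from .types import ScalingTrack

__all__ = [
    "SyncReport",
    "average_channels",
    "cross_correlation",
    "delta_range",
    "build_report",
    "permutation_null",
]


def average_channels(
    matrix: np.ndarray, times: np.ndarray, channel_subset: list[int] | None = None
) -> ScalingTrack:
    """Per-time mean of delta over selected channels, ignoring missing values."""
    if channel_subset is not None:
        if len(channel_subset) < 1:
            raise ValueError("need at least one channel to average")
        matrix = matrix[np.asarray(channel_subset, dtype=int)]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(matrix, axis=0)
    count = np.isfinite(matrix).sum(axis=0)
    return ScalingTrack(
        times=times,
        delta=mean,
        stderr=np.full(times.size, np.nan),
        n_events=count.astype(float),
        name="mean",
    )


def _pair_cc(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        raise ValueError("fewer than 3 pairwise-complete windows")
    x, y = a[m], b[m]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a track; cross-correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def cross_correlation(track_a: ScalingTrack | np.ndarray, track_b: ScalingTrack | np.ndarray) -> float:
    """Zero-lag Pearson coefficient on pairwise-complete windows."""
    a = track_a.delta if isinstance(track_a, ScalingTrack) else np.asarray(track_a, dtype=float)
    b = track_b.delta if isinstance(track_b, ScalingTrack) else np.asarray(track_b, dtype=float)
    if a.size != b.size:
        raise ValueError("tracks must share a time grid")
    return _pair_cc(a, b)


def delta_range(track: ScalingTrack | np.ndarray) -> float:
    """Range of variation Delta-delta = max - min over non-missing windows."""
    d = track.delta if isinstance(track, ScalingTrack) else np.asarray(track, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 1:
        raise ValueError("track has no valid windows")
    return float(d.max() - d.min())


@dataclass
class SyncReport:
    """Synchronization summary across channels."""

    channels: list[str]
    times: np.ndarray
    cc_matrix: np.ndarray  # symmetric, unit diagonal, NaN where undefined
    mean_track: ScalingTrack
    delta_ranges: dict[str, float]
    n_windows: int
    cc_min: float  # min off-diagonal CC
    cc_max: float  # max off-diagonal CC
    group_cc: dict[str, dict[str, float]] = field(default_factory=dict)
    # group_cc[g][ch]: CC between the group-g average track and channel ch

    def as_dict(self) -> dict:
        return {
            "channels": self.channels,
            "n_windows": self.n_windows,
            "cc_matrix": self.cc_matrix.tolist(),
            "cc_min": self.cc_min,
            "cc_max": self.cc_max,
            "delta_ranges": self.delta_ranges,
            "mean_track": {
                "times": self.mean_track.times.tolist(),
                "delta": self.mean_track.delta.tolist(),
            },
            "group_cc": self.group_cc,
        }


def build_report(
    tracks: list[ScalingTrack],
    grouping: dict[str, list[str]] | None = None,
) -> SyncReport:
    """Assemble the synchronization report from aligned scaling tracks.

    ``grouping`` maps a group name (e.g. ``"eeg"``) to channel names; the
    mean track is averaged over the first group (or all channels), and for
    every group the CC between its average track and each remaining channel
    is reported alongside the plain channel-pairwise matrix — the two
    conventions for summarizing many-channel synchrony.
    """
    times, mat = align_tracks(tracks)
    names = [tr.name for tr in tracks]
    k = len(tracks)
    cc = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                cc[i, j] = cc[j, i] = _pair_cc(mat[i], mat[j])
            except ValueError:
                cc[i, j] = cc[j, i] = np.nan

    if grouping:
        first = next(iter(grouping))
        subset = [names.index(ch) for ch in grouping[first]]
    else:
        subset = None
    mean_track = average_channels(mat, times, subset)

    group_cc: dict[str, dict[str, float]] = {}
    for g, members in (grouping or {}).items():
        idx = [names.index(ch) for ch in members]
        g_mean = average_channels(mat, times, idx).delta
        group_cc[g] = {}
        for i, ch in enumerate(names):
            if ch in members:
                continue
            try:
                group_cc[g][ch] = _pair_cc(g_mean, mat[i])
            except ValueError:
                group_cc[g][ch] = float("nan")

    off = cc[~np.eye(k, dtype=bool)] if k > 1 else np.array([np.nan])
    off = off[np.isfinite(off)] if np.isfinite(off).any() else np.array([np.nan])
    return SyncReport(
        channels=names,
        times=times,
        cc_matrix=cc,
        mean_track=mean_track,
        delta_ranges={nm: delta_range(mat[i]) for i, nm in enumerate(names)},
        n_windows=int(times.size),
        cc_min=float(np.min(off)),
        cc_max=float(np.max(off)),
        group_cc=group_cc,
    )


def permutation_null(
    track_a: ScalingTrack | np.ndarray,
    track_b: ScalingTrack | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the zero-lag CC (optional check)."""
    a = track_a.delta if isinstance(track_a, ScalingTrack) else np.asarray(track_a, dtype=float)
    b = track_b.delta if isinstance(track_b, ScalingTrack) else np.asarray(track_b, dtype=float)
    obs = _pair_cc(a, b)
    rng = np.random.default_rng(seed)
    m = np.isfinite(a) & np.isfinite(b)
    x, y = a[m], b[m]
    hits = 1
    for _ in range(n_permutations):
        if abs(_pair_cc(x, rng.permutation(y))) >= abs(obs):
            hits += 1
    return hits / (n_permutations + 1)
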