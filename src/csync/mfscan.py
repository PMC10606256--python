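"""Sliding-window MDEA: the time-resolved scaling track delta(t).

The signal is cut into overlapping windows (default one minute, stepped by
20 s); within each window the stripe method extracts events, the jump-ahead
trajectory is built and the diffusion-entropy slope fitted.  The resulting
per-channel series delta(t) is the multifractal-dimension trajectory whose
covariation across channels quantifies complexity synchronization.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dea, striping
from .types import RawSignal, ScalingTrack

__all__ = ["ScanConfig", "scan", "align_tracks"]


@dataclass
class ScanConfig:
    """Windowing and DEA settings for the scan.

    window_len, step : seconds.  min_events : windows with fewer extracted
    events yield a missing value, never a fabricated delta.

    Within each window the entropy is computed on ``n_w`` log-spaced window
    sizes spanning ``e_band`` mean inter-event times of that window's own
    extracted train (capped above at n_events/25 so every fitted size
    retains at least ~25 independent sub-windows), and the slope is fitted
    across the whole grid.  Scaling the grid by the local event rate keeps
    the estimator's response to the waiting-time index monotone as the
    rate drifts.  dea_params are forwarded to
    :func:`csync.dea.entropy_curve` (plus optional ``fit_range``).
    """

    window_len: float = 60.0
    step: float = 20.0
    min_events: int = 30
    e_band: tuple = (10.0, 400.0)
    n_w: int = 20
    dea_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_len <= 0 or self.step <= 0:
            raise ValueError("window_len and step must be positive")
        if self.step > self.window_len:
            raise ValueError("step must not exceed window_len")


def scan(signal: RawSignal, stripe_cfg: striping.StripeConfig, cfg: ScanConfig) -> ScalingTrack:
    """Windowed scaling estimates delta(t) for one channel."""
    n = len(signal)
    win = int(round(cfg.window_len * signal.fs))
    step = int(round(cfg.step * signal.fs))
    if n < win:
        raise ValueError(
            f"signal duration {signal.duration:g}s shorter than window {cfg.window_len:g}s"
        )
    params = dict(cfg.dea_params)
    fit_range = params.pop("fit_range", None)

    starts = np.arange(0, n - win + 1, step)
    times = (starts + win / 2.0) / signal.fs
    delta = np.full(starts.size, np.nan)
    stderr = np.full(starts.size, np.nan)
    n_events = np.zeros(starts.size)
    e_lo, e_hi_max = cfg.e_band
    for k, s0 in enumerate(starts):
        window = RawSignal(signal.data[s0 : s0 + win], fs=signal.fs, name=signal.name)
        train = striping.extract_events(window, stripe_cfg)
        n_events[k] = train.n_events
        if train.n_events < cfg.min_events:
            continue
        if "w_grid" not in params:
            tau = win / train.n_events
            e_hi = min(e_hi_max, train.n_events / 25.0)
            if e_hi <= 1.6 * e_lo:
                continue
            w_grid = np.unique(
                np.maximum(
                    2, np.round(np.logspace(np.log10(e_lo * tau), np.log10(e_hi * tau), cfg.n_w))
                ).astype(int)
            )
            if w_grid.size < 6:
                continue
            win_params = {**params, "w_grid": w_grid}
            win_fit = fit_range if fit_range is not None else (w_grid[0], w_grid[-1])
        else:
            win_params, win_fit = params, fit_range
        traj = dea.build_trajectory(train, rule="jump_ahead")
        try:
            curve = dea.entropy_curve(traj, **win_params)
            est = dea.fit_scaling(curve, fit_range=win_fit)
        except ValueError:
            continue
        delta[k] = est.delta
        stderr[k] = est.stderr
    return ScalingTrack(
        times=times,
        delta=delta,
        stderr=stderr,
        n_events=n_events,
        window_len=cfg.window_len,
        step=cfg.step,
        name=signal.name,
    )


def align_tracks(tracks: list[ScalingTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Stack tracks sharing one scan geometry into a channels x times matrix.

    Missing windows propagate as NaN.  Tracks with mismatched time grids
    (different steps or window lengths) are a configuration error.
    """
    if not tracks:
        raise ValueError("need at least one track")
    t0 = tracks[0].times
    for tr in tracks[1:]:
        if tr.times.size != t0.size or not np.allclose(tr.times, t0):
            raise ValueError("tracks have mismatched scan time grids")
    return t0.copy(), np.vstack([tr.delta for tr in tracks])
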