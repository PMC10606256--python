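"""Seeded generators for every input class the pipeline assumes.

The central object is the *crucial-event* renewal train: waiting times are
drawn i.i.d. from a shifted-Pareto (Lomax) density

    psi(t) = (mu - 1) * T**(mu - 1) / (T + t)**mu ,   t >= 0,  1 < mu < 3,

whose tail follows the inverse power law t**(-mu).  The scale T is the only
non-asymptotic choice; it defaults to one sample.  For 2 < mu < 3 the mean
waiting time is finite, T / (mu - 2), and the train is ergodic; for
1 < mu < 2 the mean diverges and the train is non-ergodic.

Controls: fractional Brownian motion (long-memory, non-renewal) and Poisson
trains (renewal but non-crucial).  The modulated multi-channel generator
produces signals whose local mu follows a shared slow quasi-periodic
function, so that windowed scaling tracks are synchronized by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import EventTrain, MultiChannelSignal, RawSignal

__all__ = [
    "RenewalSpec",
    "ModulationSpec",
    "ModulatedGroundTruth",
    "WALK_RULES",
    "sample_waiting_times",
    "sample_waiting_times_until",
    "events_from_waits",
    "make_step_signal",
    "gen_fbm",
    "fgn",
    "gen_poisson_train",
    "gen_modulated_channels",
]

WALK_RULES = ("velocity_pm1", "impulse_at_event", "jump_ahead")


def _check_mu(mu: float) -> None:
    if not (1.0 < mu < 3.0):
        raise ValueError(f"inverse power-law index mu must lie in (1, 3), got {mu}")


@dataclass
class RenewalSpec:
    """Parameters of a crucial-event renewal train.

    mu : inverse power-law waiting-time index, 1 < mu < 3
    T : waiting-time scale in samples
    n_events : number of events to draw
    rule : walking rule used when the train is turned into a signal
    seed : integer seed; all randomness flows from it
    """

    mu: float
    n_events: int
    T: float = 1.0
    rule: str = "jump_ahead"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_mu(self.mu)
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.T <= 0:
            raise ValueError("waiting-time scale T must be positive")
        if self.rule not in WALK_RULES:
            raise ValueError(f"unknown walking rule {self.rule!r}; choose from {WALK_RULES}")


@dataclass
class ModulationSpec:
    """Shared quasi-periodic modulation of the local waiting-time index.

    mu(t) = mu_base + amplitude * sin(2*pi*t / period + phase), plus an
    independent per-channel, per-segment Gaussian jitter of standard
    deviation ``channel_jitter_sd`` on mu.
    """

    mu_base: float = 2.5
    amplitude: float = 0.3
    period: float = 120.0  # seconds
    phase: float = 0.0  # radians
    channel_jitter_sd: float = 0.02
    T: float = 1.0  # waiting-time scale, samples
    segment_len: float = 1.0  # seconds of piecewise-stationary segments
    max_wait: float = 5.0  # seconds; physiological ceiling on silent gaps

    def __post_init__(self) -> None:
        lo = self.mu_base - abs(self.amplitude)
        hi = self.mu_base + abs(self.amplitude)
        if not (1.0 < lo and hi < 3.0):
            raise ValueError(
                f"modulation leaves the crucial-event domain: mu in [{lo}, {hi}] not within (1, 3)"
            )
        if self.period <= 0 or self.segment_len <= 0:
            raise ValueError("period and segment_len must be positive")
        if self.channel_jitter_sd < 0:
            raise ValueError("channel_jitter_sd must be >= 0")

    def mu_at(self, t: np.ndarray | float) -> np.ndarray:
        """Jitter-free shared modulation mu(t) at time t (seconds)."""
        t = np.asarray(t, dtype=float)
        return self.mu_base + self.amplitude * np.sin(2 * np.pi * t / self.period + self.phase)


@dataclass
class ModulatedGroundTruth:
    """Per-segment ground truth returned alongside modulated channels."""

    seg_times: np.ndarray  # segment-centre times, seconds
    mu: np.ndarray  # (n_channels, n_segments) realized (jittered) mu
    delta: np.ndarray  # 1 / (mu - 1), same shape
    shared_delta: np.ndarray  # jitter-free 1 / (mu(t) - 1)

    def delta_at(self, t: np.ndarray, channel: int | None = None) -> np.ndarray:
        """Ground-truth delta interpolated at times t (seconds)."""
        track = self.shared_delta if channel is None else self.delta[channel]
        return np.interp(np.asarray(t, dtype=float), self.seg_times, track)


# ---------------------------------------------------------------------------
# waiting times and event trains


def sample_waiting_times(spec: RenewalSpec) -> np.ndarray:
    """Draw i.i.d. waiting times from the shifted-Pareto density.

    Inverse-transform sampling is exact: with U ~ Uniform(0, 1),
    t = T * (U**(-1/(mu-1)) - 1) has survival function (T/(T+t))**(mu-1).
    """
    rng = np.random.default_rng(spec.seed)
    return _waits(spec.mu, spec.T, spec.n_events, rng)


def _waits(mu: float, T: float, n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    return T * (u ** (-1.0 / (mu - 1.0)) - 1.0)


def sample_waiting_times_until(
    mu: float, t_max: float, rng: np.random.Generator, T: float = 1.0, chunk: int = 1024
) -> np.ndarray:
    """Draw waiting times until their cumulative sum exceeds ``t_max``."""
    _check_mu(mu)
    parts = []
    total = 0.0
    while total <= t_max:
        w = _waits(mu, T, chunk, rng)
        parts.append(w)
        total += float(w.sum())
    waits = np.concatenate(parts)
    stop = np.searchsorted(np.cumsum(waits), t_max, side="right") + 1
    return waits[:stop]


def events_from_waits(waits: np.ndarray, dt: float = 1.0, length: int | None = None) -> EventTrain:
    """Accumulate waiting times into integer sample indices.

    ``dt`` is the number of samples per unit waiting time.  Events that
    round onto the same sample are merged so the train stays strictly
    increasing.
    """
    waits = np.asarray(waits, dtype=float)
    if np.any(waits < 0):
        raise ValueError("waiting times must be nonnegative")
    if waits.size == 0:
        return EventTrain(np.empty(0, dtype=np.int64), length=int(length or 0))
    pos = np.cumsum(waits) * dt
    idx = np.unique(np.floor(pos).astype(np.int64))
    if length is None:
        length = int(idx[-1]) + 1
    else:
        idx = idx[idx < length]
    return EventTrain(idx, length=int(length))


def make_step_signal(
    train: EventTrain, length: int, rule: str, seed: int = 0, fs: float = 1.0
) -> RawSignal:
    """Walker increment signal xi(t) for a walking rule.

    velocity_pm1 : xi is constant +/-1 between events; the sign is re-drawn
        by a fair coin toss at every event.
    impulse_at_event : xi vanishes between events and takes the value +/-1
        (fair coin) at event samples.
    jump_ahead : xi vanishes between events and is +1 at event samples.
    """
    if rule not in WALK_RULES:
        raise ValueError(f"unknown walking rule {rule!r}; choose from {WALK_RULES}")
    ev = train.indices
    if ev.size and ev[-1] >= length:
        raise ValueError("all event indices must be < length")
    rng = np.random.default_rng(seed)
    xi = np.zeros(length)
    if rule == "jump_ahead":
        xi[ev] = 1.0
    elif rule == "impulse_at_event":
        xi[ev] = rng.choice([-1.0, 1.0], size=ev.size)
    else:  # velocity_pm1
        signs = rng.choice([-1.0, 1.0], size=ev.size + 1)
        bounds = np.concatenate([[0], ev, [length]]).astype(np.int64)
        xi = np.repeat(signs, np.diff(bounds))
    return RawSignal(xi, fs=fs, name=rule)


# ---------------------------------------------------------------------------
# controls


def fgn(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by Davies–Harte circulant embedding.

    Returns n increments with autocovariance
    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}).
    """
    if not (0.0 < H < 1.0):
        raise ValueError(f"Hurst index must lie in (0, 1), got {H}")
    if H == 0.5:
        return rng.standard_normal(n)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size
    lam = np.fft.rfft(row).real
    # circulant eigenvalues are theoretically nonnegative for fGn; clamp fp noise
    lam = np.maximum(lam, 0.0)
    z = rng.standard_normal(lam.size) + 1j * rng.standard_normal(lam.size)
    z[0] = z[0].real * math.sqrt(2.0)
    z[-1] = z[-1].real * math.sqrt(2.0)
    path = np.fft.irfft(np.sqrt(lam / (2.0 * m)) * z * m, n=m)
    return path[:n]


def gen_fbm(H: float, length: int, seed: int = 0, fs: float = 1.0) -> RawSignal:
    """Discrete fractional Brownian motion path of a given Hurst index."""
    rng = np.random.default_rng(seed)
    return RawSignal(np.cumsum(fgn(H, length, rng)), fs=fs, name=f"fbm_H{H:g}")


def gen_poisson_train(rate: float, length: int, seed: int = 0, fs: float = 1.0) -> EventTrain:
    """Homogeneous Poisson events: exponential waits, renewal, non-crucial."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    n_guess = int(rate * length + 6 * math.sqrt(rate * length) + 16)
    waits = rng.exponential(1.0 / rate, size=n_guess)
    while waits.sum() <= length:
        waits = np.concatenate([waits, rng.exponential(1.0 / rate, size=n_guess)])
    pos = np.cumsum(waits)
    idx = np.unique(np.floor(pos[pos < length]).astype(np.int64))
    return EventTrain(idx, length=int(length), fs=fs)


# ---------------------------------------------------------------------------
# modulated multi-channel generator


def _modulated_channel(
    mod: ModulationSpec, n_samples: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One telegraph channel whose local mu follows the modulation.

    The signal alternates between +1 and -1 at every event so that stripe
    extraction recovers the event train exactly.  Returns (signal, mu per
    segment).
    """
    seg = int(round(mod.segment_len * fs))
    n_seg = int(np.ceil(n_samples / seg))
    t_seg = (np.arange(n_seg) + 0.5) * mod.segment_len
    mu_seg = mod.mu_at(t_seg)
    if mod.channel_jitter_sd > 0:
        # smooth per-channel jitter (correlation time ~30 s) so that the
        # stated sd survives window-scale averaging instead of washing out
        # as independent per-segment noise
        z = rng.normal(size=n_seg)
        k = np.exp(-np.arange(n_seg) * mod.segment_len / 30.0)
        smooth = np.convolve(z, k)[:n_seg]
        sd = smooth.std()
        if sd > 0:
            mu_seg = mu_seg + mod.channel_jitter_sd * smooth / sd
    mu_seg = np.clip(mu_seg, 1.05, 2.95)

    # sequential renewal draws: each waiting time follows the law of the
    # segment in which it starts and may extend across segment boundaries,
    # so the heavy tail is never censored
    events = []
    t = 0.0
    while t < n_samples:
        s = min(int(t // seg), n_seg - 1)
        seg_end = (s + 1) * seg
        mu_now = mu_seg[s]
        mean_w = mod.T / max(mu_now - 2.0, 0.05) + mod.T
        k = max(16, int((seg_end - t) / mean_w * 1.5))
        w = _waits(mu_now, mod.T, k, rng)
        if mod.max_wait > 0:
            # organ signals keep producing events: cap silent gaps at a
            # physiological ceiling (the inverse power law is preserved
            # over the window scales the scan resolves)
            w = np.minimum(w, mod.max_wait * fs)
        pos = t + np.cumsum(w)
        events.append(pos[pos < seg_end])
        if pos[-1] >= seg_end:
            # first wait crossing the boundary keeps its draw-time law;
            # later draws of this chunk are discarded
            nxt = pos[pos >= seg_end][0]
            if nxt < n_samples:
                events.append(np.array([nxt]))
            t = nxt
        else:
            t = pos[-1]
    pos_all = np.concatenate(events) if events else np.empty(0)
    ev = np.unique(np.floor(pos_all).astype(np.int64))
    ev = ev[(ev >= 0) & (ev < n_samples)]

    sign = np.ones(n_samples)
    if ev.size:
        flips = np.zeros(n_samples)
        flips[ev] = 1.0
        sign = np.where(np.cumsum(flips) % 2 == 0, 1.0, -1.0)
    return sign, mu_seg


def gen_modulated_channels(
    mod: ModulationSpec,
    n_channels: int,
    duration: float,
    fs: float,
    seed: int = 0,
    independent: bool = False,
) -> tuple[MultiChannelSignal, ModulatedGroundTruth]:
    """Multi-channel telegraph signals with a shared slow mu(t) modulation.

    Every channel is a +/-1 telegraph whose event rate follows piecewise-
    stationary segments with local index mu(t); the ground-truth windowed
    scaling index is delta(t) = 1 / (mu(t) - 1) (ergodic branch).  With
    ``independent=True`` each channel receives its own random period and
    phase, producing unsynchronized tracks (a null fixture).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    n_samples = int(round(duration * fs))
    ss = np.random.SeedSequence([int(seed), 0xC5])
    child = ss.spawn(n_channels + 1)
    rng_mod = np.random.default_rng(child[-1])

    sigs, mus = [], []
    for c in range(n_channels):
        rng = np.random.default_rng(child[c])
        m = mod
        if independent:
            # fast, incommensurate periods and random phases decorrelate the
            # tracks within records holding only a handful of cycles
            m = ModulationSpec(
                mu_base=mod.mu_base,
                amplitude=mod.amplitude,
                period=float(np.exp(rng_mod.uniform(np.log(mod.period / 3.0), np.log(mod.period)))),
                phase=float(rng_mod.uniform(0.0, 2 * np.pi)),
                channel_jitter_sd=mod.channel_jitter_sd,
                T=mod.T,
                segment_len=mod.segment_len,
                max_wait=mod.max_wait,
            )
        x, mu_seg = _modulated_channel(m, n_samples, fs, rng)
        sigs.append(x)
        mus.append(mu_seg)

    mu = np.vstack(mus)
    n_seg = mu.shape[1]
    seg_times = (np.arange(n_seg) + 0.5) * mod.segment_len
    gt = ModulatedGroundTruth(
        seg_times=seg_times,
        mu=mu,
        delta=1.0 / (mu - 1.0),
        shared_delta=1.0 / (mod.mu_at(seg_times) - 1.0),
    )
    signal = MultiChannelSignal(
        np.column_stack(sigs), fs=fs, channels=[f"ch{c + 1}" for c in range(n_channels)]
    )
    return signal, gt
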