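# Methods

`csync` implements a pipeline for measuring *complexity synchronization*:
the covariation in time of the temporal-complexity indices of several
simultaneously recorded physiological channels (EEG, ECG, respiration and
the like).  This note records the models, the estimators, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Crucial events and the index algebra

The working model of a physiological channel is a renewal point process
whose inter-event waiting times follow an inverse power law,
psi(t) ∝ t^(−mu) with 1 < mu < 3 ("crucial events").  The package adopts
the shifted-Pareto (Lomax) form

    psi(t) = (mu − 1) T^(mu−1) / (T + t)^mu ,      t ≥ 0,

because it has exactly the required tail, admits exact inverse-transform
sampling, and is the conventional finite-time completion in this
literature; the scale T defaults to one sample.  For 2 < mu < 3 the mean
wait T/(mu − 2) is finite and the train is ergodic; for 1 < mu < 2 the
mean diverges, the process ages, and time averages and ensemble averages
part company — a fact with concrete consequences for estimation (below).

A signal X(t) built from the events scales as X(λt) = λ^delta X(t).  The
scaling index delta, the waiting-time index mu, the spectral index beta
and the fractal dimension D are interchangeable measures of complexity:

    D = 2 − delta                  (always)
    beta = 3 − mu                  (beta = 1 at mu = 2: true 1/f noise)
    mu = 1 + delta                 (non-ergodic branch, 1 ≤ mu ≤ 2)
    mu = 1 + 1/delta               (ergodic branch, 2 ≤ mu ≤ 3)
    delta = 1/2                    (Gaussian regime, mu ≥ 3)

The delta→mu map is two-valued, so every conversion in `csync.indices`
demands an explicit regime argument; guessing silently would corrupt
reports.  Two further indices describe the diffusion trajectory: the
first-passage (recrossing) index muD = 2 − delta, and the crucial-event
index muS recovered from it by the super-diffusive relation
muS = 1 + 1/(2 − muD) or the sub-diffusive relation muS = 5 − 2·muD.  The
sub-diffusive relation is derived under 1 < muS < 2; applying it outside
that band (as is done for the self-organized-criticality first-passage
value muD = 1.3, giving muS = 2.4) produces a warning, not an error,
because that usage is itself part of the method's record.

## The stripe method

Continuous signals are converted to events by partitioning the amplitude
axis into stripes of fixed width; an event is a change of stripe index
between consecutive samples.  Design choices:

* the stripe grid is anchored at the signal minimum by default (the
  method's sources do not define an anchor; this choice leaves no empty
  leading stripes), and the anchor is configurable;
* samples exactly on a boundary belong to the upper stripe (floor
  convention), a deterministic tie-break;
* no hysteresis: the simplest reading of the method, and reproducible.

Event counts are invariant under affine transforms of the signal when the
grid co-moves — the property test in the suite.

## Modified diffusion entropy analysis

An event train becomes a diffusion trajectory through a walking rule:
`jump_ahead` (+1 at each event, flat otherwise — the default, and the rule
used throughout the windowed analysis), `velocity_pm1` (±1 velocity held
between events, sign re-drawn by a fair coin at each event) and
`impulse_at_event` (±1 at events, zero otherwise).  If the windowed
displacement PDF has the scaling form P(x, w) = w^(−delta) F(x/w^delta),
the Shannon entropy obeys S(w) = S(1) + delta·ln w, and delta is read as
the OLS slope of S against ln w.

Numerical conventions:

* **Binning.** Unit-width bins for integer-valued walks.  Real-valued
  trajectories use a Freedman–Diaconis width on the displacements at each
  w, *with the +ln(bin width) differential-entropy correction*.  Without
  that correction a per-w adaptive width cancels the very scale growth
  the method measures; with it, the estimate approximates the
  differential entropy, whose slope is exactly delta, and adaptive widths
  keep the resolution proportional to the distribution's width at every
  w.  A Miller–Madow term corrects the finite-count bias.
* **Windows.** Mobile (fully overlapping) start points, strided only when
  their number exceeds a cap (default 200 000), which bounds cost without
  biasing the time average.  Window sizes are log-spaced, by default 25
  points in [10, length/10]; the default fit range is the central decade
  of the valid grid.  Windows are half-open [t, t+w), indexing 0-based.
* Entropies are in nats; the slope is base-independent.
* Window sizes with fewer than `min_subwindows` (default 50)
  displacements are flagged missing, never extrapolated.
* Estimates outside 0 < delta < 1 are returned flagged, never clipped.

### Finite-size behaviour and the recovery protocols

The entropy curve of a finite ergodic train is *not* straight: counting
fluctuations converge slowly to their one-sided stable law (index
mu − 1), producing a transient at small windows, while end-of-series
truncation bends the curve down at large windows.  Near mu = 2 a single
waiting time can be a finite fraction of the whole record, so single-run
slopes scatter heavily no matter where the fit is placed.  The package
therefore ships reference recovery protocols (`csync.recovery`):

* **Ergodic branch** (2 < mu < 3, target delta = 1/(mu − 1)):
  `recover_delta_ergodic` simulates several independent signals (default
  16 realizations of 1e5 waits), runs the full chain signal → stripes →
  events → jump-ahead → entropy on a window grid proportional to each
  realization's extracted mean inter-event time, takes the pointwise
  *median* curve (robust to single-gap outliers), and fits over windows
  spanning 20–500 mean inter-event times.  That band was calibrated on
  synthetic ground truth — including held-out mu values between the
  benchmark points — to sit inside the stable-scaling region, above the
  discreteness transient and below the truncation droop; with the default
  sizes it recovers delta within ±0.04 (bias ≲ 0.03, spread ≲ 0.015).
* **Sub-diffusive branch** (1 < muS < 2, impulse rule, target
  delta = (muS − 1)/2 = 2 − muD with muD = 2.5 − muS/2): the process is
  non-ergodic and ages, and the time-averaged entropy of one long record
  drifts toward the local Gaussian value 1/2 instead of the ensemble
  scaling; verified numerically, not an implementation artifact.  The
  scaling PDF is an ensemble object here, so
  `recover_delta_subdiffusive` pools fixed-origin displacements X(w)
  across many short independent realizations (default 4000) and recovers
  delta within ±0.01 at muS = 1.5.

For fractional Brownian motion the displacement law is exactly
self-similar at every scale, so the fit uses the early decades
(w ∈ [10, length/100]); the largest windows are excluded because
long-memory increments leave them with few effectively independent
samples.  Recovered delta matches the Hurst index within 0.05 down to
1e5-sample paths.

The shuffle contrast ("memory beyond memory") permutes waiting times of
an event train, or increments of a continuous path, and re-runs the
analysis: renewal trains keep their delta (their law is exchangeable in
the waits), while FBM collapses to delta = 1/2.

## Windowed scans and synchronization

`mfscan.scan` applies stripe → jump-ahead → entropy-slope inside sliding
windows (default one minute, stepped by 20 s) to produce delta(t).  Two
window-scale choices matter:

* The per-window size grid spans 10–400 mean inter-event times *of that
  window's own train*, capped above at n_events/25 so every fitted size
  keeps ≥ ~25 independent sub-windows, and the slope is fitted across the
  whole grid.  Tying the grid to the local event rate keeps the response
  to mu(t) monotone as the rate drifts; a grid fixed in samples slides
  into the discreteness transient whenever the rate drops and folds the
  response.
* Windows with fewer than `min_events` (default 30) events, or whose
  usable grid collapses, yield a missing value.

One-minute windows operate inside the stable-law transient, so windowed
delta values carry a finite-window bias of a few hundredths and cannot
certify scaling much steeper than delta ≈ 0.85 — a window simply cannot
hold the laminar gaps that steep scaling implies.  Consequently windowed
tracks *compress* the true dynamic range and their Pearson correlation
with ground truth saturates around 0.6–0.8 even at EEG-like sampling
rates; tests assert the association at the level the estimator actually
attains.  Cross-channel synchronization, by contrast, is robust: all
channels share the same response curve, so the cross-correlation of their
tracks reflects the shared modulation faithfully.

`csreport` quantifies synchronization by zero-lag Pearson coefficients on
pairwise-complete windows (missing windows deleted pairwise), both
channel-by-channel and between a group-average track (e.g. an EEG mean)
and the remaining channels — the two conventions found in practice; both
are reported and labelled.  Delta-delta = max − min of a track summarizes
a channel's flexibility.  No significance testing is attached by default;
a permutation null is available.

## The synthetic benchmark generator

`synthgen` provides every input class with known ground truth: Lomax
renewal trains under the three walking rules, exact fractional Gaussian
noise / FBM by Davies–Harte circulant embedding, Poisson trains (renewal
but non-crucial controls), and multi-channel telegraph signals whose
local mu follows a shared slow quasi-periodic modulation

    mu(t) = mu_base + amplitude · sin(2π t / period + phase),

with defaults mu_base = 2.5, amplitude = 0.3, period = 120 s and smooth
per-channel jitter of sd 0.02 on mu (correlation time ~30 s, so the
stated sd survives window-scale averaging).  Channels are ±1 telegraphs
flipping at every event, so stripe extraction recovers the events
exactly; the ground-truth windowed index is delta(t) = 1/(mu(t) − 1).
Generation is piecewise-stationary in 1-s segments; each waiting time
follows the law of the segment in which it *starts* and may cross
boundaries, so the heavy tail is never censored.  Waiting times are
capped at 5 s: real organ signals keep producing events, whereas an
uncapped mu ≈ 2.2 train occasionally goes silent for tens of seconds,
which no windowed protocol could bridge; the cap leaves the power law
intact over all scales the scan resolves.  With `independent=True` each
channel receives its own random period (log-uniform over [period/3,
period]) and phase — the null fixture.

What these fixtures do *not* emulate: volume conduction or shared
sensor noise, artifacts, non-renewal oscillatory components, and any
physiologic coupling mechanism beyond the imposed common modulation.
Passing the synchronization benchmarks therefore shows that the pipeline
detects covarying complexity when it exists and reports none when it does
not — it does not validate any particular physiological interpretation.

All generators draw every random number from a single integer seed per
call (numpy `SeedSequence` children); no global state.

## Known limitations

* Single-record delta estimates near mu = 2 are irreducibly noisy at
  1e5 events; the recovery protocols average over realizations, which an
  empirical analysis cannot.  Treat single-window values as noisy.
* The windowed estimator's absolute values are transient-biased; use the
  long-record protocol for absolute index estimates and the scan only
  for time-resolved structure.
* The stripe method assumes amplitude resolution is meaningful; heavily
  quantized or clipped signals need a stripe size matched to the
  quantization step.
* Spectral estimation of beta is out of scope; beta is derived from mu
  algebraically.
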