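# csync

Complexity-synchronization analysis of multichannel physiological time
series: crucial-event extraction with the stripe method, modified
diffusion entropy analysis (MDEA), time-resolved scaling tracks delta(t),
the complexity-index algebra, and cross-channel synchronization reports.

## The problem

Signals from the brain, heart and lungs look nothing alike, yet each can
be modelled as a train of *crucial events* — renewal events whose waiting
times follow an inverse power law psi(t) ∝ t^(−mu) with 1 < mu < 3.  The
temporal complexity of such a train is captured by the scaling index
delta of the diffusion process built from the events, X(λt) = λ^delta
X(t), or equivalently by the fractal dimension D = 2 − delta, the
spectral index beta = 3 − mu, or mu itself:

    mu = 1 + delta      (non-ergodic, 1 ≤ mu ≤ 2)
    mu = 1 + 1/delta    (ergodic,     2 ≤ mu ≤ 3)
    delta = 1/2         (Gaussian,    mu ≥ 3)

MDEA estimates delta from data: partition the signal amplitude into
stripes, mark a crossing between stripes as an event, advance a walker by
one unit at each event ("jumping ahead"), and read delta as the slope of
the Shannon entropy of windowed displacements against ln(window size).
Applying MDEA inside sliding windows (one minute, stepped by 20 s) gives
a time-resolved track delta(t) per channel; when the tracks of different
organ signals rise and fall together — quantified by the Pearson
cross-correlation of the tracks — the signals exhibit *complexity
synchronization*.

The package is aimed at researchers analysing multichannel physiological
recordings and at methodologists who want a tested, seeded reference
implementation with synthetic benchmarks whose ground truth is known.

## Worked example

```python
from csync import csreport, indices, mfscan, striping, synthgen
from csync.recovery import recover_delta_ergodic

# 1. the index algebra: complete the tuple from delta on the ergodic branch
s = indices.index_set(0.714, "ergodic")
# -> {'delta': 0.714, 'mu': 2.4006, 'beta': 0.5994, 'D': 1.286, 'regime': 'ergodic'}

# 2. parameter recovery: simulate crucial-event signals at mu = 2.5 and
#    estimate delta through the full stripe + MDEA chain
d = recover_delta_ergodic(2.5, seed=1)
# -> 0.633, against the ergodic ground truth 1/(mu-1) = 0.667

# 3. synchronization: three channels sharing a slow quasi-periodic
#    modulation of their local mu; windowed tracks; pairwise correlations
mod = synthgen.ModulationSpec()          # mu = 2.5 +/- 0.3, period 120 s
sig, _ = synthgen.gen_modulated_channels(mod, 3, 600.0, 2000.0, seed=1)
tracks = [mfscan.scan(ch, striping.StripeConfig(1.0), mfscan.ScanConfig())
          for ch in sig]
rep = csreport.build_report(tracks)
# -> pairwise CC of delta(t) tracks: min = 0.814, max = 0.916
# -> delta ranges (max - min per channel): 0.232, 0.242, 0.218
```

The index set shows delta = 0.714 sitting on the ergodic branch
(mu ≈ 2.40, i.e. finite mean waiting times, spectral index beta ≈ 0.60,
fractal dimension 1.29).  The recovered delta = 0.633 agrees with the
ground truth 0.667 to within the protocol's documented accuracy (±0.05).
The cross-correlations ≥ 0.81 show the three synthetic channels'
complexity tracks moving together, as built in; with independently
modulated channels the same report returns correlations near zero.

## Command line

A thin CLI wraps the library:

    csync simulate --kind modulated --channels 3 --duration 600 --fs 2000 --seed 1 --out sim.csv
    csync events   --stripe-size 1.0 --in sim.csv --out events.csv
    csync dea      --in events.csv --out curve.csv
    csync scan     --config scan.yaml --in sim.csv --out tracks/
    csync convert  --delta 0.714 --regime ergodic
    csync report   --tracks tracks/ --out report.json
    csync run      --config scan.yaml --in sim.csv

`csync run` executes the whole pipeline and writes per-channel tracks, a
cross-correlation matrix and a JSON report embedding the resolved
configuration and package version.

## Layout

    src/csync/synthgen.py   seeded generators with ground truth
    src/csync/striping.py   stripe method: signal -> event train
    src/csync/dea.py        diffusion entropy, scaling fits, shuffle test
    src/csync/recovery.py   reference parameter-recovery protocols
    src/csync/mfscan.py     sliding-window delta(t) tracks
    src/csync/indices.py    delta / mu / beta / D conversions
    src/csync/csreport.py   synchronization report (CC matrix, ranges)
    src/csync/io.py         CSV/YAML formats, pipeline runner
    src/csync/cli.py        the `csync` command

See `docs/methods.md` for the estimators' assumptions, finite-size
behaviour, and the design decisions behind the defaults.
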