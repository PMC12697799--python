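# ncrkit — neural code reliability

`ncrkit` asks a simple question of a spike train: **if similar stimuli
evoke similar spiking patterns, how well can the stimulus be read back from
the pattern?** It reconstructs a continuous complex-sound spectrogram from
spike trains by averaging the stimulus segments behind the k most similar
spiking patterns, and scores the reconstruction by

```
NCR = log10 |Corr[S; N]|
```

the log absolute Pearson correlation between the actual stimulus
spectrogram `S` and its reconstruction from the response `N` (≤ 0; higher
is more reliable). Two codes are compared through a single knob — the
distance between spiking patterns: a **temporal code** (Euclidean distance
on 0.5 ms-binned spike trains convolved with a 9 ms Hann taper) and a
**rate code** (spike count in the analysis window, 100 ms by default). The
toolkit is aimed at auditory systems neuroscientists, but nothing in it is
specific to audition beyond the stimulus generators.

On top of the decoder it provides:

* **Null calibration** — NCR of homogeneous Poisson trains against the same
  stimulus sets the significance threshold (≈ −2.1 at the default 95th
  percentile under the default study conditions), independent of firing
  rate.
* **Pair synergy/redundancy** — the joint per-frequency correlation profile
  of a unit pair decomposed as `c12 = synergy + c1 + c2 − redundancy` with
  `redundancy = min(c1, c2)`, plus a ±100%-normalized synergy summary.
* **Silence and combinatorial codes** — decoding restricted to windows of
  neural silence, of spiking, or where one unit fires while the other is
  silent.
* **Stimulus complexity** — proximity, mean speed and local dissimilarity
  of the two sweep voices, and their correlation with the reliability
  profile `|Corr|(t)`.
* **STRF tools** — spectrotemporal receptive fields from a randomized
  pure-tone protocol, with best frequency, bandwidth, latency and duration,
  and tuning-vs-reliability views.
* **Synthetic ground truth** — the random-double-sweep stimulus, Poisson
  null units, and linear–nonlinear–Poisson encoders with controllable
  tuning, latency, gain and jitter, so every estimator is testable against
  known answers.

## Worked example

```python
import numpy as np
from ncrkit import (generate_rds, render_spectrogram, precise_encoder,
                    simulate_lnp, decode, scan_lags, calibrate_null)

sweeps = generate_rds(duration=60.0, seed=0)
stim = render_spectrogram(sweeps)                # 45 channels x 5 ms bins
fine = render_spectrogram(sweeps, dt=1e-3)       # 1 ms grid for simulation

unit = simulate_lnp(precise_encoder(bf=16_000.0, latency=0.015, seed=0),
                    fine, sample_dt=1.25e-4)
print(f"unit rate: {unit.n_spikes / unit.duration:.1f} sp/s")

for code in ("temporal", "rate"):
    res = decode([unit], stim, code)
    print(f"{code:8s} NCR = {res.ncr:.3f}  (|corr| = {10**res.ncr:.4f})")

null = calibrate_null(stim, rates=(2.0, 40.0), n_trains=10, seed=0)
print(f"null threshold (95th pct, 20 samples): {null.threshold:.3f}")

_, best = scan_lags([unit], stim, "temporal")
print(f"best stimulus-to-response delay: {best * 1e3:.0f} ms")
```

prints

```
unit rate: 45.1 sp/s
temporal NCR = -0.580  (|corr| = 0.2627)
rate     NCR = -0.647  (|corr| = 0.2255)
null threshold (95th pct, 20 samples): -1.942
best stimulus-to-response delay: 15 ms
```

The sharply tuned, precisely timed model unit decodes far above the Poisson
null, the temporal code beats the rate code (it would reverse for a
jittered, slowly integrating unit — see `jittered_slow_encoder`), and the
lag scan recovers the encoder's 15 ms latency. `decode` also returns the
per-time and per-frequency correlation profiles (`res.corr_t`,
`res.corr_f`) and the reconstructed spectrogram (`res.decoded.predicted`).

The same pipeline is scriptable from the shell via the `ncr` command
(`simulate`, `decode`, `scan-lags`, `scan-windows`, `calibrate`, `pair`,
`strf`, `demo`); spike tables are CSV (`unit_id,time_s`), grids are NPZ
containers, scalar results are JSON. `ncr demo` runs a seeded end-to-end
pipeline (stimulus → population → calibration → decoding → pair
decomposition) and writes a machine-readable report.

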