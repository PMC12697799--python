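# Methods

`ncrkit` measures how *reliably* a neural code represents a complex sound:
if similar stimuli evoke similar spiking patterns, then the stimulus behind
a pattern can be predicted by averaging the stimulus segments behind the
most similar patterns elsewhere in the recording. This note documents the
model, the estimators, the synthetic study conditions, and the numerical
choices; the README shows the user-facing workflow.

## The decoder

For a response window at time `t` (default length 100 ms), the decoder:

1. represents the window by a code vector — **temporal code**: spike counts
   in 0.5 ms bins convolved with a peak-normalized 9 ms Hann taper (19
   taps), one segment per unit, concatenated across units; **rate code**:
   the per-unit spike count;
2. finds the `k = 100` candidate windows with the smallest Euclidean code
   distance, excluding every candidate that overlaps the query in time
   (|Δstart| < window length) — without this exclusion a window would
   trivially retrieve itself;
3. averages the stimulus segments behind those `k` windows at each lag in
   `lags` (default {−10 ms, 0}; the segment for a window starting at `w`
   and lag `g` is `S[:, w+g : w+g+L]`), places the average at `[t+g, t+g+L]`
   and averages overlapping placements pixelwise;
4. scores the reconstruction by `NCR = log10 |Corr|`, the log absolute
   Pearson correlation between actual and predicted spectrograms over all
   covered pixels, together with per-time (`Corr(t)`, across frequency) and
   per-frequency (`Corr(f)`, across time) profiles.

NCR is ≤ 0 by construction; 0 means perfect (anti-)correlation. A constant
(zero-variance) prediction is a defined *no-information* sentinel,
serialized as `ncr = -inf`, never silently dropped.

Candidate windows step at 10 ms; queries are evaluated on a coarser 50 ms
grid (`eval_stride`), which quarters the search cost at negligible loss
because adjacent queries share 90% of their window content. Ties at the
k-th distance — ubiquitous for the rate code, where silent windows are all
identical — are resolved by a uniform draw seeded per query from
`(tie_seed, query index)`, so results are reproducible and independent of
internal chunking. Tie detection uses a relative tolerance of 1e-4 on
squared distances because code vectors are held in float32 and the
norm-expansion GEMM leaves identical patterns a rounding error apart.

**Lag conventions.** `decode(lags=...)` uses signed segment shifts
(negative = stimulus precedes the spikes, matching auditory latency).
`scan_lags(delays=...)` exposes the equivalent positive
*stimulus-to-response delays* and decodes each delay `d` with `lags={-d}`;
the best delay estimates the response latency. Ties go to the smallest
delay.

**Masked decoding.** Silence (no spikes in any unit of the group), spiking
(≥ 1 spike), and combinatorial (one named unit fires, the other is silent;
pairs only) masks restrict *both* the query and the candidate pools. For
restricted pair analyses the joint profile comes from the restricted decode
while the single-unit profiles always come from the unrestricted decodes,
so restricted synergy is measured relative to the full single-unit
information.

## Null calibration

Significance is calibrated by decoding homogeneous Poisson trains (the
null has no stimulus information) against the same stimulus under both
codes and pooling the NCR samples; the threshold is the 95th percentile
(configurable — the percentile behind the published −2.12 operating point
is not stated, so 95% is the package's default and is recorded in the
output). With the default study conditions (300 s stimulus, 100 trains with
rates log-uniform in 2–40 sp/s) the threshold lands near −2.2 and is
insensitive to the Poisson rate: the regression slope of null NCR on rate
is statistically indistinguishable from zero at the sample sizes we test
(a ~+0.006 log-unit/sp/s tendency is within its standard error band).

## Pair synergy and redundancy

For units 1 and 2 with absolute per-frequency correlation profiles `c1(f)`,
`c2(f)` and joint profile `c12(f)`, the decomposition follows the
partial-information pattern

    c12 = synergy + c1 + c2 - redundancy        (per frequency bin)

with `redundancy(f) = min(c1, c2)(f)` (the minimum information available
from either unit alone). The identity then forces
`synergy(f) = c12(f) - max(c1, c2)(f)`. The normalized summary averages
`100 * synergy(f) / max(c12, c1, c2)(f)` over valid bins (per-bin
normalization *before* averaging — the only order for which the analytic
limits are attainable): +100% when information exists only in the pair,
−100% when pairing destroys all single-unit information, 0 when the pair
matches the better single unit. Bins whose three-way maximum is 0 are
excluded and counted. The decomposition operates on absolute profiles.

## STRF tools

STRFs are PSTH grids (1 ms bins, averaged over 8 tone repetitions, sp/s)
over the 45 tone frequencies, smoothed with a uniform 5×5 window
(reflective edges). Significance: smoothed rate > baseline mean + 6
baseline SDs, with the baseline taken from the first 10 ms. Two estimator
details matter in practice:

* the baseline SD is estimated on the *raw* bins (≈ 450 samples) and
  scaled to the smoothed grid (×1/5 in the interior; near edges the exact
  per-position factor of the reflective smoother is used, since reflection
  averages duplicated bins and inflates local variance). Estimating the SD
  directly on the handful of effectively independent smoothed baseline
  samples is unstable and produced ~30% false-positive masks on untuned
  Poisson units; with the exact scaling the false-positive rate is ≤ a few
  percent;
* the Poisson counting noise of the rate estimate floors the SD (a fully
  silent baseline falls back to one expected spike per bin over the
  repetitions), because the empirical SD of near-empty bins undershoots.

Features: best frequency = argmax of the smoothed grid; bandwidth = summed
octave widths of connected significant frequency runs (each channel counts
one channel spacing, 0.122 oct by default); max rate = smoothed maximum;
spontaneous rate = baseline mean; first-spike latency = first significant
bin at the best frequency; response duration = extent of the significant
region there. The latency/duration estimators are package conventions (the
feature names are standard, their formulas are not).

`partition_by_tuning` averages a reliability profile below / within / above
the significant STRF frequency range; `bf_centered_profile` normalizes a
profile to its maximum and re-indexes it by octave offset from the best
frequency, with missing-aware population averaging.

## Synthetic study conditions

The generators define the conditions every test and the acceptance script
run under; they are not tuning knobs.

* **Stimulus** — random double sweep: two independent voices whose
  log2-frequency *velocity* is brick-wall low-pass Gaussian noise below
  10 Hz, scaled to 16 oct/s RMS, integrated, and reflected into 2–90 kHz.
  The stationary occupancy of a reflected walk is uniform, and at 16 oct/s
  a voice traverses the 5.5-octave band about once per second, so occupancy
  mixes within seconds — orders of magnitude shorter than the 5-minute
  stimulus. This matters: any persistent non-uniformity in band occupancy
  imprints a static spectral profile on *both* the stimulus and every
  average of its segments, and that shared static component biases the
  correlation score of even a completely uninformative decoder. The same
  reasoning puts reflected ridge tails in the spectrogram rendering
  (45 log-spaced channels, 5 ms bins, unit-peak Gaussian ridges of SD
  0.125 oct ≈ one channel spacing, coincident voices combined by maximum):
  edge channels capture the full folded ridge energy, keeping the
  time-averaged spectral profile flat.
* **Model neurons** — homogeneous Poisson nulls, and linear–nonlinear–
  Poisson (LNP) encoders: a separable Gaussian spectrotemporal filter
  (unit-sum weights over log-frequency, SD = `bandwidth`; unit-area
  temporal kernel, SD = `kernel_width`), half-wave rectification (a guard —
  the rendered spectrogram is nonnegative and near-zero off-ridge, so no
  mean-centering is applied), latency shift, inhomogeneous-Poisson
  sampling by per-bin Bernoulli (a warning fires above rate·dt = 0.1),
  Gaussian spike-time jitter, then refractory thinning (drop any spike
  closer than the refractory period to its kept predecessor).
* **Canonical encoders** — `precise_encoder` (bandwidth 0.125 oct, 1 ms
  kernel, gain 500, no jitter) fires brief precisely timed bursts whenever
  a voice crosses its best frequency, the regime in which within-window
  spike timing carries the information; `jittered_slow_encoder` (50 ms
  kernel, 20 ms jitter, same tuning and gain) destroys fine timing while
  the window count still tracks the stimulus. The pair realizes the
  temporal-to-rate code transition in both directions.

What the generator does *not* emulate: cochlear filtering and adaptation,
spike-sorting errors, correlated (shared-noise) variability between units,
non-Poisson interval statistics beyond the absolute refractory period, and
brain-state drift. Passing tests therefore demonstrate the estimators'
correctness and calibration on a known ground truth, not performance on
recorded data.

## Problem sizes and runtime

The test suite runs the null calibration at 36 Poisson trains (72 pooled
samples) on the full 300 s stimulus, and the seed-resampled property checks
(latency recovery, code transition, silence property, best-frequency
recovery) at 20 seeds on a 60 s stimulus; the whole suite takes ~5 minutes
on one CPU. `scripts/acceptance.py` recomputes the null threshold at the
full 100 trains (~10–12 minutes). The hot loops (k-smallest selection with
tie bookkeeping, reconstruction accumulation) are numba kernels; both are
exact, not approximations.

## Known limitations

* The decoder's cost grows with (duration/stride)²; recordings much longer
  than ~10 minutes at the default strides call for a coarser candidate
  stride or smaller k.
* Whether the published −2.12 null threshold corresponds to a percentile or
  a parametric criterion is not documented; the 95th percentile is a
  defensible default and the package records the percentile with every
  calibration.
* Whether masked analyses should restrict only the query set or also the
  candidate pool is ambiguous; the package restricts both (documented in
  `decode`), which keeps the reconstruction interpretable as "what silence
  elsewhere predicts".
* The proximity complexity trace reports a log-distance; whether "closer =
  larger" semantics are wanted is left to the caller (the sign is not
  flipped).
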