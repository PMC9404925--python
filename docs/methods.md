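# Methods

## Problem and model

The package reconstructs a continuous arterial-blood-pressure (ABP) waveform,
in mmHg, from a photoplethysmogram (PPG) recorded simultaneously at the same
sampling rate (125 Hz throughout).  The mapping is learned *per subject*: a
model is trained on the chronologically first 80% of a record's windows and
evaluated on the last 20%, because pulse morphology and the PPG-to-ABP delay
are strongly subject-dependent.

The model is a 1D W-Net: two U-Net blocks applied in sequence, the first
acting as an encoder and the second as a decoder, followed by a single
1-channel convolution with a tanh activation.  Each U-block descends
`levels` times (per level: `convs_per_level` Conv1D → BatchNorm → LeakyReLU
units, then average pooling by 2), passes a bottleneck stage, and ascends
with nearest-neighbour ×2 upsampling and skip concatenation with the
same-level encoder activation.  The LeakyReLU negative slope is 0.1.  The
U-Net variant (the left half of the W) is a single U-block with the same
head.  Three standard experiment settings are supported:

* **Method I** — W-Net on the PPG alone (1 input channel);
* **Method II** — W-Net on PPG + VPG + APG (first and second discrete
  derivatives of the PPG; 3 channels);
* **Method III** — U-Net on PPG + VPG + APG.

The deep-learning stack (reverse-mode autodiff, conv/batch-norm/pooling
layers, Adam) is implemented in `wavebp.nn` directly on numpy with a
channels-last `(batch, time, channels)` layout: convolution is one im2col
copy feeding a BLAS GEMM, its input gradient is a second GEMM against the
tap-flipped kernel, and intermediate gradient buffers are released as the
backward sweep consumes them, keeping the memory profile flat.  All model
arithmetic is float32; metric functions are float64.

## Preprocessing

* **Detrending** — the ordinary least-squares line over sample index is
  subtracted from the PPG of the whole record (it exactly annihilates affine
  trends and is idempotent).  The PPG amplitude is otherwise passed raw; an
  optional per-record z-score switch exists and is off by default.
* **Scaling** — the ABP is divided by 200 so 0–200 mmHg maps to [0, 1],
  compatible with the tanh output; reconstruction multiplies back by 200.
* **Derivatives** — VPG/APG use a forward difference at the first sample,
  the central difference `(X(i+1) − X(i−1))/2` in the interior and a backward
  difference at the last sample, computed on the full record *before*
  windowing so windows carry no per-window edge effects.
* **Windowing** — 1024-sample windows (8.192 s) at 75% overlap
  (stride 256).  A trailing stretch shorter than one window is dropped;
  windows are never padded.
* **Split** — the first `floor(0.8·n)` windows train, the rest test; no
  shuffling across the boundary.

## Training

Adam, initial learning rate 1e-3, batch size 128, 500 epochs at full scale.
The loss per window of scaled ABP is

    L = 0.05·mal + mse + (1 − |r|)

where `mal` is the maximal absolute pointwise error, `mse` the mean squared
error and `r` the Pearson correlation between the window and its
reconstruction; the batch loss is the mean over windows.  Because both
signals are on the ÷200 scale, `mal` already lies in [0, 1]; 0.05 is its
weight.  `|r|` is implemented exactly as written even though it does not
penalize anti-correlation — the MSE term dominates in that regime.  In the
differentiable loss the correlation denominator carries a 1e-8 guard so a
constant window is penalized (r → 0) rather than dividing by zero; the
scalar `pearson_r` function returns exactly 0 for zero-variance input for
the same reason.

Because `1 − |r|` is symmetric in the sign of the correlation, a freshly
initialized network sits on a ridge between two basins: whichever
correlation sign the initialization noise favors gets amplified, and the
anti-correlated solution — once reached — is a deep local minimum (leaving
it through r ≈ 0 costs ~1 in loss, staying costs only the small MSE of an
inverted low-variance signal).  Training therefore begins with a
correlation warm-up (`corr_warmup_epochs`, default 10): the first epochs
minimize `0.05·mal + mse` alone, whose single basin has the correct sign,
before the full composite loss takes over.  The warm-up is deterministic
and applies at every scale.

The learning-rate decay factor is 0.1; the trigger is reduce-on-plateau
over the epoch training loss with a patience of 50 epochs (configurable)
and a floor of 1e-6, a standard choice where only the factor itself is
pinned.  Batches are reshuffled each epoch from the run seed; no validation
split or early stopping is used.  A fixed seed gives a bit-identical run on
a fixed device.

## Stitching and evaluation

Predicted windows are stitched by keeping, at each junction, the leading
`stride` samples of the earlier window and appending the next full window —
each output sample comes from exactly one window, output length is
`(n−1)·stride + window`, and stitching ground-truth windows reproduces the
source exactly (property-tested).  No overlap averaging or cross-fading is
done.  The evaluation reference is the stitched ground-truth test windows,
so both sides share identical windowing boundaries.

Five measures compare reference and reconstruction:

* **rmse** (mmHg) and **Pearson r** on the full stitched signals;
* **normalized DTW** — dynamic time warping with local cost `|x_i − y_j|`,
  the classic three-step pattern ((i−1,j), (i,j−1), (i−1,j−1)), no warping
  window, each visited cell counted once, divided by the summed lengths
  (2N).  The DP is an O(N) two-row numba kernel validated in the tests
  against exhaustive path enumeration; it runs on the full stitched
  signals.
* **MAE of SBP/DBP** — feature points are extracted by a prominence-based
  delineator: systolic peaks are local maxima with ≥ 10 mmHg prominence
  separated by ≥ 40% of the beat period estimated from the dominant
  0.5–3 Hz spectral peak; diastolic troughs are the global minima between
  consecutive peaks (plus the flanking stretches), which enforces
  peak/trough alternation.  Each reference point is matched greedily, in
  reference order, to the nearest unused reconstructed point strictly less
  than 10 samples away; unmatched reference points are discarded and
  counted.  The MAE is the mean absolute difference over matched pairs and
  is reported as missing (never zero) when nothing matches.  This
  delineator is a documented stand-in for the published delineation
  algorithms, validated against the generator's ground truth (100% recall
  at ±2 samples on noise-free subjects).

## Synthetic subjects

Each beat is a sum of three Gaussian lobes in beat phase — systolic wave,
dicrotic shoulder, reflection wave — rolled so the beat starts at its
diastolic minimum; the sampled template is min-max normalized per beat, so
scaling to [DBP, SBP] makes the per-beat extrema *exactly* the configured
pressures on noise-free output.  Configuration validates the morphology: the
systolic lobe must carry the global maximum and a dicrotic notch (an
interior local minimum below 0.99 of its flanking maxima) must exist.

Beat periods are `60·fs/hr` with `hr ~ Normal(hr_mean, hr_sd)` truncated at
±3 sd; an ectopic beat (probability `arrhythmia_prob`) multiplies the period
by 0.6.  The PPG shares the beat timing and lobe phase/width but mixes the
lobes with its own amplitudes, is delayed by an integer number of samples
(pre-padded with its first value, keeping ground-truth alignment exact),
and receives a linear baseline drift and white noise; the ABP receives
white noise only.  Defaults model a normotensive adult under the study's
recording conditions: 120/80 mmHg, 75 ± 3 bpm, 8-min duration, 20-sample
(160 ms) PPG lag, drift 1e-5 units/sample, noise sd 0.02, no ectopy.

What the generator does *not* emulate: respiration and blood-pressure
fluctuation rhythms, measurement artifacts, probe motion, morphology change
over time, and inter-beat pressure variation (SBP/DBP are constant per
subject).  Passing tests therefore demonstrate that the pipeline is wired
correctly and can learn a realistic quasi-periodic PPG→ABP mapping with
delay and drift — not that the clinical error figures transfer to hospital
recordings.

## Reduced reference experiment

The desk-scale preset (`wavebp.presets.desk_scale`) is the configuration
used by the test suite and the reproduction script: one synthetic 10-min
subject, W-Net with 3 levels, 16 base filters and one conv unit per level
(~490k parameters), trained 100 epochs at batch size 64 (the subject yields
only ~230 training windows; halving the full-scale batch doubles the Adam
updates per epoch, which this data size needs to converge).  These sizes are the package's
reference configuration for single-CPU runs; the full-scale settings
(4 levels, 32 filters, two conv units per level, 500 epochs) remain the
defaults of `ModelConfig`/`TrainConfig`.  On this preset the held-out
reconstruction typically reaches Pearson r ≳ 0.99 and SBP MAE of a few
mmHg.

## Numerical choices and edge cases

* Window stride must be an integer (`window·(1−overlap)`); anything else is
  rejected rather than rounded.
* A split that would leave train or test empty is an error.
* Exactly-8-min records are kept by the duration filter ("less than 8 min"
  is removed); an ABP maximum of exactly 200 mmHg is kept ("above 200"
  removed).  Both filters act on the raw record.
* Feature matching uses strict `< 10` samples; a displacement of exactly 10
  is discarded.
* The derivative's interior range is 2 ≤ i ≤ N−1 with the two boundary
  formulas, resolving the overlap in the printed piecewise definition.
* Ties in the training-loss `max` distribute gradient uniformly over the
  tied samples.

## Known limitations

* Subject-specific only: no cross-subject training or transfer.
* The delineator is a stand-in; on pathological morphologies (flat pulses,
  pulsus alternans) its prominence threshold may need adjustment.
* DTW memory is O(N) but time is O(N²); full stitched records of tens of
  minutes are fine, hour-scale records would need windowed DTW.
* The numpy training stack is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for training the full 4-level model on
  hundreds of records.
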