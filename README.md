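# wavebp — PPG-to-ABP waveform reconstruction

`wavebp` reconstructs continuous arterial-blood-pressure (ABP) waveforms, in
mmHg, from photoplethysmogram (PPG) signals, using a subject-specific 1D
**W-Net** — two concatenated U-Net blocks, the first acting as an encoder
and the second as a decoder.  It is aimed at physiological-signal
researchers who want continuous, non-invasive blood-pressure waveforms
(not just cuff SBP/DBP values) from an optical sensor, and at anyone who
needs the building blocks: windowing/stitching of long biosignals, an ABP
delineator, and waveform-similarity metrics.

## Method in brief

A record of synchronized PPG and ABP at 125 Hz is preprocessed (PPG
detrended by its least-squares line; ABP divided by 200 into [0, 1]), cut
into 1024-sample windows (8.192 s) with 75% overlap, and split 80/20
chronologically.  The network maps each PPG window (optionally with its
first and second derivatives, VPG/APG) to a scaled ABP window through a
tanh output, trained with Adam on the composite loss

    L = 0.05·mal + mse + (1 − |r|)

where `mal` is the maximal absolute pointwise error, `mse` the mean squared
error and `r` the Pearson correlation of the window pair.  Predicted
windows are stitched back (the overlapped trailing 75% of the running
signal is discarded at each junction), multiplied by 200, and compared to
the reference with five measures: RMSE, Pearson r, normalized DTW distance
d̄ = d/2N, and the mean absolute error of correspondence-matched systolic
and diastolic feature points (MAE_SBP, MAE_DBP).

A synthetic-subject generator (three-Gaussian-lobe pulses with a dicrotic
notch, heart-rate jitter, a configurable PPG delay, baseline drift, noise
and optional ectopic beats, with exact per-beat SBP/DBP ground truth) makes
the whole pipeline testable without clinical data.  See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```python
from wavebp.presets import desk_scale
from wavebp.synth import generate_record
from wavebp.pipeline import run_subject

cfg = desk_scale("I", seed=0)        # W-Net, PPG-only input, 100 epochs
record, truth = generate_record(cfg.synth)   # one 10-min synthetic subject
result = run_subject(cfg, record)
rep = result.report
print(f"r={rep.pearson_r:.3f}  rmse={rep.rmse:.2f} mmHg  "
      f"mae_sbp={rep.mae_sbp:.2f}  mae_dbp={rep.mae_dbp:.2f}  "
      f"dtw={rep.dtw_norm:.3f}")
```

prints (about 13 minutes on one CPU):

```
r=0.998  rmse=1.26 mmHg  mae_sbp=2.38  mae_dbp=2.11  dtw=0.350
```

i.e. the held-out 20% of the record is reconstructed with Pearson
correlation 0.998 against the reference ABP, a pointwise error of
1.3 mmHg RMS, ~2 mmHg mean error on the matched systolic and diastolic
feature points, and a normalized DTW distance of 0.35 mmHg — the
reconstruction is nearly superimposable on the reference waveform.

The same pipeline is available from the shell:

```sh
wavebp simulate --n-records 1 --duration-s 600 --outdir records/
wavebp run --config run.yaml --records-dir records/ --outdir out/
wavebp evaluate out/reconstructions/synth-0_ref.csv out/reconstructions/synth-0_rec.csv
```

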