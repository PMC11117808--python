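# sspdim

Automatic selection of the interference-subspace dimension for
subspace-projection denoising of MEG data.

## The problem

Magnetoencephalography (MEG) — and wearable OPM-MEG in particular —
records neural fields of a few hundred femtotesla under environmental
interference that is an order of magnitude stronger even inside a
shielded room. Subspace-projection denoisers such as signal space
projection (SSP) estimate the interference subspace from an empty-room
recording and remove its leading `x` directions from the data:

    B̂ = (I − F_x F_xᵀ) Y,

where `F_x` holds the top-`x` left singular vectors of the empty-room
matrix. The dimension `x` is the critical tuning knob: too small and
interference leaks through, too large and genuine neural signal is
projected away. In practice `x` is usually picked by eye from singular
value plots or trial-and-error waveform inspection.

`sspdim` selects `x` automatically from evoked (stimulus-locked) data.
Two objectives are computed for every candidate `x`:

* **F_B — signal preservation.** The evoked response of interest is
  quantified as trial-mean Morlet time–frequency power in a chosen
  band × time window (e.g. 9–11 Hz, 0–500 ms), baseline-corrected by the
  pre-stimulus power `N(f)`; `F_B(x)` is the ratio of this quantity after
  denoising to before. 1 means no distortion.
* **F_N — noise suppression.** The ratio of total epoch power before to
  after denoising, channel-weighted by each channel's raw standard
  deviation `w_i = σ_i / Σσ` so the noisiest channels dominate.

After min–max normalization (`F_B` to [0, 1]; `F_N` to [0, 2] and through
`tanh` so runaway noise ratios saturate), the two are combined by a
weighted sum and the optimum found by traversal of the candidate range:

    F_all(x) = α·F̃_B(x) + (1 − α)·tanh(F̃_N(x)),    x* = argmax F_all(x).

Both SSP (spatial SVD subspace) and its spectral variant S3P (subspace
from the band-averaged noise cross-spectral density, projection applied
to in-band Fourier coefficients) are implemented, and a synthetic OPM-MEG
simulator with known dipole source and interference rank provides ground
truth for validating the selection via peak error (PE), mean absolute
error (MAE) and equivalent-current-dipole localization error (LE).

## Worked example

```python
from sspdim import (simulate_dataset, bandpass_filter, estimate_threshold,
                    noise_subspace_svd, ssp_apply, AnalysisWindows)
from sspdim.evaluation import evaluate_denoised

# 31 radial sensors, 50 nA·m 10 Hz dipole burst (0–500 ms of each trial),
# rank-4 interference ~10x stronger than the evoked field, plus an
# independent empty-room recording
raw, emptyroom, truth = simulate_dataset(seed=1, n_trials=100)

ep = bandpass_filter(raw, 1.0, 40.0)
er = bandpass_filter(emptyroom, 1.0, 40.0)
win = AnalysisWindows(signal_tmin=0.0, signal_tmax=0.5,
                      baseline_tmin=-0.2, baseline_tmax=0.0,
                      fmin=9.0, fmax=11.0)
trace = estimate_threshold(ep, er, "ssp", win, range(1, 11), alpha=0.5)
print("selected x =", trace.selected)

den = ssp_apply(ep, noise_subspace_svd(er, trace.selected))
m = evaluate_denoised(den, truth, trace.selected, "ssp")
print(f"PE={m.pe:.2f} fT  MAE={m.mae:.2f} fT  LE={m.le:.2f} mm")
```

Output:

```
selected x = 4
PE=240.88 fT  MAE=82.94 fT  LE=1.17 mm
```

The sweep recovers `x = 4` — exactly the rank of the simulated
interference — and denoising at that dimension localizes the dipole to
within ~1 mm of its true position. PE/MAE are the residual distortion of
the trial-averaged waveforms at the source peaks and over the whole
epoch, in femtotesla.

The same pipeline is available from the shell:

```sh
sspdim simulate --seed 1 --n-trials 100 --out data/
sspdim run data/ --out results/ --algorithm ssp
```

which writes `report.json` (objective trace, selected threshold, metrics,
config echo and log) plus the denoised epochs. Presets for real evoked
components (`somatosensory-m35`, `auditory-m100`) set the matching
analysis windows and sweep ranges.

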