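# Methods

## Signal model and the dimension-selection problem

A measured evoked MEG dataset is modeled as `Y = B + N`: neural signal
`B` plus environmental interference `N` that is spatially low-rank —
generated by a small number of distant sources whose field topographies
at the array are fixed, with only their amplitudes varying in time. An
empty-room recording samples `N` alone. SSP takes the SVD of the
empty-room channels × time matrix; the left singular vectors `f_1 … f_n`
(ordered by singular value) are candidate interference topographies, and
removing the top `x` of them,

    B̂ = (I − F_x F_xᵀ) Y,   F_x = [f_1 … f_x],

annihilates the interference they span. The projection is applied to the
channel vector at every time sample (per trial for epoched data). S3P is
the frequency-domain analogue: the subspace is the leading eigenvectors
of the noise cross-spectral density averaged over a band, and the
projection acts only on Fourier coefficients inside that band.

Choosing `x` is a bias–variance trade: each extra dimension removes more
interference but also any neural signal component lying in it. The
estimator in this package turns that trade into an explicit two-objective
optimization evaluated on the evoked data themselves.

## Objective functions

**Signal preservation, F_B.** The true `B` is unknown, so the evoked
response is defined operationally from the time–frequency decomposition:
per channel `i`,

    S_i = | mean_{f ∈ band, t ∈ signal window} Y_i(f, t)
           − mean_{f ∈ band} N_i(f) |,

where `Y_i(f, t)` is the trial-mean squared Morlet coefficient
(induced + evoked power; magnitudes are squared before trial averaging)
and `N_i(f)` the mean of the same quantity over the pre-stimulus
baseline. `F_B = mean_i Ŝ_i / mean_i S_i` with the denoised quantities in
the numerator. Identity denoising gives exactly 1. The per-channel
scalar-summary-then-average aggregation is one of several readings of a
"multichannel absolute difference"; it was chosen because it keeps each
channel's baseline correction local to that channel.

**Noise suppression, F_N.** Because the raw data are dominated by
interference, total power stands in for noise power:
`f_N(i) = mean_k Σ_t y_{ik}(t)²` over the full epoch, and
`F_N = Σ w_i f_N(i) / Σ w_i f̂_N(i)` with weights `w_i = σ_i / Σ σ_i`
computed from the standard deviation of the *raw* band-passed epochs
(over all trials and samples, pre-denoising — the paper-silent choice
documented here; continuous-data or post-denoise σ would re-rank channels
mid-sweep). If a candidate removes all weighted power, `F_N` is reported
as +inf and handled by normalization.

**Combination.** Over the candidate range, `F_B` is min–max normalized to
[0, 1] and `F_N` to [0, 2]; the +inf sentinel maps to the top of the
range, and a degenerate all-equal objective maps every candidate to the
top of its range with a warning (neutral, keeps the sum finite). `F_N`
then passes through `tanh`, which saturates for thoroughly denoised
candidates so that late, large `F_N` gains cannot mask growing signal
distortion. The selected dimension is the smallest `x` maximizing
`F_all(x) = α F̃_B + (1−α) tanh(F̃_N)`; ties break toward smaller `x`
(less projection, less distortion risk). `α` defaults to 0.5. The sweep
is a plain traversal — candidate ranges are ≤ 10 by construction — and a
failure at an individual `x` is recorded in the trace rather than
aborting, provided at least two candidates succeed. The noise SVD (or
CSD eigendecomposition) is computed once per sweep and sliced per `x`.

## Time–frequency parameters

Morlet wavelets with `n_cycles = max(f/2, 3)` per frequency, on an
integer-Hz grid spanning the analysis band (9, 10, 11 Hz for the
simulated study). The floor of 3 cycles keeps wavelets short enough for
sub-second epochs; `f/2` gives ~2 Hz bandwidth at 10 Hz. Samples within
one Gaussian time-SD of the wavelet envelope (`σ_t = n_cycles / 2πf`,
80 ms at 9 Hz) of either epoch edge are excluded from baseline and
signal-window means, where convolution edge artifacts exceed a few
percent; a longer exclusion would consume the entire −200–0 ms baseline
at these frequencies. If the margin would empty a window entirely the
raw window is used instead (a biased estimate beats none). TF power is
recomputed per candidate `x` on the denoised epochs — wavelet power is
quadratic, so no linearity shortcut exists.

## Preprocessing

Band-pass 1–40 Hz via 4th-order Butterworth run forward and backward
(zero phase, squared magnitude response): evoked latencies are untouched
and 50/60 Hz mains lines sit ≥ 28 dB down. The identical filter is
applied to the empty-room data before subspace estimation so the
subspace describes interference in the analysis band. Epochs are closed
intervals `[tmin, tmax]` sample-aligned by rounding `tmin·srate`; the
sample at t = 0 is the stimulus sample. Bad-epoch rejection removes a
trial iff any channel's peak-to-peak amplitude exceeds the threshold
(2000 fT default, MNE-style semantics); it applies to evoked epochs
only, not to the empty-room data. In the simulated study regime the
stationary interference itself exceeds that threshold on every trial; a
peak-to-peak screen separates nothing there, so the pipeline logs the
condition and retains all trials rather than failing.

## S3P details

The cross-spectral density is estimated by Welch segmentation (1 s Hann
windows, 50% overlap) and averaged over all Fourier bins in the band —
one band-averaged spatial basis, applied per bin inside the band. The
alternative (a separate basis per bin) is defensible; the band-averaged
form was chosen because a physical interference source has one
topography across neighboring bins, and it makes S3P structurally
parallel to SSP. Complex eigenvectors are phase-rotated to minimize
their imaginary part; a residual imaginary norm above 1e-6 contributes
its own (orthonormalized) basis column. The subspace band defaults to
the full 1–40 Hz analysis band rather than the narrow signal band, so
broadband interference remains removable. Applying the projection to the
half-spectrum (rfft) coefficients and inverting keeps the output real by
construction.

## Synthetic study

The generator emulates a small wearable-MEG evoked experiment:

* **Array** — 31 radial magnetometers, golden-angle quasi-uniform on a
  10 cm-radius spherical cap (polar angle ≤ 75°); geometry written to
  `sensors.txt`.
* **Source** — current dipole 7 cm from the sphere center under the cap,
  tangential orientation, 50 nA·m peak, 10 Hz sinusoid active 0–500 ms
  of each −200–800 ms trial, 300 trials by default, identical across
  trials. Forward model: spherical-conductor radial closed form
  `B = (μ0/4π)((p × Q)·r̂)/|r − p|³`; radial moments are silent, so the
  source must be tangential. Peak evoked field ≈ 1700 fT at the best
  channel, hundreds of fT typically.
* **Interference** — rank 4 by default: four random unit spatial
  patterns (pairwise angle ≥ 30° by rejection sampling; a deterministic
  "uniform field + three gradients" preset is also provided), each
  driven by an independent Gaussian timecourse band-limited to 1–40 Hz.
  Patterns are scaled to unit mean per-channel RMS so the per-component
  amplitude (1000 fT) is an average per-channel RMS; the rank-4 total of
  ≈ 2000 fT per channel makes interference roughly ten times the evoked
  signal, the intended regime. Sensor white noise: 30 fT SD.
  Interference is spectrally flat across the analysis band by design, so
  the estimator must find the spatial dimension, not a spectral cue.
* **Empty room** — a second, independently seeded realization of the
  same interference model, never mixed with signal.
* Trial k of the measured data adds the k-th consecutive,
  non-overlapping slice of the interference realization; all generators
  are pure functions of (configuration, seed).

What this does *not* emulate: realistic cortical geometry or a
BEM/MRI-based forward model, non-stationary or impulsive artifacts,
sensor calibration errors, movement, or interference with structured
spectra (mains harmonics, trains). Passing the synthetic study shows the
estimator recovers a well-defined low-rank interference dimension under
the stated amplitude regime; it does not certify performance on
recordings whose interference violates the low-rank stationary model.

## Evaluation

All metrics operate on trial-averaged waveforms. PE averages
|B_recon − B_sim| over the extrema (maxima *and* minima — all ten
high-SNR samples of the 10 Hz burst, rather than five maxima only) of
the known source sine, then over channels; MAE averages over every
sample and channel; both in fT and linear in the error. LE fits a single
equivalent current dipole to the reconstructed average at the moment the
true signal peaks: a 1 cm coarse grid inside a 9 cm sphere, the optimal
moment at each node by linear least squares against the radial lead
field, followed by greedy hill-climbing refinement at 5 mm then 1 mm
steps; LE is the Euclidean distance to the true position in mm. The
grid-based fit is deterministic and accurate to ~the refinement step for
noiseless maps (~1 mm); distributed source imaging is out of scope since
only the simulation provides ground truth.

## Study sizes and defaults

The simulator defaults to the full 300-trial protocol. The bundled
validation study (test suite and `scripts/acceptance.py`) runs ten
independent seeds at 100 trials each — the selection behavior is
trial-count-stable well below that, and ten seeds at 100 trials
characterize the selection distribution more informatively than fewer
seeds at 300. Candidate range 1–10, α = 0.5, simulated-study analysis
windows (0–500 ms, 9–11 Hz, baseline −200–0 ms) throughout. Named
presets carry the window conventions for real somatosensory (M35:
30–50 ms, 5–15 Hz) and auditory (M100: 90–120 ms, 5–20 Hz, range 1–8)
components; these are configuration only and untested against real
recordings here.

## Numerical conventions

* SVD/eigenvector sign fixed by making each column's largest-magnitude
  entry positive.
* Projector algebra is exact to ~1e-10 by construction
  (orthonormality enforced at subspace creation).
* Data layout is channels × time everywhere; the projection is the
  left-multiplication form of the same operator however the algebra is
  written for time × channels data.
* Units: fT for fields, meters for geometry, seconds for time, nA·m for
  dipole moments; conversions only at I/O boundaries.
* Fixture I/O prints floats with `%.17g`, which round-trips float64
  bit-exactly.

### What the evoked-average metrics can and cannot show

PE and LE are computed on trial-averaged waveforms at the moments the
signal peaks. Averaging n trials shrinks any *unremoved* stationary
interference by 1/√n, while the signal loss from projecting out x
directions is deterministic and does not average away (with random
interference topographies in 31 channels, the rank-4 projection removes
≈ 12% of the signal power, i.e. ≈ 35% in amplitude at the array). As a
consequence, on synthetic data with random patterns, under-projected
reconstructions (x = 1, 2 or even x = 0) frequently score *better* PE
and LE than the true rank, even though their single-trial residual noise
is an order of magnitude worse. MAE, which integrates over the whole
epoch including the signal-free baseline, penalizes residual
interference reliably: at the true rank it beats both no projection and
near-total projection on every tested seed. This is exactly why the
selection objective evaluates single-trial power (F_N) rather than
average-waveform error — the quantity that matters for induced-response,
connectivity or single-trial analyses — and it bounds what evoked-average
metrics can certify about a denoiser.

## Known limitations

* The normalization of F_B/F_N is relative to the swept range: traces
  from different sweeps (or algorithms) are not directly comparable in
  absolute `F_all` value.
* `α` and the candidate range remain user choices; the method is
  semi-automatic in that sense.
* S3P as implemented follows one reading of a sparsely documented
  method (band-averaged basis, per-bin application); other readings
  exist.
* The ECD localizer assumes the spherical radial model of the
  simulator; applying it to real-helmet data would require the true
  sensor geometry and a matching forward model.
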