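"""Objective functions and automatic interference-dimension selection.

The dimension x of the interference subspace trades off noise removal
against distortion of the evoked signal.  Two objectives quantify the
trade:

* F_B — signal-preservation ratio.  The evoked signal is defined from the
  trial-averaged Morlet time–frequency power in a band x time window of
  interest, baseline-corrected by the pre-stimulus power; F_B is the
  ratio of that quantity after denoising to before (1 = no distortion,
  0 = signal destroyed).
* F_N — noise-suppression ratio.  Total epoch power before over after
  denoising, weighted per channel by the channel's raw standard deviation
  so noisy channels dominate (1 = nothing removed, large = strong
  suppression).

Both are evaluated for every candidate x; after min–max normalization
(F_B to [0, 1], F_N to [0, 2] then through tanh to damp runaway noise
ratios) they are combined by a weighted sum

    F_all(x) = alpha * F_B_norm(x) + (1 - alpha) * tanh(F_N_norm(x))

and the x maximizing F_all is selected (smallest x on ties).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .data_model import AnalysisWindows, ContinuousRecording, EpochedRecording
from .projection import (
    InterferenceSubspace,
    _fix_signs,
    _realify,
    _welch_csd,
    s3p_apply,
    ssp_apply,
)

logger = logging.getLogger("sspdim")

__all__ = [
    "TFPower",
    "BaselinePower",
    "ObjectiveTrace",
    "morlet_n_cycles",
    "tf_power",
    "baseline_power",
    "distortion_objective",
    "channel_weights",
    "noise_objective",
    "estimate_threshold",
]


# ---------------------------------------------------------------------------
# Time-frequency power
# ---------------------------------------------------------------------------

@dataclass
class TFPower:
    """Trial-mean Morlet power: channels x frequencies x time, fT^2."""

    power: np.ndarray
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s
    n_trials: int
    n_cycles: np.ndarray = field(default=None)  # per frequency

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape[1:] != (self.freqs.size, self.times.size):
            raise ValueError("power axes inconsistent with freqs/times")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.n_cycles is None:
            self.n_cycles = np.array([morlet_n_cycles(f) for f in self.freqs])


@dataclass
class BaselinePower:
    """Pre-stimulus mean power per channel and frequency, fT^2."""

    power: np.ndarray  # channels x frequencies
    baseline: tuple[float, float]  # s

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def morlet_n_cycles(freq: float) -> float:
    """Cycles per wavelet: f/2, floored at 3 (short enough for brief epochs,
    long enough for ~2 Hz spectral resolution at 10 Hz)."""
    return max(freq / 2.0, 3.0)


def _edge_margin_s(freq: float, n_cycles: float) -> float:
    # one Gaussian time-SD of the wavelet envelope; samples closer than
    # this to an epoch edge carry substantial convolution edge artifact
    return n_cycles / (2.0 * np.pi * freq)


def tf_power(ep: EpochedRecording, freqs: Sequence[float]) -> TFPower:
    """Trial-mean squared Morlet coefficients per channel/frequency/time.

    This is induced + evoked power: the wavelet transform is applied per
    trial and magnitudes are squared *before* averaging over trials.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= ep.srate / 2):
        raise ValueError(f"freqs must lie in (0, {ep.srate / 2}) Hz")
    if ep.n_trials < 1:
        raise ValueError("need at least one trial")
    n_cycles = np.array([morlet_n_cycles(f) for f in freqs])
    epoch_len = ep.n_times / ep.srate
    # mne builds wavelets spanning 5 SD of the Gaussian envelope per side
    wavelet_len = 10.0 * n_cycles / (2.0 * np.pi * freqs)
    if np.any(wavelet_len > epoch_len):
        fbad = freqs[np.argmax(wavelet_len)]
        raise ValueError(
            f"epoch of {epoch_len:.3f} s is shorter than the "
            f"{wavelet_len.max():.3f} s wavelet at {fbad:g} Hz; "
            f"need epochs of at least {wavelet_len.max():.3f} s"
        )
    # mne wants (n_epochs, n_channels, n_times)
    arr = np.transpose(ep.data, (1, 0, 2))
    power = tfr_array_morlet(
        arr, sfreq=ep.srate, freqs=freqs, n_cycles=n_cycles,
        output="avg_power", zero_mean=True, verbose="error",
    )
    return TFPower(
        power=power, freqs=freqs, times=ep.times.copy(),
        n_trials=ep.n_trials, n_cycles=n_cycles,
    )


def _valid_window_mask(
    tfp: TFPower, f_index: int, tmin: float, tmax: float
) -> np.ndarray:
    """Samples of [tmin, tmax] far enough from the epoch edges at this
    frequency for the wavelet estimate to be trusted."""
    margin = _edge_margin_s(tfp.freqs[f_index], tfp.n_cycles[f_index])
    t = tfp.times
    eps = 0.5 / max(1.0, 1.0 / (t[1] - t[0])) if t.size > 1 else 0.0
    window = (t >= tmin - eps) & (t <= tmax + eps)
    interior = (t >= t[0] + margin) & (t <= t[-1] - margin)
    mask = window & interior
    # degrade gracefully: if the margin swallows the whole window, fall
    # back to the raw window (better a biased estimate than none)
    return mask if mask.any() else window


def baseline_power(
    tfp: TFPower, baseline_tmin: float, baseline_tmax: float
) -> BaselinePower:
    """Mean power over the pre-stimulus window, per channel and frequency."""
    if baseline_tmax > 0:
        raise ValueError("baseline must end at or before t=0")
    out = np.empty((tfp.power.shape[0], tfp.freqs.size))
    for j in range(tfp.freqs.size):
        mask = _valid_window_mask(tfp, j, baseline_tmin, baseline_tmax)
        if not mask.any():
            raise ValueError(
                f"baseline window [{baseline_tmin}, {baseline_tmax}] s "
                "contains no samples of the epoch"
            )
        out[:, j] = tfp.power[:, j, mask].mean(axis=1)
    return BaselinePower(power=out, baseline=(baseline_tmin, baseline_tmax))


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def _evoked_band_power(
    tfp: TFPower, base: BaselinePower, win: AnalysisWindows
) -> np.ndarray:
    """Per-channel signed evoked power: band x signal-window mean of the TF
    power minus the band-mean baseline power."""
    fsel = np.flatnonzero((tfp.freqs >= win.fmin) & (tfp.freqs <= win.fmax))
    if fsel.size == 0:
        raise ValueError(
            f"band [{win.fmin}, {win.fmax}] Hz outside the computed "
            f"frequency grid {tfp.freqs}"
        )
    per_freq = np.empty((tfp.power.shape[0], fsel.size))
    for i, j in enumerate(fsel):
        mask = _valid_window_mask(tfp, j, win.signal_tmin, win.signal_tmax)
        per_freq[:, i] = tfp.power[:, j, mask].mean(axis=1)
    return per_freq.mean(axis=1) - base.power[:, fsel].mean(axis=1)


def distortion_objective(
    tf_raw: TFPower,
    base_raw: BaselinePower,
    tf_den: TFPower,
    base_den: BaselinePower,
    win: AnalysisWindows,
) -> float:
    """Signal-preservation ratio F_B.

    Per channel i, S_i = |evoked band power| (signal-window TF power minus
    band-mean baseline); F_B = mean_i(S_i denoised) / mean_i(S_i raw).
    Identity denoising gives exactly 1; removing the signal gives 0.
    """
    if not np.array_equal(tf_raw.freqs, tf_den.freqs) or not np.array_equal(
        tf_raw.times, tf_den.times
    ):
        raise ValueError("raw and denoised TF power must share freqs/times")
    s_raw = np.abs(_evoked_band_power(tf_raw, base_raw, win))
    s_den = np.abs(_evoked_band_power(tf_den, base_den, win))
    denom = s_raw.mean()
    if denom == 0:
        raise ValueError(
            "no evoked power in the selected time-frequency window; "
            "cannot form the distortion ratio"
        )
    return float(s_den.mean() / denom)


def channel_weights(ep: EpochedRecording) -> np.ndarray:
    """Noise-level channel weights w_i = sigma_i / sum(sigma).

    sigma_i is the standard deviation of channel i over all trials and
    samples of the raw band-passed epochs; channels dominated by
    interference receive proportionally larger weight.  Scale-invariant.
    """
    sigma = ep.data.reshape(ep.n_channels, -1).std(axis=1)
    total = sigma.sum()
    if total == 0:
        raise ValueError("all channels are identically zero; weights undefined")
    return sigma / total


def noise_objective(
    raw: EpochedRecording, den: EpochedRecording, weights: np.ndarray
) -> float:
    """Noise-suppression ratio F_N.

    f_N(i) = trial-mean total power of channel i over the full epoch;
    F_N = sum_i w_i f_N(i) raw / sum_i w_i f_N(i) denoised.  Identity
    denoising gives 1; the more power removed, the larger F_N.  If the
    denoiser removes everything the ratio is reported as +inf and handled
    by the normalization step.
    """
    if raw.data.shape != den.data.shape:
        raise ValueError("raw and denoised epochs must have the same shape")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (raw.n_channels,):
        raise ValueError("one weight per channel required")

    def _f_n(ep: EpochedRecording) -> np.ndarray:
        return (ep.data**2).sum(axis=2).mean(axis=1)  # per channel

    num = float(weights @ _f_n(raw))
    den_val = float(weights @ _f_n(den))
    if den_val == 0:
        return float("inf")
    return num / den_val


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveTrace:
    """Per-threshold objective values and the selected optimum."""

    thresholds: list[int]
    FB_raw: list[float]
    FN_raw: list[float]
    FB_norm: list[float]
    FN_norm: list[float]
    Fall: list[float]
    alpha: float
    selected: int
    weights: np.ndarray
    algorithm: str
    failures: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "thresholds": list(self.thresholds),
            "FB_raw": list(self.FB_raw),
            "FN_raw": [v if np.isfinite(v) else "inf" for v in self.FN_raw],
            "FB_norm": list(self.FB_norm),
            "FN_norm": list(self.FN_norm),
            "Fall": list(self.Fall),
            "alpha": self.alpha,
            "selected": self.selected,
            "weights": np.asarray(self.weights).tolist(),
            "algorithm": self.algorithm,
            "failures": {str(k): v for k, v in self.failures.items()},
        }

    def to_table(self) -> str:
        """Columnar text: x, F_B, F_N, F_all (one row per threshold)."""
        lines = ["x\tFB_raw\tFN_raw\tFall"]
        for x, fb, fn, fa in zip(self.thresholds, self.FB_raw, self.FN_raw, self.Fall):
            lines.append(f"{x}\t{fb:.6g}\t{fn:.6g}\t{fa:.6g}")
        lines.append(f"# selected x = {self.selected}")
        return "\n".join(lines) + "\n"


def _minmax(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Min-max normalize finite values to [lo, hi]; +inf maps to hi.

    Degenerate all-equal input maps everything to hi (neutral: keeps the
    combined objective finite and the sweep well-defined) with a warning.
    """
    out = np.full(values.shape, hi, dtype=float)
    finite = np.isfinite(values)
    v = values[finite]
    if v.size == 0:
        return out
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        warnings.warn(
            "objective constant across thresholds; normalization degenerate "
            "(all values mapped to the top of the range)",
            RuntimeWarning,
        )
        return out
    out[finite] = lo + (hi - lo) * (v - vmin) / (vmax - vmin)
    return out


def _band_freq_grid(win: AnalysisWindows) -> np.ndarray:
    """Integer-Hz frequency grid spanning the analysis band."""
    lo = int(np.ceil(win.fmin - 1e-9))
    hi = int(np.floor(win.fmax + 1e-9))
    if hi < lo:
        return np.array([0.5 * (win.fmin + win.fmax)])
    return np.arange(lo, hi + 1, dtype=float)


def estimate_threshold(
    ep: EpochedRecording,
    noise: ContinuousRecording,
    algorithm: str,
    win: AnalysisWindows,
    x_range: Sequence[int],
    alpha: float = 0.5,
    s3p_band: tuple[float, float] | None = None,
) -> ObjectiveTrace:
    """Sweep candidate interference dimensions and pick the optimum.

    For every x in ``x_range`` the interference subspace is built from the
    empty-room recording, the epochs are denoised, and F_B(x) / F_N(x)
    are evaluated; after normalization the weighted sum F_all is maximized
    (simple traversal — the range is small by design).  Failures at
    individual x values are recorded in the trace rather than aborting, as
    long as at least two thresholds succeed.

    ``ep`` and ``noise`` are expected to be band-pass filtered identically
    beforehand (the pipeline in :mod:`sspdim.cli` does this).  For S3P the
    subspace band defaults to 1–40 Hz, the standard analysis band.
    """
    x_range = [int(x) for x in x_range]
    if not x_range:
        raise ValueError("x_range must be non-empty")
    if max(x_range) > ep.n_channels:
        raise ValueError("x_range exceeds the number of channels")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if algorithm not in ("ssp", "s3p"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if s3p_band is None:
        s3p_band = (1.0, 40.0)

    freqs = _band_freq_grid(win)
    weights = channel_weights(ep)
    tf_raw = tf_power(ep, freqs)
    base_raw = baseline_power(tf_raw, win.baseline_tmin, win.baseline_tmax)

    # one decomposition for the whole sweep, sliced per x
    if algorithm == "ssp":
        u, svals, _ = np.linalg.svd(noise.data, full_matrices=False)
        u = _fix_signs(u)

        def make_sub(x: int) -> InterferenceSubspace:
            basis = u[:, :x] if x > 0 else np.empty((noise.n_channels, 0))
            return InterferenceSubspace(
                basis=basis, singular_values=svals, x=x, algorithm="ssp"
            )

        apply_fn = ssp_apply
    else:
        csd, _ = _welch_csd(noise, s3p_band)
        evals, evecs = np.linalg.eigh(csd)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order].real, 0.0)
        evecs = evecs[:, order]

        def make_sub(x: int) -> InterferenceSubspace:
            basis = _realify(evecs[:, :x], x) if x > 0 else np.empty((noise.n_channels, 0))
            return InterferenceSubspace(
                basis=basis, singular_values=evals, x=basis.shape[1],
                algorithm="s3p", band=s3p_band,
            )

        apply_fn = s3p_apply

    fb_raw, fn_raw, failures = [], [], {}
    for x in x_range:
        try:
            sub = make_sub(x)
            den = apply_fn(ep, sub)
            tf_den = tf_power(den, freqs)
            base_den = baseline_power(tf_den, win.baseline_tmin, win.baseline_tmax)
            fb = distortion_objective(tf_raw, base_raw, tf_den, base_den, win)
            fn = noise_objective(ep, den, weights)
        except Exception as exc:  # record and continue the sweep
            failures[x] = f"{type(exc).__name__}: {exc}"
            fb, fn = float("nan"), float("nan")
            logger.warning("threshold x=%d failed: %s", x, failures[x])
        fb_raw.append(fb)
        fn_raw.append(fn)
    n_ok = sum(1 for v in fb_raw if not np.isnan(v))
    if n_ok < min(2, len(x_range)):
        raise RuntimeError(
            f"threshold sweep failed at {len(failures)}/{len(x_range)} "
            f"candidates: {failures}"
        )

    fb_arr = np.array(fb_raw)
    fn_arr = np.array(fn_raw)
    ok = ~np.isnan(fb_arr)
    fb_norm = np.full(fb_arr.shape, np.nan)
    fn_norm = np.full(fn_arr.shape, np.nan)
    fb_norm[ok] = _minmax(fb_arr[ok], 0.0, 1.0)
    fn_norm[ok] = _minmax(fn_arr[ok], 0.0, 2.0)
    fall = alpha * fb_norm + (1.0 - alpha) * np.tanh(fn_norm)
    # smallest x achieving the maximum (ties favor less projection)
    best = np.nanmax(fall)
    selected = min(
        x for x, f in zip(x_range, fall) if not np.isnan(f) and f >= best - 1e-15
    )
    return ObjectiveTrace(
        thresholds=x_range,
        FB_raw=[float(v) for v in fb_arr],
        FN_raw=[float(v) for v in fn_arr],
        FB_norm=[float(v) for v in fb_norm],
        FN_norm=[float(v) for v in fn_norm],
        Fall=[float(v) for v in fall],
        alpha=float(alpha),
        selected=int(selected),
        weights=weights,
        algorithm=algorithm,
        failures=failures,
    )
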