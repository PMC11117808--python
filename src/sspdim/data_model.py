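"""Core containers, preprocessing and I/O for evoked MEG recordings.

Field data are held in femtotesla (fT), geometry in meters, time in
seconds throughout; conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger("sspdim")

__all__ = [
    "SensorArray",
    "ContinuousRecording",
    "EpochedRecording",
    "AnalysisWindows",
    "RejectionReport",
    "bandpass_filter",
    "epoch",
    "reject_bad_epochs",
    "evoked_average",
    "read_recording",
    "write_recording",
    "read_sensors",
    "write_sensors",
    "write_report",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SensorArray:
    """Positions and sensitive axes of a magnetometer array.

    Positions are head-centered Cartesian coordinates in meters;
    orientations are unit vectors along each sensor's sensitive axis
    (radial for the simulated array).
    """

    channel_ids: list[str]
    positions: np.ndarray  # (n_channels, 3), m
    orientations: np.ndarray  # (n_channels, 3), unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = len(self.channel_ids)
        if len(set(self.channel_ids)) != n:
            raise ValueError("channel_ids must be unique")
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValueError("positions/orientations must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")
        radii = np.linalg.norm(self.positions, axis=1)
        if np.any(radii <= 0):
            raise ValueError("sensor positions must be nonzero")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientation vectors must have unit norm")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)


@dataclass
class ContinuousRecording:
    """A channels x time matrix of field values in fT."""

    data: np.ndarray  # (n_channels, n_times), fT
    srate: float  # Hz
    channel_ids: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be 2-D (channels x time)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_ids)} channel_ids"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, **prov: Any) -> "ContinuousRecording":
        return ContinuousRecording(
            data=data, srate=self.srate, channel_ids=list(self.channel_ids),
            provenance={**self.provenance, **prov},
        )


@dataclass
class EpochedRecording:
    """Stimulus-locked trials: channels x trials x time, field in fT.

    ``times`` is the event-relative axis in seconds; the sample at t=0 is
    the stimulus sample.
    """

    data: np.ndarray  # (n_channels, n_trials, n_times), fT
    srate: float
    times: np.ndarray  # (n_times,), s
    channel_ids: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be 3-D (channels x trials x time)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        dt = np.diff(self.times)
        if self.times.size > 1:
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.srate) > 1e-6 / self.srate):
                raise ValueError("times must be uniformly spaced at 1/srate")
        if not (self.times[0] <= 0.0 <= self.times[-1] + 1e-12):
            raise ValueError("epoch must contain t=0 or a baseline ending at 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy_with(self, data: np.ndarray, **prov: Any) -> "EpochedRecording":
        return EpochedRecording(
            data=data, srate=self.srate, times=self.times.copy(),
            channel_ids=list(self.channel_ids),
            provenance={**self.provenance, **prov},
        )


@dataclass(frozen=True)
class AnalysisWindows:
    """Time segments and frequency band of interest for the objectives.

    The signal window holds the evoked component (e.g. 0–500 ms for the
    simulated burst); the baseline window is pre-stimulus and must end at
    or before t=0.
    """

    signal_tmin: float
    signal_tmax: float
    baseline_tmin: float
    baseline_tmax: float
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        if not (self.baseline_tmax <= 0.0 <= self.signal_tmin < self.signal_tmax):
            raise ValueError(
                "require baseline_tmax <= 0 <= signal_tmin < signal_tmax"
            )
        if self.baseline_tmin >= self.baseline_tmax:
            raise ValueError("baseline window must be non-empty")
        if not (0.0 < self.fmin < self.fmax):
            raise ValueError("require 0 < fmin < fmax")


@dataclass
class RejectionReport:
    """Outcome of peak-to-peak bad-epoch rejection."""

    threshold: float  # fT
    n_original: int
    removed_trials: list[int]
    offending_channels: dict[int, list[str]]  # trial index -> channel ids

    @property
    def n_kept(self) -> int:
        return self.n_original - len(self.removed_trials)

    def to_dict(self) -> dict[str, Any]:
        return {
            "threshold_ft": self.threshold,
            "n_original": self.n_original,
            "n_kept": self.n_kept,
            "removed_trials": list(self.removed_trials),
            "offending_channels": {
                str(k): v for k, v in self.offending_channels.items()
            },
        }


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _design_bandpass(low: float, high: float, srate: float) -> np.ndarray:
    nyq = srate / 2.0
    if not (0.0 < low < high):
        raise ValueError(f"require 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(
            f"band edge {high} Hz is at or above Nyquist ({nyq} Hz) "
            f"for srate={srate} Hz"
        )
    return signal.butter(4, [low, high], btype="bandpass", fs=srate, output="sos")


def bandpass_filter(rec, low: float, high: float):
    """Zero-phase Butterworth band-pass, applied per channel.

    A 4th-order design is run forward and backward (``sosfiltfilt``), so
    the effective magnitude response is the square of the single-pass
    response and the phase is zero — evoked latencies are preserved.
    Works on both continuous and epoched recordings; shape is preserved.
    """
    sos = _design_bandpass(low, high, rec.srate)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(np.ascontiguousarray(filtered), bandpass=(low, high))


def epoch(
    rec: ContinuousRecording,
    onsets: Sequence[int],
    tmin: float,
    tmax: float,
) -> EpochedRecording:
    """Cut stimulus-locked epochs out of a continuous recording.

    ``onsets`` are stimulus sample indices.  The epoch time axis is the
    closed interval [tmin, tmax], sample-aligned by rounding
    ``tmin * srate`` to the nearest integer.  Trials whose window falls
    outside the recording are dropped (with a logged count), not an error.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    n0 = int(round(tmin * rec.srate))
    n1 = int(round(tmax * rec.srate))
    times = np.arange(n0, n1 + 1) / rec.srate
    trials = []
    n_dropped = 0
    for onset in onsets:
        start, stop = onset + n0, onset + n1 + 1
        if start < 0 or stop > rec.n_times:
            n_dropped += 1
            continue
        trials.append(rec.data[:, start:stop])
    if n_dropped:
        logger.info(
            "epoch: dropped %d/%d trials outside the recording bounds",
            n_dropped, len(onsets),
        )
    if not trials:
        raise ValueError("no epoch window fits inside the recording")
    data = np.stack(trials, axis=1)  # channels x trials x time
    return EpochedRecording(
        data=data, srate=rec.srate, times=times,
        channel_ids=list(rec.channel_ids),
        provenance={**rec.provenance, "n_dropped_out_of_bounds": n_dropped},
    )


def reject_bad_epochs(
    ep: EpochedRecording, threshold: float
) -> tuple[EpochedRecording, RejectionReport]:
    """Drop trials whose per-channel peak-to-peak amplitude exceeds ``threshold``.

    A trial is removed iff any channel's max-minus-min within the epoch
    exceeds the threshold (in fT).  Returns the cleaned recording and a
    report listing removed trials with their offending channels.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    p2p = ep.data.max(axis=2) - ep.data.min(axis=2)  # channels x trials
    bad = p2p > threshold
    removed = np.flatnonzero(bad.any(axis=0))
    offending = {
        int(k): [ep.channel_ids[c] for c in np.flatnonzero(bad[:, k])]
        for k in removed
    }
    if removed.size == ep.n_trials:
        raise ValueError(
            f"all {ep.n_trials} trials exceed the {threshold} fT rejection "
            "threshold; trial averaging is undefined"
        )
    keep = np.setdiff1d(np.arange(ep.n_trials), removed)
    report = RejectionReport(
        threshold=float(threshold),
        n_original=ep.n_trials,
        removed_trials=[int(k) for k in removed],
        offending_channels=offending,
    )
    if removed.size:
        logger.info(
            "reject_bad_epochs: removed %d/%d trials above %g fT",
            removed.size, ep.n_trials, threshold,
        )
    out = ep.copy_with(ep.data[:, keep, :], rejection=report.to_dict())
    return out, report


def evoked_average(ep: EpochedRecording) -> np.ndarray:
    """Trial-averaged waveforms, channels x time."""
    return ep.data.mean(axis=1)


# ---------------------------------------------------------------------------
# I/O — plain-text fixture format and JSON reports
# ---------------------------------------------------------------------------
#
# Fixture format: UTF-8 text, header lines
#   # srate_hz=<float>
#   # channels=<comma-separated ids>
#   # times_s=<comma-separated floats>     (epoched trials only)
# followed by one whitespace-separated row of fT values per channel.
# Epoched fixtures are directories of per-trial files trial_<k>.txt plus
# sensors.txt with `id x y z ox oy oz` per line (meters).

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _parse_header(lines: list[str], path: Path) -> dict[str, str]:
    header: dict[str, str] = {}
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        m = re.match(r"#\s*(\w+)\s*=\s*(.*)\s*$", line)
        if m is None:
            raise ValueError(f"{path}: malformed header at line {i + 1}: {line!r}")
        header[m.group(1)] = m.group(2)
    if "srate_hz" not in header or "channels" not in header:
        raise ValueError(f"{path}: header must define srate_hz and channels")
    return header


def _read_fixture_file(path: Path) -> tuple[np.ndarray, float, list[str], np.ndarray | None]:
    lines = path.read_text().splitlines()
    header = _parse_header(lines, path)
    srate = float(header["srate_hz"])
    channel_ids = [c.strip() for c in header["channels"].split(",")]
    times = None
    if "times_s" in header:
        times = np.array([float(v) for v in header["times_s"].split(",")])
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if len(body) != len(channel_ids):
        raise ValueError(
            f"{path}: header lists {len(channel_ids)} channels but the body "
            f"has {len(body)} data rows"
        )
    data = np.array([[float(v) for v in ln.split()] for ln in body])
    return data, srate, channel_ids, times


def _write_fixture_file(
    path: Path,
    data: np.ndarray,
    srate: float,
    channel_ids: list[str],
    times: np.ndarray | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# srate_hz={_FLOAT_FMT % srate}\n")
        fh.write(f"# channels={','.join(channel_ids)}\n")
        if times is not None:
            fh.write("# times_s=" + ",".join(_FLOAT_FMT % t for t in times) + "\n")
        for row in data:
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")


def read_sensors(path: str | Path) -> SensorArray:
    """Read a ``sensors.txt`` geometry table (id x y z ox oy oz, meters)."""
    path = Path(path)
    ids, pos, ori = [], [], []
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}: line {i + 1} needs 7 fields, got {len(parts)}")
        ids.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
        ori.append([float(v) for v in parts[4:7]])
    return SensorArray(channel_ids=ids, positions=np.array(pos), orientations=np.array(ori))


def write_sensors(path: str | Path, sensors: SensorArray) -> None:
    with open(path, "w") as fh:
        for cid, p, o in zip(sensors.channel_ids, sensors.positions, sensors.orientations):
            fields = [cid] + [_FLOAT_FMT % v for v in (*p, *o)]
            fh.write(" ".join(fields) + "\n")


def read_recording(path: str | Path, format: str = "fixture"):
    """Read a continuous or epoched recording.

    ``format='fixture'`` reads the plain-text format above: a single file
    is a continuous recording; a directory of ``trial_<k>.txt`` files is
    an epoched recording.  ``format='fif'`` delegates to the standard MEG
    reader (optional convenience; never required by the fixture pipeline).
    """
    path = Path(path)
    if format == "fif":
        import mne

        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        picks = mne.pick_types(raw.info, meg=True)
        data = raw.get_data(picks=picks) * 1e15  # T -> fT
        ids = [raw.ch_names[p] for p in picks]
        return ContinuousRecording(data=data, srate=float(raw.info["sfreq"]), channel_ids=ids)
    if format != "fixture":
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    if path.is_dir():
        trial_files = sorted(
            path.glob("trial_*.txt"),
            key=lambda p: int(re.search(r"trial_(\d+)", p.name).group(1)),
        )
        if not trial_files:
            raise ValueError(f"{path}: no trial_<k>.txt files found")
        mats, srate, ids, times = [], None, None, None
        for tf in trial_files:
            data, s, cids, t = _read_fixture_file(tf)
            if srate is None:
                srate, ids, times = s, cids, t
            elif s != srate or cids != ids:
                raise ValueError(f"{tf}: header inconsistent with other trials")
            mats.append(data)
        data = np.stack(mats, axis=1)
        if times is None:
            times = np.arange(data.shape[2]) / srate - 0.0
        return EpochedRecording(data=data, srate=srate, times=times, channel_ids=ids)
    data, srate, ids, _times = _read_fixture_file(path)
    return ContinuousRecording(data=data, srate=srate, channel_ids=ids)


def write_recording(path: str | Path, rec) -> None:
    """Write a recording in the fixture format (inverse of ``read_recording``)."""
    path = Path(path)
    if isinstance(rec, ContinuousRecording):
        _write_fixture_file(path, rec.data, rec.srate, rec.channel_ids)
    elif isinstance(rec, EpochedRecording):
        path.mkdir(parents=True, exist_ok=True)
        for k in range(rec.n_trials):
            _write_fixture_file(
                path / f"trial_{k:03d}.txt", rec.data[:, k, :], rec.srate,
                rec.channel_ids, times=rec.times,
            )
    else:
        raise TypeError(f"cannot write object of type {type(rec).__name__}")


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report(path: str | Path, report: dict[str, Any]) -> None:
    """Serialize an analysis report to JSON (keys sorted, deterministic)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_NumpyJSONEncoder)
        fh.write("\n")
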