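"""Synthetic OPM-MEG evoked data with ground truth.

Emulates a small wearable-MEG evoked experiment: a sinusoidal current
dipole burst (50 nA*m, 10 Hz, active 0-500 ms of each 1 s trial, 300
trials) measured by ~31 radial magnetometers on a spherical cap, buried
under low-rank spatially-correlated environmental interference whose
amplitude greatly exceeds the evoked field, plus independent sensor white
noise.  A second, statistically matched interference realization serves
as the empty-room recording from which the denoiser estimates its
subspace.  The interference rank is the recoverable ground truth.

The forward model is the spherical-conductor radial-magnetometer closed
form: B(r) = (mu0 / 4 pi) * ((p x Q) . r_hat) / |r - p|^3, which is what
a radially oriented magnetometer over a spherically symmetric conductor
measures from a dipole Q at p.  Radial dipoles are magnetically silent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import signal as sp_signal

from .data_model import ContinuousRecording, EpochedRecording, SensorArray

logger = logging.getLogger("sspdim")

__all__ = [
    "DipoleSource",
    "InterferenceModel",
    "SimulationTruth",
    "cap_sensor_array",
    "default_dipole",
    "radial_lead_field",
    "simulate_evoked",
    "uniform_plus_gradient_patterns",
    "random_patterns",
    "simulate_interference",
    "assemble_dataset",
    "simulate_dataset",
    "write_truth",
    "read_truth",
]

_MU0_OVER_4PI = 1e-7  # T*m/A
_SENSOR_RADIUS_M = 0.10


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def cap_sensor_array(
    n: int = 31,
    radius: float = _SENSOR_RADIUS_M,
    max_polar_deg: float = 75.0,
) -> SensorArray:
    """Quasi-uniform radial magnetometer layout on a spherical cap.

    Channels are spread over the cap by a golden-angle spiral (uniform in
    cos(polar angle)); orientations are radial, pointing outward.  Stands
    in for a rigid-helmet layout over one hemisphere.
    """
    if n < 1:
        raise ValueError("need at least one sensor")
    zmin = np.cos(np.deg2rad(max_polar_deg))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    z = 1.0 - (1.0 - zmin) * (k + 0.5) / n
    phi = k * golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    units = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    positions = radius * units
    ids = [f"MEG{i + 1:03d}" for i in range(n)]
    return SensorArray(channel_ids=ids, positions=positions, orientations=units)


@dataclass
class DipoleSource:
    """A sinusoidal-burst current dipole.

    The moment direction must have a nonzero tangential component — a
    purely radial dipole in a spherical conductor produces no external
    field and would be invisible to the array.
    """

    position: np.ndarray  # (3,), m, inside the sensor sphere
    moment_direction: np.ndarray  # (3,), unit
    peak_moment: float = 50.0  # nA*m
    frequency: float = 10.0  # Hz
    active_tmin: float = 0.0  # s
    active_tmax: float = 0.5  # s
    n_trials: int = 300

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.moment_direction = np.asarray(self.moment_direction, dtype=float)
        nrm = np.linalg.norm(self.moment_direction)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError("moment_direction must be a unit vector")
        if np.linalg.norm(self.position) >= _SENSOR_RADIUS_M:
            raise ValueError("source must lie strictly inside the sensor sphere")
        if self.active_tmin >= self.active_tmax:
            raise ValueError("active window must be non-empty")

    def to_dict(self) -> dict[str, Any]:
        return {
            "position_m": self.position.tolist(),
            "moment_direction": self.moment_direction.tolist(),
            "peak_moment_nam": self.peak_moment,
            "frequency_hz": self.frequency,
            "active_window_s": [self.active_tmin, self.active_tmax],
            "n_trials": self.n_trials,
        }


def default_dipole(n_trials: int = 300) -> DipoleSource:
    """The standard simulated source: 7 cm from center under the cap,
    tangentially oriented, 50 nA*m at 10 Hz, active 0-500 ms."""
    u = np.array([0.3, 0.1, 0.95])
    u /= np.linalg.norm(u)
    position = 0.07 * u
    tangent = np.cross(u, [0.0, 0.0, 1.0])
    tangent /= np.linalg.norm(tangent)
    return DipoleSource(position=position, moment_direction=tangent, n_trials=n_trials)


def radial_lead_field(
    sensors: SensorArray, pos: np.ndarray, moment: np.ndarray
) -> np.ndarray:
    """Field (fT) at each radial sensor from a dipole ``moment`` (nA*m) at ``pos``.

    B_i = (mu0/4pi) * ((pos x Q) . r_hat_i) / |r_i - pos|^3, linear in Q;
    a dipole parallel to its own position vector gives zero everywhere.
    """
    pos = np.asarray(pos, dtype=float)
    q_si = np.asarray(moment, dtype=float) * 1e-9  # nA*m -> A*m
    diff = sensors.positions - pos[None, :]
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist < 1e-4):
        raise ValueError("source coincides with a sensor position")
    r_hat = sensors.orientations  # radial sensitive axes
    cross = np.cross(pos, q_si)
    b_tesla = _MU0_OVER_4PI * (r_hat @ cross) / dist**3
    return b_tesla * 1e15  # -> fT


# ---------------------------------------------------------------------------
# Evoked signal
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    b_sim: np.ndarray  # clean sensor epochs, channels x trials x time, fT
    times: np.ndarray  # s, epoch axis
    srate: float
    dipole: DipoleSource
    interference_rank: int
    seed: int | None
    sensors: SensorArray
    meta: dict[str, Any] = field(default_factory=dict)

    def evoked_average(self) -> np.ndarray:
        return self.b_sim.mean(axis=1)


def simulate_evoked(
    sensors: SensorArray,
    src: DipoleSource,
    srate: float = 1000.0,
    window: tuple[float, float] = (-0.2, 0.8),
    seed: int | None = None,
) -> SimulationTruth:
    """Noise-free sensor-space epochs from a sinusoidal dipole burst.

    The moment waveform is peak_moment * sin(2 pi f t) inside the active
    window and zero outside, identical on every trial (the generator is
    deterministic; ``seed`` is recorded for provenance only).
    """
    if src.frequency >= srate / 2:
        raise ValueError("source frequency must be below Nyquist")
    tmin, tmax = window
    if not (tmin <= src.active_tmin < src.active_tmax <= tmax):
        raise ValueError("active window must lie inside the epoch window")
    n0, n1 = int(round(tmin * srate)), int(round(tmax * srate))
    times = np.arange(n0, n1 + 1) / srate
    waveform = np.zeros_like(times)
    active = (times >= src.active_tmin) & (times < src.active_tmax)
    waveform[active] = src.peak_moment * np.sin(
        2 * np.pi * src.frequency * (times[active] - src.active_tmin)
    )
    pattern = radial_lead_field(sensors, src.position, src.moment_direction)
    single = pattern[:, None] * waveform[None, :]  # channels x time
    b_sim = np.repeat(single[:, None, :], src.n_trials, axis=1)
    return SimulationTruth(
        b_sim=b_sim, times=times, srate=srate, dipole=src,
        interference_rank=0, seed=seed, sensors=sensors,
    )


# ---------------------------------------------------------------------------
# Interference
# ---------------------------------------------------------------------------

@dataclass
class InterferenceModel:
    """Low-rank spatially correlated environmental interference.

    Each of ``rank`` spatial patterns is driven by an independent
    band-limited Gaussian timecourse.  Patterns are scaled to unit mean
    per-channel RMS, so ``component_rms`` is the average per-channel RMS
    contribution of one component in fT.  Independent white sensor noise
    of SD ``sensor_noise_sd`` is added on top.
    """

    rank: int = 4
    spatial_patterns: np.ndarray | None = None  # channels x rank
    component_rms: float = 1000.0  # fT, per-channel average
    band: tuple[float, float] = (1.0, 40.0)  # Hz
    sensor_noise_sd: float = 30.0  # fT

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError("rank must be non-negative")
        if self.rank == 0 and self.sensor_noise_sd <= 0:
            raise ValueError("need rank >= 1 or positive sensor noise")
        if self.component_rms < 0 or self.sensor_noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.spatial_patterns is not None:
            self.spatial_patterns = np.asarray(self.spatial_patterns, dtype=float)
            if self.spatial_patterns.shape[1] != self.rank:
                raise ValueError("need one spatial pattern per component")
            if np.linalg.matrix_rank(self.spatial_patterns) < self.rank:
                raise ValueError("spatial patterns must be linearly independent")


def random_patterns(
    n_channels: int, rank: int, rng: np.random.Generator,
    min_angle_deg: float = 30.0,
) -> np.ndarray:
    """Random unit spatial patterns with pairwise angle >= ``min_angle_deg``
    (rejection sampling), approximating distinct far-field interference
    topographies."""
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    cols: list[np.ndarray] = []
    attempts = 0
    while len(cols) < rank:
        v = rng.standard_normal(n_channels)
        v /= np.linalg.norm(v)
        if all(abs(v @ c) <= cos_max for c in cols):
            cols.append(v)
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place patterns at the requested separation")
    return np.stack(cols, axis=1)


def uniform_plus_gradient_patterns(sensors: SensorArray) -> np.ndarray:
    """Rank-4 preset mimicking shielded-room residuals: a uniform field
    along z plus three first-order gradients, as seen by radial sensors."""
    r, o = sensors.positions, sensors.orientations
    cols = [
        o[:, 2],                      # uniform Bz
        r[:, 0] * o[:, 2] + r[:, 2] * o[:, 0],  # dBz/dx-type gradient
        r[:, 1] * o[:, 2] + r[:, 2] * o[:, 1],  # dBz/dy-type gradient
        r[:, 2] * o[:, 2] - 0.5 * (r[:, 0] * o[:, 0] + r[:, 1] * o[:, 1]),
    ]
    pats = np.stack([c / np.linalg.norm(c) for c in cols], axis=1)
    return pats


def simulate_interference(
    sensors: SensorArray,
    model: InterferenceModel,
    duration: float,
    srate: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> ContinuousRecording:
    """One realization of the interference model as a continuous recording.

    Component timecourses are white Gaussian noise band-pass filtered to
    ``model.band`` and rescaled to unit RMS; each is broadcast through its
    spatial pattern (normalized to sqrt(n_channels), i.e. unit mean
    per-channel RMS) at amplitude ``component_rms``.  Deterministic given
    the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch = sensors.n_channels
    n_t = int(round(duration * srate))
    if n_t < 2:
        raise ValueError("duration too short")
    data = np.zeros((n_ch, n_t))
    if model.rank > 0:
        patterns = model.spatial_patterns
        if patterns is None:
            patterns = random_patterns(n_ch, model.rank, rng)
        # unit mean per-channel RMS: ||pattern|| = sqrt(n_channels)
        patterns = patterns / np.linalg.norm(patterns, axis=0, keepdims=True)
        patterns = patterns * np.sqrt(n_ch)
        sos = sp_signal.butter(
            4, list(model.band), btype="bandpass", fs=srate, output="sos"
        )
        for j in range(model.rank):
            tc = sp_signal.sosfiltfilt(sos, rng.standard_normal(n_t))
            tc /= np.sqrt(np.mean(tc**2))
            data += np.outer(patterns[:, j], model.component_rms * tc)
    if model.sensor_noise_sd > 0:
        data += model.sensor_noise_sd * rng.standard_normal((n_ch, n_t))
    return ContinuousRecording(
        data=data, srate=srate, channel_ids=list(sensors.channel_ids),
        provenance={"kind": "interference", "rank": model.rank},
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    truth: SimulationTruth,
    interference: ContinuousRecording,
    emptyroom: ContinuousRecording,
) -> tuple[EpochedRecording, ContinuousRecording, SimulationTruth]:
    """Combine clean epochs with interference into the measured dataset.

    Trial k of the raw epochs is B_sim plus the k-th consecutive,
    non-overlapping slice of the first interference realization; the
    second realization is returned untouched as the empty-room recording.
    """
    if interference.channel_ids != list(truth.sensors.channel_ids):
        raise ValueError("interference channels do not match the sensor array")
    if interference.srate != truth.srate:
        raise ValueError("sampling-rate mismatch")
    n_ch, n_trials, n_samp = truth.b_sim.shape
    needed = n_trials * n_samp
    if interference.n_times < needed:
        raise ValueError(
            f"interference recording of {interference.n_times} samples is too "
            f"short: need {needed} for {n_trials} trials of {n_samp} samples"
        )
    slices = interference.data[:, :needed].reshape(n_ch, n_trials, n_samp)
    raw = EpochedRecording(
        data=truth.b_sim + slices,
        srate=truth.srate,
        times=truth.times.copy(),
        channel_ids=list(truth.sensors.channel_ids),
        provenance={"kind": "simulated_raw", "interference_rank": truth.interference_rank},
    )
    return raw, emptyroom, truth


def simulate_dataset(
    seed: int,
    n_trials: int = 300,
    n_sensors: int = 31,
    srate: float = 1000.0,
    window: tuple[float, float] = (-0.2, 0.8),
    interference: InterferenceModel | None = None,
    dipole: DipoleSource | None = None,
) -> tuple[EpochedRecording, ContinuousRecording, SimulationTruth]:
    """End-to-end generation of one study dataset.

    Defaults reproduce the standard simulated conditions: 31 radial
    sensors, a 50 nA*m / 10 Hz dipole burst active 0-500 ms of each
    -200..800 ms epoch, 300 trials, rank-4 interference (1000 fT
    per-channel RMS per component, 1-40 Hz) with 30 fT sensor noise, and
    an independent statistically matched empty-room recording.  Pure
    function of (configuration, seed).
    """
    if interference is None:
        interference = InterferenceModel()
    if dipole is None:
        dipole = default_dipole(n_trials=n_trials)
    sensors = cap_sensor_array(n=n_sensors)
    ss = np.random.SeedSequence(seed)
    rng_patterns, rng_meas, rng_empty = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    if interference.rank > 0 and interference.spatial_patterns is None:
        interference = InterferenceModel(
            rank=interference.rank,
            spatial_patterns=random_patterns(
                sensors.n_channels, interference.rank, rng_patterns
            ),
            component_rms=interference.component_rms,
            band=interference.band,
            sensor_noise_sd=interference.sensor_noise_sd,
        )
    truth = simulate_evoked(sensors, dipole, srate=srate, window=window, seed=seed)
    truth.interference_rank = interference.rank
    n_samp = truth.times.size
    duration = (dipole.n_trials * n_samp + 1) / srate
    meas = simulate_interference(sensors, interference, duration, srate, rng_meas)
    empty = simulate_interference(sensors, interference, duration, srate, rng_empty)
    raw, emptyroom, truth = assemble_dataset(truth, meas, empty)
    truth.meta.update(
        {"interference": {
            "rank": interference.rank,
            "component_rms_ft": interference.component_rms,
            "band_hz": list(interference.band),
            "sensor_noise_sd_ft": interference.sensor_noise_sd,
        }}
    )
    return raw, emptyroom, truth


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------

def write_truth(path: str | Path, truth: SimulationTruth) -> None:
    """Persist the recoverable ground truth (dipole, rank, seed) as JSON.

    The clean epochs themselves are deterministic given the dipole and
    sensor layout and are not duplicated on disk.
    """
    payload = {
        "dipole": truth.dipole.to_dict(),
        "interference_rank": truth.interference_rank,
        "seed": truth.seed,
        "srate_hz": truth.srate,
        "window_s": [float(truth.times[0]), float(truth.times[-1])],
        "meta": truth.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path, sensors: SensorArray) -> SimulationTruth:
    """Rebuild a SimulationTruth from ``truth.json`` plus the sensor table."""
    payload = json.loads(Path(path).read_text())
    d = payload["dipole"]
    dipole = DipoleSource(
        position=np.array(d["position_m"]),
        moment_direction=np.array(d["moment_direction"]),
        peak_moment=d["peak_moment_nam"],
        frequency=d["frequency_hz"],
        active_tmin=d["active_window_s"][0],
        active_tmax=d["active_window_s"][1],
        n_trials=d["n_trials"],
    )
    truth = simulate_evoked(
        sensors, dipole, srate=payload["srate_hz"],
        window=tuple(payload["window_s"]), seed=payload["seed"],
    )
    truth.interference_rank = payload["interference_rank"]
    truth.meta = payload.get("meta", {})
    return truth
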