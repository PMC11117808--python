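"""Interference-subspace estimation and subspace-projection denoising.

SSP estimates the interference subspace from the left singular vectors of
an empty-room recording and removes it by orthogonal projection in channel
space.  S3P is the frequency-domain analogue: the subspace comes from the
leading eigenvectors of the noise cross-spectral density averaged over a
frequency band, and the projection is applied to the Fourier coefficients
of the data inside that band only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import numpy as np

from .data_model import ContinuousRecording, EpochedRecording

logger = logging.getLogger("sspdim")

__all__ = [
    "InterferenceSubspace",
    "DenoisedRecording",
    "noise_subspace_svd",
    "ssp_apply",
    "s3p_subspace",
    "s3p_apply",
    "export_subspace",
]

#: Denoised recordings keep the container type of their input; provenance
#: records the algorithm and dimension used.
DenoisedRecording = Union[ContinuousRecording, EpochedRecording]


@dataclass
class InterferenceSubspace:
    """An orthonormal channel-space basis spanning the interference.

    ``basis`` holds the x leading noise directions as columns; the full
    non-increasing singular/eigenvalue spectrum is kept for diagnostics.
    """

    basis: np.ndarray  # (n_channels, x), orthonormal columns
    singular_values: np.ndarray  # (n_channels,), non-increasing
    x: int
    algorithm: str  # "ssp" | "s3p"
    band: tuple[float, float] | None = None  # Hz, s3p only
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.basis.ndim != 2 or self.basis.shape[1] != self.x:
            raise ValueError("basis must be (n_channels, x)")
        if self.x > self.basis.shape[0]:
            raise ValueError("x cannot exceed the number of channels")
        if self.x > 0:
            gram = self.basis.T @ self.basis
            if not np.allclose(gram, np.eye(self.x), atol=1e-10):
                raise ValueError("basis columns must be orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-9 * max(1.0, self.singular_values[0] if self.singular_values.size else 1.0)):
            raise ValueError("singular values must be non-increasing")
        if np.any(self.singular_values < -1e-12):
            raise ValueError("singular values must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.basis.shape[0]

    def projector(self) -> np.ndarray:
        """The rank-x projector P = F_x F_x^T onto the interference subspace."""
        return self.basis @ self.basis.T


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (reproducible
    sign convention for SVD/eigendecompositions)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


# ---------------------------------------------------------------------------
# SSP (spatial domain)
# ---------------------------------------------------------------------------

def noise_subspace_svd(noise: ContinuousRecording, x: int) -> InterferenceSubspace:
    """Estimate the interference subspace by SVD of empty-room data.

    The columns of the returned basis are the left (channel-space)
    singular vectors of the channels x time noise matrix, ordered by
    decreasing singular value; the full singular spectrum is returned for
    diagnostics.  ``x = 0`` yields an empty basis (identity projection).
    """
    n_ch = noise.n_channels
    if not (0 <= x <= n_ch):
        raise ValueError(f"x={x} outside [0, {n_ch}]")
    if noise.n_times < n_ch:
        raise ValueError(
            f"empty-room recording has {noise.n_times} samples; need at "
            f"least {n_ch} (one per channel) for a full spectrum"
        )
    u, s, _ = np.linalg.svd(noise.data, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(noise.data.shape) * np.finfo(float).eps))
    if x > rank:
        warnings.warn(
            f"requested x={x} exceeds the numerical rank {rank} of the "
            "empty-room data; trailing basis vectors span numerical noise",
            RuntimeWarning,
        )
    basis = _fix_signs(u[:, :x]) if x > 0 else np.empty((n_ch, 0))
    return InterferenceSubspace(
        basis=basis, singular_values=s, x=x, algorithm="ssp",
        meta={"n_noise_samples": noise.n_times},
    )


def ssp_apply(rec: DenoisedRecording, sub: InterferenceSubspace) -> DenoisedRecording:
    """Project a recording onto the complement of the interference subspace.

    Every time-sample channel vector y is replaced by (I - F_x F_x^T) y;
    epoched input is handled trial by trial.  With x = 0 the output equals
    the input exactly.
    """
    if sub.n_channels != rec.n_channels:
        raise ValueError(
            f"subspace has {sub.n_channels} channels, recording has {rec.n_channels}"
        )
    if sub.x == 0:
        return rec.copy_with(rec.data.copy(), denoised={"algorithm": sub.algorithm, "x": 0})
    f = sub.basis
    if isinstance(rec, EpochedRecording):
        # (I - FF^T) applied to the channel axis of channels x trials x time
        data = rec.data - np.einsum("ij,jkt->ikt", f @ f.T, rec.data)
    else:
        data = rec.data - f @ (f.T @ rec.data)
    return rec.copy_with(data, denoised={"algorithm": sub.algorithm, "x": sub.x})


# ---------------------------------------------------------------------------
# S3P (frequency domain)
# ---------------------------------------------------------------------------

def _welch_csd(noise: ContinuousRecording, band: tuple[float, float]):
    """Band-averaged Hermitian cross-spectral density by Welch segmentation.

    1 s Hann segments with 50% overlap (shorter if the recording is);
    returns the CSD averaged over all Fourier bins inside ``band`` and the
    number of segments used.
    """
    fmin, fmax = band
    nyq = noise.srate / 2.0
    if not (0.0 < fmin < fmax < nyq):
        raise ValueError(f"band {band} must lie within (0, {nyq}) Hz")
    nper = min(int(round(noise.srate)), noise.n_times)
    step = max(1, nper // 2)
    window = np.hanning(nper)
    freqs = np.fft.rfftfreq(nper, d=1.0 / noise.srate)
    in_band = (freqs >= fmin) & (freqs <= fmax)
    if not np.any(in_band):
        raise ValueError(
            f"band {band} Hz contains no Fourier bins at a segment length "
            f"of {nper} samples ({noise.srate} Hz sampling)"
        )
    starts = range(0, noise.n_times - nper + 1, step)
    csd = np.zeros((noise.n_channels, noise.n_channels), dtype=complex)
    n_seg = 0
    for s0 in starts:
        seg = noise.data[:, s0:s0 + nper] * window
        spec = np.fft.rfft(seg, axis=1)[:, in_band]
        csd += spec @ spec.conj().T
        n_seg += 1
    csd /= n_seg * in_band.sum()
    return csd, n_seg


def _realify(vectors: np.ndarray, n_keep: int) -> np.ndarray:
    """Convert complex eigenvectors to a real orthonormal basis.

    Each eigenvector is phase-rotated to concentrate its energy on the
    real axis; if a significant imaginary part remains the real and
    imaginary parts both enter the basis (the subspace they span in real
    arithmetic is 2-dimensional).  Columns are orthonormalized in order
    and the result truncated to ``n_keep`` columns at most.
    """
    n_ch = vectors.shape[0]
    cols: list[np.ndarray] = []
    for j in range(vectors.shape[1]):
        v = vectors[:, j]
        # rotate so that sum(v_i^2) is real-positive: minimizes ||imag(v)||
        theta = 0.5 * np.angle(np.sum(v**2))
        v = v * np.exp(-1j * theta)
        candidates = [v.real]
        if np.linalg.norm(v.imag) > 1e-6:
            candidates.append(v.imag)
        for c in candidates:
            # Gram-Schmidt against already-accepted columns
            for b in cols:
                c = c - b * (b @ c)
            nrm = np.linalg.norm(c)
            if nrm > 1e-10:
                cols.append(c / nrm)
        if len(cols) >= n_keep:
            break
    basis = np.stack(cols[:n_keep], axis=1) if cols else np.empty((n_ch, 0))
    return _fix_signs(basis) if basis.shape[1] else basis


def s3p_subspace(
    noise: ContinuousRecording, x: int, band: tuple[float, float]
) -> InterferenceSubspace:
    """Spectral interference subspace from the noise cross-spectral density.

    The Hermitian CSD of the empty-room data is estimated by Welch
    segmentation and averaged over the Fourier bins inside ``band``; the
    basis consists of its top-x eigenvectors, resolved to a real
    orthonormal basis.  Eigenvalues are reported in ``singular_values``.
    """
    n_ch = noise.n_channels
    if not (0 <= x <= n_ch):
        raise ValueError(f"x={x} outside [0, {n_ch}]")
    csd, n_seg = _welch_csd(noise, band)
    evals, evecs = np.linalg.eigh(csd)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order].real, 0.0)
    evecs = evecs[:, order]
    basis = _realify(evecs[:, : max(x, 0)], x) if x > 0 else np.empty((n_ch, 0))
    return InterferenceSubspace(
        basis=basis, singular_values=evals, x=basis.shape[1], algorithm="s3p",
        band=(float(band[0]), float(band[1])), meta={"n_segments": n_seg},
    )


def s3p_apply(rec: DenoisedRecording, sub: InterferenceSubspace) -> DenoisedRecording:
    """Apply spectral subspace projection inside the subspace's band.

    Each channel (per trial) is Fourier-transformed; for frequency bins
    inside ``sub.band`` the channel vector of complex coefficients is
    projected onto the complement of the basis; bins outside the band are
    untouched; the inverse transform restores the time domain (real by
    construction of the half-spectrum transform).
    """
    if sub.n_channels != rec.n_channels:
        raise ValueError(
            f"subspace has {sub.n_channels} channels, recording has {rec.n_channels}"
        )
    if sub.x == 0:
        return rec.copy_with(rec.data.copy(), denoised={"algorithm": "s3p", "x": 0})
    if sub.band is None:
        raise ValueError("s3p subspace carries no band")
    fmin, fmax = sub.band
    f = sub.basis

    def _project(mat: np.ndarray) -> np.ndarray:  # channels x time
        n = mat.shape[1]
        spec = np.fft.rfft(mat, axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0 / rec.srate)
        in_band = (freqs >= fmin) & (freqs <= fmax)
        spec[:, in_band] -= f @ (f.T @ spec[:, in_band])
        return np.fft.irfft(spec, n=n, axis=1)

    if isinstance(rec, EpochedRecording):
        data = np.stack(
            [_project(rec.data[:, k, :]) for k in range(rec.n_trials)], axis=1
        )
    else:
        data = _project(rec.data)
    return rec.copy_with(data, denoised={"algorithm": "s3p", "x": sub.x})


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_subspace(path: str | Path, sub: InterferenceSubspace) -> None:
    """Write basis and singular spectrum as JSON plus columnar text for audit."""
    path = Path(path)
    payload = {
        "algorithm": sub.algorithm,
        "x": sub.x,
        "band_hz": list(sub.band) if sub.band else None,
        "singular_values": sub.singular_values.tolist(),
        "basis": sub.basis.tolist(),
        "meta": sub.meta,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    txt = path.with_suffix(".txt")
    with open(txt, "w") as fh:
        fh.write("# singular_values: " + " ".join(f"{v:.10g}" for v in sub.singular_values) + "\n")
        for row in sub.basis:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
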