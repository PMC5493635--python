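"""Synthetic image stacks and Poisson noise injection.

A stack ``I`` (N pixels x K frames) is the matrix product of the system
matrix G (N x M) and the photon-count matrix S (M x K): frame ``k`` is
the photon-weighted sum of the emitter images.  Peak signal-to-noise is
defined through Poisson counting statistics: a matrix scaled so its
maximum expected count is ``peak_snr**2`` has SNR ``sqrt(count) =
peak_snr`` at the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .kinetics import PhotonCountMatrix
from .optics import SystemMatrix

__all__ = [
    "ImageStack",
    "simulate_stack",
    "add_poisson_noise",
    "write_stack_tiff",
    "read_stack_tiff",
]

_SNR_CAP = 1e6


@dataclass(frozen=True)
class ImageStack:
    """N x K pixel measurements with acquisition metadata."""

    I: np.ndarray
    frame_time: float = 10.0
    provenance: str = "simulated"  # or "loaded"
    pixel_size_nm: float | None = None

    @property
    def N(self) -> int:
        return self.I.shape[0]

    @property
    def K(self) -> int:
        return self.I.shape[1]


def simulate_stack(system: SystemMatrix | np.ndarray,
                   counts: PhotonCountMatrix | np.ndarray,
                   frame_time: float | None = None,
                   pixel_size_nm: float | None = None) -> ImageStack:
    """Noiseless stack I = G @ S."""
    G = system.G if isinstance(system, SystemMatrix) else np.asarray(system)
    if isinstance(counts, PhotonCountMatrix):
        S = counts.S
        if frame_time is None:
            frame_time = counts.frame_time
    else:
        S = np.asarray(counts)
    if G.shape[1] != S.shape[0]:
        raise ValueError(
            f"emitter dimension mismatch: G is {G.shape}, S is {S.shape}")
    if pixel_size_nm is None and isinstance(system, SystemMatrix):
        pixel_size_nm = system.grid.pixel_size_nm
    return ImageStack(G @ S, frame_time if frame_time is not None else 10.0,
                      "simulated", pixel_size_nm)


def add_poisson_noise(X: np.ndarray, peak_snr: float, rng_seed) -> np.ndarray:
    """Poisson noise at a given peak SNR; the expectation is preserved.

    X is scaled so its maximum equals ``peak_snr**2`` (the peak expected
    photon count), each entry is replaced by a Poisson draw, and the
    result is scaled back.  An all-zero input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    if peak_snr <= 0:
        raise ValueError("peak_snr must be positive")
    peak = X.max()
    if peak <= 0:
        return X.copy()
    peak_snr = min(peak_snr, _SNR_CAP)
    scale = peak_snr ** 2 / peak
    rng = np.random.default_rng(rng_seed)
    return rng.poisson(X * scale).astype(float) / scale


def write_stack_tiff(path, stack: ImageStack) -> None:
    """Write the stack as a multi-page 32-bit float TIFF, one frame per page."""
    frames = stack.I.T.astype(np.float32)[:, :, None]  # (K, N, 1) pages
    meta = {
        "frame_time_ms": stack.frame_time,
        "pixel_size_nm": stack.pixel_size_nm,
        "provenance": stack.provenance,
    }
    tifffile.imwrite(path, frames, metadata=meta)


def read_stack_tiff(path) -> ImageStack:
    """Load a stack previously written by :func:`write_stack_tiff`."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    I = np.asarray(arr, dtype=float).T
    return ImageStack(
        I,
        float(meta.get("frame_time_ms") or 10.0),
        "loaded",
        meta.get("pixel_size_nm"),
    )
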