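"""SVD clutter rejection and power-Doppler rendering.

The reconstructed complex field carries both quasi-static tissue
backscatter (clutter) and broadband Doppler-shifted signal from moving
blood.  Clutter is rejected by removing the leading singular components
of the space-time (Casorati) matrix; the blood-flow contrast is then the
short-time-Fourier power integrated over a frequency band, by default
3-16.5 kHz at a 33 kHz frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ComplexFieldStack


@dataclass(frozen=True)
class DopplerBand:
    """Doppler frequency band, in hertz.  Both edges are inclusive."""

    f_low: float = 3e3
    f_high: float = 16.5e3

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError("need 0 <= f_low < f_high")

    def validate_for(self, frame_rate: float) -> None:
        if self.f_high > frame_rate / 2 + 1e-9:
            raise ValueError(
                f"f_high = {self.f_high} Hz exceeds the Nyquist frequency "
                f"{frame_rate / 2} Hz")


@dataclass
class PowerDopplerImage:
    """Per-pixel in-band Doppler power (arbitrary units, >= 0)."""

    power: np.ndarray
    band: DopplerBand
    n_frames_used: int

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2:
            raise ValueError("power must be a 2-D image")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power contains non-finite values")
        if np.any(self.power < -1e-12 * max(1.0, self.power.max(initial=0.0))):
            raise ValueError("power must be non-negative")
        np.clip(self.power, 0.0, None, out=self.power)


def svd_clutter_filter(stack: ComplexFieldStack,
                       n_reject: int) -> ComplexFieldStack:
    """Remove the ``n_reject`` leading singular components of the stack.

    The Nt x (Ny*Nx) Casorati matrix is projected onto the orthogonal
    complement of its ``n_reject`` leading singular vector pairs, which
    carry the brightest (quasi-static) signal.  The filtered matrix is
    exactly orthogonal to the rejected components.

    Eigendecomposition of the small Nt x Nt temporal Gram matrix is used,
    which is equivalent to a singular value decomposition of the Casorati
    matrix for the purpose of this projection.
    """
    if n_reject < 0:
        raise ValueError("n_reject must be >= 0")
    nt = stack.n_frames
    if n_reject >= nt:
        raise ValueError(f"n_reject = {n_reject} must be < Nt = {nt}")
    if n_reject == 0:
        return replace(stack, field=stack.field.copy())
    casorati = stack.field.reshape(nt, -1)
    gram = casorati @ casorati.conj().T
    eigval, eigvec = np.linalg.eigh(gram)
    # eigh returns ascending order; leading components are the last columns
    u = eigvec[:, -n_reject:]
    filtered = casorati - u @ (u.conj().T @ casorati)
    return replace(stack, field=filtered.reshape(stack.shape))


def _band_bins(window: int, frame_rate: float, band: DopplerBand) -> np.ndarray:
    """Boolean mask of DFT bins whose |frequency| lies inside the band."""
    freqs = np.fft.fftfreq(window, d=1.0 / frame_rate)
    tol = 1e-9 * frame_rate
    return (np.abs(freqs) >= band.f_low - tol) & \
           (np.abs(freqs) <= band.f_high + tol)


def _window_starts(nt: int, window: int, overlap: int) -> list[int]:
    if not 0 < window <= nt:
        raise ValueError(f"window = {window} must be in 1..Nt = {nt}")
    if not 0 <= overlap < window:
        raise ValueError("overlap must satisfy 0 <= overlap < window")
    hop = window - overlap
    starts = list(range(0, nt - window + 1, hop))
    return starts or [0]

def power_doppler(stack: ComplexFieldStack,
                  band: DopplerBand | None = None,
                  frame_rate: float | None = None,
                  window: int | None = None,
                  overlap: int = 0) -> PowerDopplerImage:
    """Short-time-Fourier power-Doppler image of a complex field stack.

    For each pixel the squared spectral magnitude is summed over the DFT
    bins with ``f_low <= |f| <= f_high`` and averaged over the short-time
    windows.  The normalisation is such that with the full band
    (``0..frame_rate/2``) and a single full-length window the result
    equals the temporal mean squared modulus (Parseval).

    ``window`` defaults to the full sequence length (one window), which is
    how one 512-frame acquisition batch is rendered.
    """
    if band is None:
        band = DopplerBand()
    if frame_rate is None:
        frame_rate = stack.config.frame_rate
    band.validate_for(frame_rate)
    nt = stack.n_frames
    if window is None:
        window = nt
    starts = _window_starts(nt, window, overlap)
    bins = _band_bins(window, frame_rate, band)
    if not bins.any():
        raise ValueError("the Doppler band contains no DFT bin at this "
                         "window length and frame rate")
    acc = np.zeros(stack.shape[1:], dtype=np.float64)
    for s in starts:
        spectrum = np.fft.fft(stack.field[s:s + window], axis=0)
        acc += np.sum(np.abs(spectrum[bins]) ** 2, axis=0)
    power = acc / (len(starts) * window**2)
    return PowerDopplerImage(power, band, nt)


def temporal_trace(stack: ComplexFieldStack,
                   roi_mask: np.ndarray,
                   band: DopplerBand | None = None,
                   frame_rate: float | None = None,
                   window: int | None = None,
                   overlap: int = 0) -> np.ndarray:
    """Time series of ROI-averaged in-band Doppler power.

    One value per short-time window: the per-pixel in-band power of that
    window averaged over the region of interest.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.shape[1:]:
        raise ValueError("roi_mask must match the lateral frame shape")
    if not roi_mask.any():
        raise ValueError("roi_mask is empty")
    if band is None:
        band = DopplerBand()
    if frame_rate is None:
        frame_rate = stack.config.frame_rate
    band.validate_for(frame_rate)
    nt = stack.n_frames
    if window is None:
        window = nt
    starts = _window_starts(nt, window, overlap)
    bins = _band_bins(window, frame_rate, band)
    if not bins.any():
        raise ValueError("the Doppler band contains no DFT bin at this "
                         "window length and frame rate")
    roi = stack.field[:, roi_mask]
    trace = np.empty(len(starts), dtype=np.float64)
    for i, s in enumerate(starts):
        spectrum = np.fft.fft(roi[s:s + window], axis=0)
        trace[i] = np.mean(np.sum(np.abs(spectrum[bins]) ** 2, axis=0))
    return trace / window**2
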