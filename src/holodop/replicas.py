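"""Detection and suppression of shifted ghost replicas.

An excessive curvature mismatch between the reference and object waves at
the sensor produces faint shifted duplicates ("ghosts") of the rendered
image, typically in four directions.  Their positions are found from the
local maxima of the image autocorrelation; their strength is the ratio of
the secondary correlation peak to the zero-lag value.

Removal works with a basis of translated copies of the image.  A singular
value decomposition of the original image stacked with the translated
copies isolates the content they share (the main features); subtracting
the projection onto this leading eigenimage from each translated copy
leaves residual templates that carry the replica-position features only.
The removal image is the least-squares combination of these residuals
fitted to the original, so the subtraction can only decrease the energy
of the (mean-removed) image.

All correlations are linear (zero-padded FFT) on mean-subtracted images,
because the replicas are plain translations, not circular ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .doppler import PowerDopplerImage


@dataclass
class ReplicaSet:
    """Replica offsets (pixels, (dy, dx) relative to the main image) and
    their relative intensities (secondary / central correlation peak)."""

    offsets: np.ndarray
    relative_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.relative_intensity = np.asarray(self.relative_intensity,
                                             dtype=np.float64)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must be (k, 2) integer vectors")
        if len(self.offsets) != len(self.relative_intensity):
            raise ValueError("one intensity per offset required")
        if np.any(np.all(self.offsets == 0, axis=1)):
            raise ValueError("the zero offset is the main image, not a "
                             "replica")
        if np.any((self.relative_intensity <= 0.0)
                  | (self.relative_intensity >= 1.0)):
            raise ValueError("relative intensities must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.offsets)


def _as_array(image) -> np.ndarray:
    return np.asarray(getattr(image, "power", image), dtype=np.float64)


def _autocorrelation(image: np.ndarray):
    """Linear (zero-padded) autocorrelation of the mean-subtracted image.

    Returns the correlation map and the index of the zero-lag sample.
    """
    a = image - image.mean()
    ny, nx = a.shape
    fa = np.fft.fft2(a, s=(2 * ny - 1, 2 * nx - 1))
    ac = np.fft.fftshift(np.fft.ifft2(fa * np.conj(fa)).real)
    return ac, (ny - 1, nx - 1)


def translate(image: np.ndarray, offset) -> np.ndarray:
    """Integer-pixel translation with zero padding (content moves by
    ``offset = (dy, dx)``)."""
    dy, dx = int(offset[0]), int(offset[1])
    out = np.zeros_like(image)
    ny, nx = image.shape
    src_y = slice(max(0, -dy), min(ny, ny - dy))
    src_x = slice(max(0, -dx), min(nx, nx - dx))
    dst_y = slice(max(0, dy), min(ny, ny + dy))
    dst_x = slice(max(0, dx), min(nx, nx + dx))
    out[dst_y, dst_x] = image[src_y, src_x]
    return out


def secondary_peak_ratio(image, offsets) -> np.ndarray:
    """Autocorrelation value at each offset divided by the zero-lag value.

    The ratio at offset (0, 0) is 1 by definition; for a replica of
    relative amplitude ``alpha`` at offset ``delta`` the ratio at
    ``delta`` is approximately ``alpha``.
    """
    img = _as_array(image)
    offsets = np.atleast_2d(np.asarray(offsets, dtype=int))
    ac, (cy, cx) = _autocorrelation(img)
    central = ac[cy, cx]
    if central <= 0:
        raise ValueError("image is constant; autocorrelation undefined")
    ny, nx = img.shape
    ratios = np.empty(len(offsets))
    for i, (dy, dx) in enumerate(offsets):
        if abs(dy) >= ny or abs(dx) >= nx:
            raise ValueError(f"offset ({dy}, {dx}) outside the image")
        ratios[i] = ac[cy + dy, cx + dx] / central
    return ratios


def locate_replica_offsets(image, n_replicas: int = 4,
                           exclusion_radius: int = 8,
                           min_ratio: float = 0.0) -> ReplicaSet:
    """Locate replica offsets from autocorrelation local maxima.

    Returns the ``n_replicas`` strongest local maxima of the linear
    autocorrelation outside ``exclusion_radius`` pixels around zero lag,
    with their peak-to-central-peak ratios.  Raises (reporting the count
    found) if fewer positive local maxima exist.
    """
    from scipy.ndimage import maximum_filter

    img = _as_array(image)
    if img.std() == 0:
        raise ValueError("image is constant; replicas cannot be located")
    ac, (cy, cx) = _autocorrelation(img)
    central = ac[cy, cx]
    local_max = (ac == maximum_filter(ac, size=3)) & (ac > 0)
    yy, xx = np.mgrid[0:ac.shape[0], 0:ac.shape[1]]
    lag_y, lag_x = yy - cy, xx - cx
    local_max &= np.hypot(lag_y, lag_x) > exclusion_radius
    ratios = ac[local_max] / central
    cand_y = lag_y[local_max]
    cand_x = lag_x[local_max]
    keep = ratios > min_ratio
    ratios, cand_y, cand_x = ratios[keep], cand_y[keep], cand_x[keep]
    if len(ratios) < n_replicas:
        raise ValueError(f"requested {n_replicas} replicas but only "
                         f"{len(ratios)} local maxima found")
    order = np.argsort(ratios)[::-1][:n_replicas]
    offsets = np.stack([cand_y[order], cand_x[order]], axis=1)
    return ReplicaSet(offsets, np.clip(ratios[order], 1e-12, 1 - 1e-12))


def build_shifted_basis(image, replicas: ReplicaSet) -> np.ndarray:
    """Stack of copies of the image translated by minus each offset, so
    that each replica's features land on the main features' position."""
    img = _as_array(image)
    return np.stack([translate(img, -off) for off in replicas.offsets])


def remove_replicas(image, replicas: ReplicaSet,
                    rank: int | None = None):
    """Attenuate the declared replicas by SVD eigenimage subtraction.

    Copies of the (mean-removed) image are translated onto each replica
    position; a singular value decomposition of this shifted-image basis
    yields orthonormal eigenimages that carry the spurious features to be
    removed.  The removal image is the projection of the original onto
    the span of these eigenimages (``rank`` limits how many are used;
    default all significant ones), and is subtracted from the original.
    Being a least-squares projection, the subtraction can only decrease
    the energy of the mean-removed image.

    Returns ``(clean image, report dict)`` where the report holds
    per-offset before/after secondary-peak ratios and attenuation
    factors (before / |after|).
    """
    if len(replicas) < 2:
        raise ValueError("need at least two replicas for a meaningful SVD")
    img = _as_array(image)
    work = img - img.mean()
    # templates aligned with each replica: main features moved onto the
    # replica position
    templates = np.stack([translate(work, off) for off in replicas.offsets])
    k = len(replicas)
    flat = templates.reshape(k, -1)
    norms = np.linalg.norm(flat, axis=1)
    if np.all(norms < 1e-12 * max(1.0, np.linalg.norm(work))):
        warnings.warn("degenerate shifted basis; image left unchanged",
                      RuntimeWarning, stacklevel=2)
        return _wrap_like(image, img), _report(image, img, replicas)
    _, s, vt = np.linalg.svd(flat, full_matrices=False)
    significant = s > 1e-9 * s[0]
    if significant.sum() < k:
        warnings.warn("shifted basis is degenerate (linearly dependent "
                      "images); image left unchanged", RuntimeWarning,
                      stacklevel=2)
        return _wrap_like(image, img), _report(image, img, replicas)
    n_use = k if rank is None else int(np.clip(rank, 1, k))
    eigenimages = vt[:n_use]
    coef = eigenimages @ work.reshape(-1)
    removal = (coef @ eigenimages).reshape(img.shape)
    clean = _wrap_like(image, img - removal)
    return clean, _report(image, clean, replicas)


def _wrap_like(original, array: np.ndarray):
    if isinstance(original, PowerDopplerImage):
        return PowerDopplerImage(np.clip(array, 0.0, None), original.band,
                                 original.n_frames_used)
    return array


def _report(before, after, replicas: ReplicaSet) -> dict:
    try:
        ratios_before = secondary_peak_ratio(before, replicas.offsets)
        ratios_after = secondary_peak_ratio(after, replicas.offsets)
    except ValueError:  # constant image: ratios undefined
        nan = np.full(len(replicas), np.nan)
        return {
            "offsets": [tuple(int(v) for v in off)
                        for off in replicas.offsets],
            "ratio_before": nan.tolist(),
            "ratio_after": nan.tolist(),
            "attenuation": nan.tolist(),
        }
    attenuation = np.abs(ratios_before) / np.maximum(np.abs(ratios_after),
                                                     1e-12)
    return {
        "offsets": [tuple(int(v) for v in off) for off in replicas.offsets],
        "ratio_before": ratios_before.tolist(),
        "ratio_after": ratios_after.tolist(),
        "attenuation": attenuation.tolist(),
    }
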