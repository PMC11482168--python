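"""Numerical Shack-Hartmann wavefront sensing by subaperture correlation.

The pupil-plane field is split into a regular grid of square
subapertures.  Each subaperture is rendered separately into a
power-Doppler subimage that shares the full field of view at reduced
resolution.  A local wavefront tilt over a subaperture translates its
subimage, so subimage shifts measured by cross-correlation against a
reference image play the role of Shack-Hartmann spot displacements.

Two reference choices are supported: the central subaperture's own
subimage, and the full-pupil image resized to the subimage dimensions.
The latter sets the average gradient as the zero level and avoids the
reference carrying the speckle of one particular subaperture.

Shift sign convention: a subimage equal to the reference translated by
``(dx, dy)`` pixels (x = columns, y = rows, both increasing with index)
has measured shift ``(dx, dy)``.  With the centred-spectrum transforms of
:mod:`holodop.core`, a pupil phase ramp of slope ``a`` rad/pupil-pixel
across a subaperture of side ``S`` translates its subimage by
``-a * S / (2 * pi)`` pixels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from skimage.transform import resize

from .core import ComplexFieldStack, Plane, from_pupil
from .doppler import DopplerBand, PowerDopplerImage, power_doppler, \
    svd_clutter_filter


class ReferenceMode(str, enum.Enum):
    CENTRAL = "central"
    RESIZED_FULL = "resized_full"


@dataclass(frozen=True)
class SubapertureGrid:
    """Regular grid of square, non-overlapping pupil subapertures.

    ``centers`` are in normalised pupil coordinates: the gridded region
    spans [-1, 1] in each direction, so the unit circle is inscribed in
    the grid.  Subapertures whose centre falls outside the unit circle
    (the corners) are flagged by ``inside_circle`` and excluded from
    wavefront fitting.
    """

    n_side: int
    aperture_px: int
    centers: np.ndarray = dataclass_field(repr=False, default=None)
    inside_circle: np.ndarray = dataclass_field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_side < 3:
            raise ValueError("n_side must be >= 3")
        if self.aperture_px < 1:
            raise ValueError("aperture_px must be >= 1")
        if self.centers is None:
            u = (2 * np.arange(self.n_side) + 1 - self.n_side) / self.n_side
            cx, cy = np.meshgrid(u, u, indexing="xy")
            centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
            object.__setattr__(self, "centers", centers)
        if self.inside_circle is None:
            radii = np.hypot(self.centers[:, 0], self.centers[:, 1])
            # a centre within half a subaperture width (1/n_side in
            # normalised units) of the unit circle still overlaps the
            # pupil substantially; on a 7x7 grid this drops exactly the
            # four corners (|c| = sqrt(2) * 6/7 ~ 1.21)
            tol = 1.0 / self.n_side
            object.__setattr__(self, "inside_circle",
                               radii <= 1.0 + tol + 1e-12)

    @classmethod
    def for_pupil(cls, n_px: int, n_side: int) -> "SubapertureGrid":
        """Largest grid of ``n_side`` x ``n_side`` square windows that fits
        a centred ``n_px`` pupil array."""
        aperture_px = n_px // n_side
        if aperture_px < 1:
            raise ValueError("grid does not fit in the pupil array")
        return cls(n_side=n_side, aperture_px=aperture_px)

    @property
    def n_subapertures(self) -> int:
        return self.n_side**2

    @property
    def span_px(self) -> int:
        """Side length in pixels of the gridded pupil region."""
        return self.n_side * self.aperture_px

    def window_slices(self, n_px: int):
        """Half-open (row, col) index ranges of every subaperture window
        inside a centred ``n_px`` array (row-major subaperture order)."""
        span = self.span_px
        if span > n_px:
            raise ValueError(f"grid span {span} px exceeds array size {n_px}")
        start = (n_px - span) // 2
        slices = []
        for iy in range(self.n_side):
            for ix in range(self.n_side):
                r0 = start + iy * self.aperture_px
                c0 = start + ix * self.aperture_px
                slices.append((slice(r0, r0 + self.aperture_px),
                               slice(c0, c0 + self.aperture_px)))
        return slices

    @property
    def central_index(self) -> int:
        """Index of the subaperture containing the pupil centre."""
        mid = self.n_side // 2
        return mid * self.n_side + mid


@dataclass(frozen=True)
class ReferenceSpec:
    """Reference-image choice and correlation settings."""

    mode: ReferenceMode = ReferenceMode.RESIZED_FULL
    crop_margin: float = 0.25
    peak_threshold: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ReferenceMode(self.mode))
        if not 0.0 <= self.crop_margin < 0.45:
            raise ValueError("crop_margin must be in [0, 0.45)")
        if not 0.0 <= self.peak_threshold <= 1.0:
            raise ValueError("peak_threshold must be in [0, 1]")


@dataclass
class ShiftField:
    """Per-subaperture subimage displacements (subimage pixels).

    ``shifts[i] = (dx, dy)``; ``peak_value`` is the normalised
    cross-correlation maximum; ``valid`` flags subapertures whose peak
    reached the threshold used during measurement.
    """

    shifts: np.ndarray
    peak_value: np.ndarray
    valid: np.ndarray
    reference_mode: ReferenceMode

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        self.peak_value = np.asarray(self.peak_value, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n, 2)")
        if not (len(self.shifts) == len(self.peak_value) == len(self.valid)):
            raise ValueError("inconsistent per-subaperture array lengths")
        self.reference_mode = ReferenceMode(self.reference_mode)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def split_pupil(pupil_stack: ComplexFieldStack,
                grid: SubapertureGrid) -> list[ComplexFieldStack]:
    """Cut a pupil-plane stack into ``n_side**2`` subaperture stacks.

    Each output stack holds the windowed pupil content of one square
    subaperture (hard binary mask); the windows tile the gridded region
    without overlap, so the subaperture energies sum to at most the total
    pupil energy.
    """
    if pupil_stack.plane != Plane.PUPIL:
        raise ValueError("split_pupil expects a pupil-plane stack")
    n_px = pupil_stack.shape[-1]
    if pupil_stack.shape[-2] != n_px:
        raise ValueError("square pupil arrays expected")
    out = []
    for rows, cols in grid.window_slices(n_px):
        sub = pupil_stack.field[:, rows, cols].copy()
        out.append(ComplexFieldStack(sub, Plane.PUPIL, pupil_stack.z,
                                     pupil_stack.config))
    return out


def render_subimages(sub_stacks: list[ComplexFieldStack],
                     band: DopplerBand | None = None,
                     frame_rate: float | None = None,
                     n_reject: int = 2,
                     window: int | None = None,
                     overlap: int = 0) -> list[PowerDopplerImage]:
    """Render one power-Doppler subimage per subaperture stack.

    Each windowed pupil stack is transformed back to the image plane on
    its own (reduced) grid, clutter-filtered and integrated over the
    Doppler band.  All subimages share the field of view of the full
    image at a resolution reduced by the pupil-support reduction.
    """
    images = []
    for sub in sub_stacks:
        img = from_pupil(sub)
        img = svd_clutter_filter(img, n_reject)
        images.append(power_doppler(img, band=band, frame_rate=frame_rate,
                                    window=window, overlap=overlap))
    return images


def make_reference(full_image: PowerDopplerImage | np.ndarray,
                   central_subimage: PowerDopplerImage | np.ndarray,
                   spec: ReferenceSpec) -> np.ndarray:
    """Build the correlation reference image.

    ``central`` mode returns the central subaperture's subimage;
    ``resized_full`` downsamples the full-pupil image to the subimage
    dimensions (anti-aliased, geometry preserving).
    """
    full = np.asarray(getattr(full_image, "power", full_image),
                      dtype=np.float64)
    central = np.asarray(getattr(central_subimage, "power",
                                 central_subimage), dtype=np.float64)
    if spec.mode == ReferenceMode.CENTRAL:
        return central.copy()
    if full.shape == central.shape:
        return full.copy()
    return resize(full, central.shape, anti_aliasing=True,
                  preserve_range=True)


def _parabola_offset(y_minus: float, y_0: float, y_plus: float) -> float:
    """Vertex offset of the parabola through three equispaced samples.

    Falls back to the integer peak (offset 0) for flat or non-concave
    neighbourhoods; the offset is clamped to +/- 0.5 samples.
    """
    denom = y_minus - 2.0 * y_0 + y_plus
    if denom >= -1e-300:
        return 0.0
    delta = 0.5 * (y_minus - y_plus) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _crop(image: np.ndarray, margin: float) -> np.ndarray:
    m = int(round(margin * image.shape[0]))
    if m == 0:
        return image
    return image[m:-m, m:-m]


def correlate_images(image: np.ndarray, reference: np.ndarray,
                     min_overlap: float = 0.3):
    """Normalised linear cross-correlation shift of ``image`` vs ``reference``.

    The zero-mean normalised cross-correlation is evaluated over the
    *overlap region* of every integer lag (zero-padded linear correlation
    with overlap-corrected means and variances, computed by FFT), so
    large shifts are not penalised by the shrinking support.  The search
    is limited to lags keeping at least ``min_overlap`` of the pixels in
    common; the integer peak is refined to subpixel precision with two
    independent 1-D three-point parabola fits.

    Returns ``(dx, dy, peak_value)`` with ``peak_value`` in [-1, 1] (the
    normalised correlation coefficient over the overlap at the peak).
    ``(dx, dy)`` is the translation that maps the reference onto the
    image.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference must have the same shape")
    a = image - image.mean()
    b = reference - reference.mean()
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0, 0.0, 0.0
    ny, nx = a.shape
    shape = (2 * ny, 2 * nx)
    fa = np.fft.fft2(a, s=shape)
    fb = np.fft.fft2(b, s=shape)
    fa2 = np.fft.fft2(a * a, s=shape)
    fb2 = np.fft.fft2(b * b, s=shape)
    ones = np.fft.fft2(np.ones_like(a), s=shape)

    def xcorr(f, g):
        return np.fft.fftshift(np.fft.ifft2(f * np.conj(g)).real)

    corr_ab = xcorr(fa, fb)
    n_ovl = np.maximum(np.round(xcorr(ones, ones)), 1.0)
    sum_a = xcorr(fa, ones)
    sum_b = xcorr(ones, fb)
    sum_a2 = xcorr(fa2, ones)
    sum_b2 = xcorr(ones, fb2)
    num = corr_ab - sum_a * sum_b / n_ovl
    var_a = np.maximum(sum_a2 - sum_a**2 / n_ovl, 0.0)
    var_b = np.maximum(sum_b2 - sum_b**2 / n_ovl, 0.0)
    denom = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 1e-12 * a.size, num / denom, -np.inf)
    ncc[n_ovl < min_overlap * a.size] = -np.inf
    cy, cx = ny, nx  # zero-lag position after fftshift
    py, px = np.unravel_index(np.argmax(ncc), ncc.shape)
    if not np.isfinite(ncc[py, px]):
        return 0.0, 0.0, 0.0
    neighbours = ncc[py - 1:py + 2, px - 1:px + 2] if \
        0 < py < ncc.shape[0] - 1 and 0 < px < ncc.shape[1] - 1 else None
    if neighbours is not None and np.all(np.isfinite(neighbours)):
        dy = py - cy + _parabola_offset(ncc[py - 1, px], ncc[py, px],
                                        ncc[py + 1, px])
        dx = px - cx + _parabola_offset(ncc[py, px - 1], ncc[py, px],
                                        ncc[py, px + 1])
    else:
        dy, dx = py - cy, px - cx
    peak = float(np.clip(ncc[py, px], -1.0, 1.0))
    return float(dx), float(dy), peak


def measure_shifts(subimages: list[PowerDopplerImage | np.ndarray],
                   reference: np.ndarray,
                   spec: ReferenceSpec,
                   reference_mode: ReferenceMode | None = None) -> ShiftField:
    """Measure per-subaperture subimage shifts against a reference.

    Subimages and reference are cropped by ``spec.crop_margin`` per edge
    (removing the vignetted borders whose angular composition differs
    across the field of view), mean-subtracted and cross-correlated.
    Subapertures whose normalised correlation peak stays below
    ``spec.peak_threshold`` are flagged invalid.
    """
    reference = np.asarray(getattr(reference, "power", reference),
                           dtype=np.float64)
    ref_c = _crop(reference, spec.crop_margin)
    n = len(subimages)
    if n == 0:
        raise ValueError("no subimages given")
    shifts = np.zeros((n, 2))
    peaks = np.zeros(n)
    for i, sub in enumerate(subimages):
        img = np.asarray(getattr(sub, "power", sub), dtype=np.float64)
        img_c = _crop(img, spec.crop_margin)
        if img_c.shape != ref_c.shape:
            raise ValueError("reference size does not match subimages "
                             "after cropping")
        dx, dy, peak = correlate_images(img_c, ref_c)
        shifts[i] = (dx, dy)
        peaks[i] = peak
    valid = peaks >= spec.peak_threshold
    if not valid.any():
        raise ValueError("all subapertures fell below the correlation "
                         "peak threshold")
    mode = reference_mode if reference_mode is not None else spec.mode
    return ShiftField(shifts, peaks, valid, mode)
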