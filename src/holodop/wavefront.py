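"""Wavefront reconstruction from subaperture shifts.

Two regularisations of the measured slope field are implemented:

* **Modal (Zernike)** - each Zernike mode is split into subapertures and
  its mean local gradient becomes one column of a transition matrix
  ``M`` mapping mode coefficients to per-subaperture (x, y) shift
  couples; the coefficients solve ``M c = y`` in the least-squares
  (Moore-Penrose) sense.  Corner subapertures whose centre lies outside
  the unit circle are excluded.
* **Zonal (gradient integration)** - measured shifts are converted to
  phase slopes, interpolated to the full pupil grid with a smooth
  bivariate spline, and integrated by a curl-minimising least-squares
  (Neumann Poisson) solver.

Because the shift origin is arbitrary (the reference image fixes it only
up to a constant, and tip/tilt does not blur the image), both paths
project the measurement onto the zero-mean shift subspace: the mean shift
over the used subapertures is subtracted from the data *and* from the
columns of the transition matrix, which keeps the linear system
self-consistent.

Units: Zernike coefficients are in micrometres of optical path; phase
maps are in radians.  Conversion is ``phase = 2 * pi * path / lambda``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.fft import dctn, idctn
from scipy.interpolate import RectBivariateSpline, griddata

from .core import ComplexFieldStack, Plane
from .shack_hartmann import ShiftField, SubapertureGrid
from .zernike import ZERNIKE_ORDERING, mode_count, modes_for_radial_orders, \
    synthesize, zernike_eval

#: Default wavelength used for micrometre <-> radian conversion (um).
DEFAULT_WAVELENGTH_UM = 0.852


def um_to_rad(path_um, wavelength_um: float = DEFAULT_WAVELENGTH_UM):
    """Optical path (um) to phase (rad): ``2 pi / lambda``."""
    return 2.0 * np.pi * np.asarray(path_um, dtype=np.float64) / wavelength_um


def rad_to_um(phase_rad, wavelength_um: float = DEFAULT_WAVELENGTH_UM):
    """Phase (rad) to optical path (um)."""
    return np.asarray(phase_rad, dtype=np.float64) * wavelength_um / (2.0 * np.pi)


class WavefrontSource(str, enum.Enum):
    ZERNIKE = "zernike"
    GRADIENT_INTEGRATION = "gradient_integration"


@dataclass(frozen=True)
class ZernikeModeSet:
    """Ordered set of Zernike modes (radial order n, azimuthal order m)."""

    modes: tuple
    indexing: str = ZERNIKE_ORDERING

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", tuple(tuple(m) for m in self.modes))

    @classmethod
    def from_radial_orders(cls, n_lo: int, n_hi: int) -> "ZernikeModeSet":
        return cls(tuple(modes_for_radial_orders(n_lo, n_hi)))

    @property
    def p(self) -> int:
        return len(self.modes)


@dataclass
class ZernikeCoefficients:
    """Zernike expansion coefficients in micrometres of optical path."""

    c: np.ndarray
    mode_set: ZernikeModeSet

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.c.shape != (self.mode_set.p,):
            raise ValueError("coefficient vector length must equal the "
                             "number of modes")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("coefficients must be finite")

    def rms(self) -> float:
        """Wavefront RMS in um: the quadrature sum of the coefficients
        (the modes are orthonormal over the unit disk)."""
        return float(np.sqrt(np.sum(self.c**2)))

    def to_wavefront(self, n_px: int, radius_px: float | None = None,
                     wavelength_um: float = DEFAULT_WAVELENGTH_UM
                     ) -> "WavefrontEstimate":
        """Synthesise the phase map (radians) on an ``n_px`` pupil grid."""
        if radius_px is None:
            radius_px = n_px / 2.0
        coords = (np.arange(n_px) - n_px // 2) / radius_px
        x, y = np.meshgrid(coords, coords, indexing="xy")
        path_um = synthesize(list(self.mode_set.modes), self.c, x, y)
        mask = np.hypot(x, y) <= 1.0
        return WavefrontEstimate(um_to_rad(path_um, wavelength_um),
                                 WavefrontSource.ZERNIKE, mask)


@dataclass
class WavefrontEstimate:
    """Pupil-plane phase map in radians over a binary pupil mask."""

    phase: np.ndarray
    source: WavefrontSource
    pupil_mask: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.pupil_mask = np.asarray(self.pupil_mask, dtype=bool)
        if self.phase.shape != self.pupil_mask.shape:
            raise ValueError("phase and pupil_mask shapes differ")
        self.source = WavefrontSource(self.source)
        if not np.all(np.isfinite(self.phase[self.pupil_mask])):
            raise ValueError("phase must be finite inside the pupil mask")
        self.phase = np.where(self.pupil_mask, self.phase, 0.0)

    def rms_rad(self) -> float:
        inside = self.phase[self.pupil_mask]
        return float(np.sqrt(np.mean((inside - inside.mean())**2)))


@dataclass
class TransitionMatrix:
    """``n x p`` matrix of per-subaperture mean Zernike gradients.

    Rows come in (x, y) couples for every subaperture retained by the
    circular-pupil criterion; ``subaperture_map`` lists the grid indices
    (row-major) contributing rows.  Entries are in subimage pixels of
    shift per micrometre of mode coefficient.
    """

    entries: np.ndarray
    subaperture_map: np.ndarray
    mode_set: ZernikeModeSet
    grid: SubapertureGrid

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        self.subaperture_map = np.asarray(self.subaperture_map, dtype=int)
        if self.entries.shape != (2 * len(self.subaperture_map),
                                  self.mode_set.p):
            raise ValueError("entries shape inconsistent with map and modes")

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass
class ResidualReport:
    """Imposed-vs-estimated wavefront error summary.

    ``fraction`` is ``rms_residual / rms_imposed`` and is NaN (with
    ``fraction_defined`` False) when the imposed wavefront is zero.
    """

    rms_imposed: float
    rms_residual: float
    variance_residual: float
    fraction: float
    fraction_defined: bool = True


def _mode_gradient_means(grid: SubapertureGrid, n: int, m: int):
    """Mean (d/dx, d/dy) of mode (n, m) over every subaperture window.

    Gradients are with respect to the normalised pupil coordinate (the
    gridded region spans [-1, 1]).
    """
    span = grid.span_px
    u = (2.0 * np.arange(span) + 1.0 - span) / span
    x, y = np.meshgrid(u, u, indexing="xy")
    z = zernike_eval(n, m, x, y)
    du = 2.0 / span
    gy, gx = np.gradient(z, du)
    s = grid.aperture_px
    ns = grid.n_side
    gx_means = gx.reshape(ns, s, ns, s).mean(axis=(1, 3)).ravel()
    gy_means = gy.reshape(ns, s, ns, s).mean(axis=(1, 3)).ravel()
    return gx_means, gy_means


def build_transition_matrix(grid: SubapertureGrid,
                            modes: ZernikeModeSet,
                            wavelength_um: float = DEFAULT_WAVELENGTH_UM
                            ) -> TransitionMatrix:
    """Assemble the Zernike-modes-to-shifts transition matrix.

    Column ``j`` holds the per-subaperture mean x- and y-gradient of mode
    ``Z_j``, scaled to the subimage shift (pixels) produced by 1 um of
    that mode.  Only subapertures whose centre lies inside the unit
    circle contribute rows.
    """
    retained = np.flatnonzero(grid.inside_circle)
    n_rows = 2 * len(retained)
    if n_rows < modes.p:
        raise ValueError(
            f"underdetermined system: {n_rows} shift components for "
            f"{modes.p} modes ({modes.p - n_rows} short)")
    # shift produced by 1 um of mode j over subaperture i:
    #   s = -(2 / (lambda_um * n_side)) * mean gradient  (see module doc)
    scale = -2.0 / (wavelength_um * grid.n_side)
    entries = np.zeros((n_rows, modes.p))
    for j, (n, m) in enumerate(modes.modes):
        gx_means, gy_means = _mode_gradient_means(grid, n, m)
        entries[0::2, j] = scale * gx_means[retained]
        entries[1::2, j] = scale * gy_means[retained]
    return TransitionMatrix(entries, retained, modes, grid)


def solve_zernike(tm: TransitionMatrix, shifts: ShiftField,
                  demean: bool = True) -> ZernikeCoefficients:
    """Least-squares Zernike coefficients (um) from measured shifts.

    Rows of invalid subapertures are dropped from both sides.  With
    ``demean`` (default) the mean x- and y-shift over the used
    subapertures is removed from the data and from the matrix columns,
    eliminating the arbitrary shift origin of the reference image.
    """
    if len(shifts.shifts) != tm.grid.n_subapertures:
        raise ValueError("shift field does not match the grid")
    keep = shifts.valid[tm.subaperture_map]
    if keep.sum() * 2 < tm.mode_set.p:
        raise ValueError("too few valid subapertures for the mode count")
    rows = np.repeat(keep, 2)
    m = tm.entries[rows].copy()
    used = tm.subaperture_map[keep]
    y = shifts.shifts[used].reshape(-1).copy()  # interleaved (dx, dy)
    if demean:
        for comp in (0, 1):
            sel = np.arange(comp, len(y), 2)
            y[sel] -= y[sel].mean()
            m[sel] -= m[sel].mean(axis=0)
    rank = np.linalg.matrix_rank(m)
    if rank < tm.mode_set.p:
        raise ValueError(
            f"rank-deficient system after row dropping (rank {rank} < "
            f"{tm.mode_set.p} modes)")
    c, *_ = np.linalg.lstsq(m, y, rcond=None)
    return ZernikeCoefficients(c, tm.mode_set)


def poisson_solve_neumann(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Least-squares (curl-minimising) integration of a slope field.

    Frankot-Chellappa spectral integration on mirror-extended slopes:
    ``gx`` is extended odd in x / even in y and ``gy`` odd in y / even in
    x, which makes the implied surface an even periodic function and
    removes wrap-around artefacts; the curl component of the slope field
    is discarded by the least-squares projection.  Slopes are per unit
    pixel; the mean of the result is set to zero.
    """
    if gx.shape != gy.shape or gx.ndim != 2:
        raise ValueError("gx and gy must be 2-D arrays of the same shape")
    ny, nx = gx.shape
    # mirror extension: surface even in both axes => gx odd in x, even in
    # y; gy odd in y, even in x
    gx_e = np.block([[gx, -gx[:, ::-1]], [gx[::-1, :], -gx[::-1, ::-1]]])
    gy_e = np.block([[gy, gy[:, ::-1]], [-gy[::-1, :], -gy[::-1, ::-1]]])
    fy = np.fft.fftfreq(2 * ny)[:, None]
    fx = np.fft.fftfreq(2 * nx)[None, :]
    denom = fx**2 + fy**2
    denom[0, 0] = 1.0
    num = -1j * (fx * np.fft.fft2(gx_e) + fy * np.fft.fft2(gy_e))
    w_hat = num / (2.0 * np.pi * denom)
    w_hat[0, 0] = 0.0
    w = np.fft.ifft2(w_hat).real[:ny, :nx]
    return w - w.mean()


def integrate_gradient(shifts: ShiftField, grid: SubapertureGrid,
                       n_px: int, demean: bool = True) -> WavefrontEstimate:
    """Zonal wavefront reconstruction by direct slope integration.

    Measured shifts are normalised by the subaperture pixel count and
    scaled to phase slopes (``pi * Nx`` per unit normalised coordinate,
    i.e. ``2 pi s / S`` radians per pupil pixel).  The sparse slope grid
    is interpolated to the full ``n_px`` pupil grid with a smooth
    bivariate spline (edge-clamped), invalid subapertures being filled
    from their neighbours first, and integrated by the curl-minimising
    Neumann-Poisson solver.  The result is in radians over the disk
    inscribed in the gridded region.
    """
    ns = grid.n_side
    if len(shifts.shifts) != grid.n_subapertures:
        raise ValueError("shift field does not match the grid")
    valid = shifts.valid.reshape(ns, ns)
    if valid.sum() < 4:
        raise ValueError("need at least 4 valid subapertures to "
                         "interpolate the slope field")
    s = grid.aperture_px
    data = shifts.shifts.copy()
    if demean:
        data -= data[shifts.valid].mean(axis=0)
    # phase slope in rad per pupil pixel; sign per the shift convention
    slope_px = -2.0 * np.pi * data / s
    sx = slope_px[:, 0].reshape(ns, ns)
    sy = slope_px[:, 1].reshape(ns, ns)
    if not valid.all():
        jj, ii = np.meshgrid(np.arange(ns), np.arange(ns), indexing="xy")
        pts = np.stack([ii[valid], jj[valid]], axis=1)
        bad = ~valid
        query = np.stack([ii[bad], jj[bad]], axis=1)
        for comp in (sx, sy):
            vals = comp[valid]
            filled = griddata(pts, vals, query, method="linear")
            nearest = griddata(pts, vals, query, method="nearest")
            filled = np.where(np.isfinite(filled), filled, nearest)
            comp[bad] = filled
    span = grid.span_px
    start = (n_px - span) // 2
    centers = start + np.arange(ns) * s + (s - 1) / 2.0
    k = min(3, ns - 1)
    pix = np.clip(np.arange(n_px, dtype=np.float64),
                  centers[0], centers[-1])
    gx = RectBivariateSpline(centers, centers, sx, kx=k, ky=k)(pix, pix)
    gy = RectBivariateSpline(centers, centers, sy, kx=k, ky=k)(pix, pix)
    phase = poisson_solve_neumann(gx, gy)
    coords = np.arange(n_px) - n_px // 2
    xg, yg = np.meshgrid(coords, coords, indexing="xy")
    mask = np.hypot(xg, yg) <= span / 2.0
    phase = np.where(mask, phase, 0.0)
    inside = phase[mask]
    phase[mask] = inside - inside.mean()
    return WavefrontEstimate(phase, WavefrontSource.GRADIENT_INTEGRATION,
                             mask)


def remove_tip_tilt(w: WavefrontEstimate) -> WavefrontEstimate:
    """Subtract the least-squares plane (piston, tip, tilt) over the mask.

    The residual is orthogonal to piston/tip/tilt over the mask; the
    operation is idempotent.  Tip and tilt translate the image without
    blurring it, so they carry no resolution information.
    """
    mask = w.pupil_mask
    if not mask.any():
        raise ValueError("empty pupil mask")
    ny, nx = w.phase.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    basis = np.stack([np.ones(mask.sum()), xx[mask], yy[mask]], axis=1)
    coef, *_ = np.linalg.lstsq(basis, w.phase[mask], rcond=None)
    plane = coef[0] + coef[1] * xx + coef[2] * yy
    phase = np.where(mask, w.phase - plane, 0.0)
    return WavefrontEstimate(phase, w.source, mask)


def apply_correction(pupil_stack: ComplexFieldStack,
                     w: WavefrontEstimate | np.ndarray) -> ComplexFieldStack:
    """Multiply every pupil frame by ``exp(-i * phase)``.

    The corrector is a unit-modulus phase factor, so the per-frame energy
    is unchanged.
    """
    if pupil_stack.plane != Plane.PUPIL:
        raise ValueError("apply_correction expects a pupil-plane stack")
    phase = np.asarray(getattr(w, "phase", w), dtype=np.float64)
    if phase.shape != pupil_stack.shape[1:]:
        raise ValueError("phase map shape does not match the pupil frames")
    corrected = pupil_stack.field * np.exp(-1j * phase)
    return ComplexFieldStack(corrected, Plane.PUPIL, pupil_stack.z,
                             pupil_stack.config)


def _map_rms_um(w: WavefrontEstimate, mask: np.ndarray,
                wavelength_um: float) -> float:
    vals = w.phase[mask]
    vals = vals - vals.mean()
    return float(rad_to_um(np.sqrt(np.mean(vals**2)), wavelength_um))


def residual_metrics(imposed, estimated,
                     wavelength_um: float = DEFAULT_WAVELENGTH_UM
                     ) -> ResidualReport:
    """RMS error of an estimated wavefront against the imposed one.

    Accepts two :class:`ZernikeCoefficients` on the same mode set
    (compared mode-wise) or two :class:`WavefrontEstimate` maps (compared
    over the intersection of the masks after piston/tip/tilt removal).
    RMS values are in micrometres; the residual variance is in rad^2.
    """
    if isinstance(imposed, ZernikeCoefficients) and \
            isinstance(estimated, ZernikeCoefficients):
        if imposed.mode_set.modes != estimated.mode_set.modes:
            raise ValueError("coefficient sets use different modes")
        rms_imp = imposed.rms()
        residual = ZernikeCoefficients(imposed.c - estimated.c,
                                       imposed.mode_set)
        rms_res = residual.rms()
    elif isinstance(imposed, WavefrontEstimate) and \
            isinstance(estimated, WavefrontEstimate):
        if imposed.phase.shape != estimated.phase.shape:
            raise ValueError("wavefront maps have different shapes")
        mask = imposed.pupil_mask & estimated.pupil_mask
        imp = remove_tip_tilt(WavefrontEstimate(imposed.phase,
                                                imposed.source, mask))
        est = remove_tip_tilt(WavefrontEstimate(estimated.phase,
                                                estimated.source, mask))
        diff = WavefrontEstimate(imp.phase - est.phase, imp.source, mask)
        rms_imp = _map_rms_um(imp, mask, wavelength_um)
        rms_res = _map_rms_um(diff, mask, wavelength_um)
    else:
        raise TypeError("imposed and estimated must both be coefficients "
                        "or both be wavefront maps")
    var_res = float(um_to_rad(rms_res, wavelength_um)**2)
    if rms_imp > 0:
        return ResidualReport(rms_imp, rms_res, var_res, rms_res / rms_imp)
    warnings.warn("imposed wavefront is zero; residual fraction undefined",
                  RuntimeWarning, stacklevel=2)
    return ResidualReport(rms_imp, rms_res, var_res, float("nan"), False)
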