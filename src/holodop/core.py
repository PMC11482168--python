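"""Complex-field bookkeeping and angular-spectrum holography.

The optical model is an in-line near-infrared interferometer imaging the
eye fundus: a fast camera records real-valued interferograms, which are
numerically propagated with the angular-spectrum method to form the
time-resolved complex field in the image plane.  A spatial Fourier
transform moves the field to the pupil (reciprocal) plane where digital
adaptive optics operates.

Conventions used throughout the package
---------------------------------------
* The sign of the reconstruction distance ``z`` is positive when
  propagating from the sensor toward the scene.
* The pupil plane holds the *centred* spatial spectrum: zero frequency at
  index ``N // 2`` (``fftshift`` convention).  The image <-> pupil
  transforms are unitary (``norm="ortho"``), so Parseval's equality holds
  frame by frame.
* Evanescent components of the angular-spectrum transfer function are set
  to zero.
* Coordinates are 0-based with pixel centres at integer indices;
  subaperture windows are half-open index ranges.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field as dataclass_field, replace

import numpy as np


class Plane(str, enum.Enum):
    """Plane in which a complex field stack is expressed."""

    SENSOR = "sensor"
    IMAGE = "image"
    PUPIL = "pupil"


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of the holographic recording.

    Parameters
    ----------
    wavelength:
        Laser wavelength in metres (near-infrared, 852 nm by default).
    pixel_pitch:
        Camera pixel pitch in metres (28 um for the offline camera).
    n_lateral:
        Number of lateral pixels of the (square) sensor frame.
    eye_length:
        Average cornea-to-retina distance in metres.
    lens_focal:
        Focal length of the imaging lens in metres.
    frame_rate:
        Camera frame rate in hertz.
    """

    wavelength: float = 852e-9
    pixel_pitch: float = 28e-6
    n_lateral: int = 768
    eye_length: float = 25e-3
    lens_focal: float = 100e-3
    frame_rate: float = 33e3

    def __post_init__(self) -> None:
        for name in ("wavelength", "pixel_pitch", "eye_length", "lens_focal",
                     "frame_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_lateral < 0:
            raise ValueError("n_lateral must be non-negative")
        if self.n_lateral % 2:
            raise ValueError("n_lateral must be even")

    def magnification(self) -> float:
        """Transverse magnification of the fundus image, f / d_eye."""
        return magnification(self)

    def field_of_view(self) -> float:
        """Lateral extent of the retinal field of view in metres."""
        return field_of_view(self)

    def max_reconstruction_distance(self) -> float:
        """Aliasing-free angular-spectrum distance bound in metres."""
        return max_reconstruction_distance(self)


def magnification(config: OpticalConfig) -> float:
    """Magnification ratio of the retinal image, ``f / d_eye``."""
    return config.lens_focal / config.eye_length


def field_of_view(config: OpticalConfig) -> float:
    """Field of view in the retina plane, ``Nx * d / M`` (metres)."""
    return config.n_lateral * config.pixel_pitch / magnification(config)


def max_reconstruction_distance(config: OpticalConfig) -> float:
    """Largest distance with constant rendered pixel pitch, ``Nx d^2 / lambda``.

    Below this bound the angular-spectrum reconstruction keeps the pixel
    pitch of the sensor; beyond it the kernel aliases.
    """
    return config.n_lateral * config.pixel_pitch**2 / config.wavelength


@dataclass
class InterferogramStack:
    """Raw camera frames (counts) with acquisition metadata."""

    frames: np.ndarray
    config: OpticalConfig = dataclass_field(default_factory=OpticalConfig)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be Nt x Ny x Nx")
        nt, ny, nx = self.frames.shape
        if nt < 2:
            raise ValueError("need at least two frames")
        if ny != nx:
            raise ValueError("square frames expected (Ny == Nx)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("camera counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_field(self) -> "ComplexFieldStack":
        """Promote raw interferograms to a sensor-plane complex field."""
        return ComplexFieldStack(self.frames.astype(np.complex128),
                                 Plane.SENSOR, 0.0, self.config)


@dataclass
class ComplexFieldStack:
    """Time-resolved complex optical field in a named plane.

    ``z`` records the cumulative reconstruction distance applied by
    angular-spectrum propagation (metres, positive toward the scene).
    """

    field: np.ndarray
    plane: Plane = Plane.SENSOR
    z: float = 0.0
    config: OpticalConfig = dataclass_field(default_factory=OpticalConfig)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.complex128)
        if self.field.ndim != 3:
            raise ValueError("field must be Nt x Ny x Nx")
        self.plane = Plane(self.plane)
        if not np.all(np.isfinite(self.field.view(np.float64))):
            raise ValueError("field contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.field.shape[0]

    @property
    def shape(self):
        return self.field.shape

    def energy(self) -> np.ndarray:
        """Per-frame energy (sum of squared moduli)."""
        return np.sum(np.abs(self.field) ** 2, axis=(1, 2))


def _angular_spectrum_kernel(ny: int, nx: int, pitch: float,
                             wavelength: float, z: float) -> np.ndarray:
    """Unitary angular-spectrum transfer function, evanescent part zeroed."""
    fx = np.fft.fftfreq(nx, d=pitch)
    fy = np.fft.fftfreq(ny, d=pitch)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    arg = 1.0 / wavelength**2 - f2
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    kernel = np.where(propagating, np.exp(2j * np.pi * z * kz), 0.0)
    return kernel


def angular_spectrum_propagate(field: ComplexFieldStack, z: float,
                               strict: bool = True) -> ComplexFieldStack:
    """Propagate a sensor- or image-plane field stack by a distance ``z``.

    The transfer function is unitary on propagating components, so the
    per-frame energy is conserved (up to evanescent content, zeroed).

    Parameters
    ----------
    field:
        Stack in the sensor or image plane.
    z:
        Propagation distance in metres; positive toward the scene.
    strict:
        If True, exceeding the aliasing bound
        :func:`max_reconstruction_distance` raises; otherwise a warning is
        emitted and the propagation proceeds.
    """
    if field.plane == Plane.PUPIL:
        raise ValueError("angular-spectrum propagation operates in the "
                         "sensor or image plane, not the pupil plane")
    zmax = max_reconstruction_distance(field.config)
    if abs(z) > zmax:
        msg = (f"|z| = {abs(z):.3g} m exceeds the aliasing bound "
               f"{zmax:.3g} m")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    if z == 0.0:
        return replace(field, field=field.field.copy())
    nt, ny, nx = field.shape
    kernel = _angular_spectrum_kernel(ny, nx, field.config.pixel_pitch,
                                      field.config.wavelength, z)
    spectrum = np.fft.fft2(field.field, axes=(-2, -1))
    out = np.fft.ifft2(spectrum * kernel, axes=(-2, -1))
    return ComplexFieldStack(out, Plane.IMAGE, field.z + z, field.config)


def to_pupil(field: ComplexFieldStack) -> ComplexFieldStack:
    """Move an image-plane stack to the pupil (reciprocal) plane.

    Unitary 2-D FFT per frame with the zero frequency shifted to the array
    centre.  Round trip with :func:`from_pupil` is the identity to
    floating-point tolerance.
    """
    if field.plane != Plane.IMAGE:
        raise ValueError("to_pupil expects an image-plane field")
    pupil = np.fft.fftshift(
        np.fft.fft2(field.field, axes=(-2, -1), norm="ortho"),
        axes=(-2, -1))
    return ComplexFieldStack(pupil, Plane.PUPIL, field.z, field.config)


def from_pupil(field: ComplexFieldStack) -> ComplexFieldStack:
    """Inverse of :func:`to_pupil`; returns an image-plane stack."""
    if field.plane != Plane.PUPIL:
        raise ValueError("from_pupil expects a pupil-plane field")
    image = np.fft.ifft2(
        np.fft.ifftshift(field.field, axes=(-2, -1)),
        axes=(-2, -1), norm="ortho")
    return ComplexFieldStack(image, Plane.IMAGE, field.z, field.config)
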