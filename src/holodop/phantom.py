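"""Synthetic fundus phantoms for end-to-end validation.

The generator emulates the observables of fundus Doppler holography on a
desk scale: a temporally constant tissue backscatter field (fully
developed speckle), vessel regions carrying stationary band-limited
circular complex Gaussian noise (the simplest process matching the
power-Doppler observable), optional additive detection noise, optional
pupil-plane aberration, and optional additive shifted replicas.  All
randomness flows from a single integer seed through a spawned
`numpy.random.SeedSequence` scheme, so experiments replay bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import line

from .core import ComplexFieldStack, OpticalConfig, Plane, from_pupil, \
    to_pupil
from .replicas import secondary_peak_ratio, translate
from .wavefront import DEFAULT_WAVELENGTH_UM, WavefrontEstimate, \
    WavefrontSource, um_to_rad
from .zernike import synthesize, unit_disk_grid


@dataclass
class VesselCurve:
    """A vessel as a polyline with a width and a Doppler flow band."""

    points: np.ndarray          # (k, 2) array of (row, col) vertices
    width: float                # pixels
    flow_band: tuple            # (f_low, f_high) in hertz
    brightness: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 \
                or len(self.points) < 2:
            raise ValueError("points must be a (k >= 2, 2) polyline")
        if self.width < 1:
            raise ValueError("vessel width must be >= 1 px")
        f_lo, f_hi = self.flow_band
        if not 0 < f_lo < f_hi:
            raise ValueError("flow band must satisfy 0 < f_low < f_high")


@dataclass
class SceneSpec:
    """Full description of a synthetic fundus scene."""

    image_size: int = 256
    vessel_curves: list = dataclass_field(default_factory=list)
    tissue_reflectance: float = 1.0
    speckle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.tissue_reflectance < 0:
            raise ValueError("tissue_reflectance must be >= 0")


@dataclass
class AberrationSpec:
    """Imposed pupil-plane aberration as Zernike terms.

    ``coefficients`` is a list of ``(n, m, value_um)`` entries; optical
    path values are in micrometres.
    """

    coefficients: list

    def __post_init__(self) -> None:
        for n, m, c in self.coefficients:
            if not np.isfinite(c):
                raise ValueError("aberration coefficients must be finite")

    @classmethod
    def from_cylinder(cls, power_diopters: float,
                      pupil_radius_mm: float) -> "AberrationSpec":
        """Astigmatic (cylindrical) lens of given power over a pupil.

        A cylinder of power ``C`` adds the optical path
        ``W = C r^2 cos^2(theta) / 2``, which decomposes into defocus and
        0-degree astigmatism.  The pupil radius fixes the
        dioptre-to-micrometre conversion and must be supplied.
        """
        a_m = pupil_radius_mm * 1e-3
        scale_um = power_diopters * a_m**2 * 1e6
        return cls([(2, 0, scale_um / (8.0 * np.sqrt(3.0))),
                    (2, 2, scale_um / (4.0 * np.sqrt(6.0)))])

    def phase_map(self, n_px: int, radius_px: float | None = None,
                  wavelength_um: float = DEFAULT_WAVELENGTH_UM) -> np.ndarray:
        """Phase screen in radians on an ``n_px`` pupil grid."""
        x, y = unit_disk_grid(n_px, radius_px)
        modes = [(n, m) for n, m, _ in self.coefficients]
        values = [c for _, _, c in self.coefficients]
        return um_to_rad(synthesize(modes, values, x, y), wavelength_um)

    def to_wavefront(self, n_px: int, radius_px: float | None = None,
                     wavelength_um: float = DEFAULT_WAVELENGTH_UM
                     ) -> WavefrontEstimate:
        x, y = unit_disk_grid(n_px, radius_px)
        mask = np.hypot(x, y) <= 1.0
        return WavefrontEstimate(self.phase_map(n_px, radius_px,
                                                wavelength_um),
                                 WavefrontSource.ZERNIKE, mask)


def default_scene(image_size: int = 256, seed: int = 0,
                  n_vessels: int = 9,
                  flow_band: tuple = (4e3, 14e3)) -> SceneSpec:
    """Optic-nerve-head-like scene: a vascular ring around the centre and
    curved vessels radiating outward, widths scaled with the image size."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15C]))
    n = image_size
    scale = n / 256.0
    curves = []
    # vascular ring around the disc margin
    theta = np.linspace(0.0, 2.0 * np.pi, 48)
    ring_r = 0.13 * n
    ring = np.stack([n / 2 + ring_r * np.sin(theta),
                     n / 2 + ring_r * np.cos(theta)], axis=1)
    curves.append(VesselCurve(ring, max(3.0, 7.0 * scale), flow_band,
                              brightness=1.2))
    for i in range(n_vessels):
        ang = 2.0 * np.pi * (i + rng.uniform(-0.25, 0.25)) / n_vessels
        r = 0.10 * n
        pos = np.array([n / 2 + r * np.sin(ang), n / 2 + r * np.cos(ang)])
        direction = ang + rng.uniform(-0.3, 0.3)
        pts = [pos.copy()]
        step = 0.06 * n
        while 4 <= pos[0] <= n - 5 and 4 <= pos[1] <= n - 5:
            direction += rng.uniform(-0.35, 0.35)
            pos = pos + step * np.array([np.sin(direction),
                                         np.cos(direction)])
            pts.append(np.clip(pos, 2, n - 3).copy())
            if len(pts) > 40:
                break
        if len(pts) < 2:
            continue
        width = max(2.0, rng.uniform(4.0, 15.0) * scale)
        curves.append(VesselCurve(np.asarray(pts), width, flow_band,
                                  brightness=rng.uniform(0.7, 1.3)))
    return SceneSpec(image_size=n, vessel_curves=curves, seed=seed)


def mesh_scene(image_size: int = 256, seed: int = 0,
               n_segments: int = 120,
               flow_band: tuple = (4e3, 14e3)) -> SceneSpec:
    """Spatially isotropic capillary-mesh scene: short curved vessel
    segments scattered uniformly over the field.

    Unlike :func:`default_scene` it has no global radial organisation,
    so its autocorrelation decays quickly with lag; it is the scene of
    choice for replica-injection experiments, where the image's own
    long-range self-similarity must stay small compared to the injected
    replica intensities.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE5]))
    n = image_size
    curves = []
    for _ in range(n_segments):
        pos = rng.uniform(8, n - 8, 2)
        ang = rng.uniform(0, 2 * np.pi)
        pts = [pos.copy()]
        for _ in range(int(rng.integers(3, 8))):
            ang += rng.uniform(-0.6, 0.6)
            pos = pos + 0.05 * n * np.array([np.sin(ang), np.cos(ang)])
            pts.append(np.clip(pos, 2, n - 3).copy())
        curves.append(VesselCurve(np.asarray(pts),
                                  max(1.5, rng.uniform(1.5, 3.5) * n / 256.0),
                                  flow_band,
                                  brightness=rng.uniform(0.8, 1.2)))
    return SceneSpec(image_size=n, vessel_curves=curves, seed=seed)


def _rasterize(curve: VesselCurve, n: int) -> np.ndarray:
    """Soft-edged vessel profile in [0, 1] from a polyline and width."""
    skeleton = np.zeros((n, n), dtype=bool)
    pts = np.clip(np.round(curve.points).astype(int), 0, n - 1)
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = line(a[0], a[1], b[0], b[1])
        skeleton[rr, cc] = True
    if not skeleton.any():
        return np.zeros((n, n))
    dist = distance_transform_edt(~skeleton)
    return np.clip(1.0 - (dist - curve.width / 2.0) / 1.5, 0.0, 1.0)


def vessel_maps(scene: SceneSpec):
    """Per-pixel vessel weight in [0, 1] and index of the owning curve
    (-1 where no vessel)."""
    n = scene.image_size
    weight = np.zeros((n, n))
    owner = np.full((n, n), -1, dtype=int)
    for i, curve in enumerate(scene.vessel_curves):
        prof = _rasterize(curve, n)
        better = prof > weight
        weight[better] = prof[better]
        owner[better] = i
    return weight, owner


def _band_limited_noise(rng: np.random.Generator, n_frames: int,
                        n_pix: int, frame_rate: float,
                        band: tuple) -> np.ndarray:
    """Stationary circular complex Gaussian noise, white inside the band
    ``|f| in [f_low, f_high]`` and zero outside, unit mean power."""
    freqs = np.fft.fftfreq(n_frames, d=1.0 / frame_rate)
    sel = (np.abs(freqs) >= band[0]) & (np.abs(freqs) <= band[1])
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise ValueError("flow band contains no DFT bin at this frame "
                         "count and frame rate")
    spectrum = np.zeros((n_frames, n_pix), dtype=np.complex128)
    spectrum[sel] = rng.standard_normal((n_sel, n_pix)) \
        + 1j * rng.standard_normal((n_sel, n_pix))
    x = np.fft.ifft(spectrum, axis=0)
    return x * (n_frames / np.sqrt(2.0 * n_sel))


def generate_phantom_stack(scene: SceneSpec,
                           n_frames: int = 128,
                           frame_rate: float = 33e3,
                           seed: int | None = None,
                           noise_level: float = 0.05,
                           config: OpticalConfig | None = None
                           ) -> ComplexFieldStack:
    """Image-plane complex field stack of the synthetic scene.

    Static tissue (optionally speckled) is temporally constant; vessel
    pixels carry band-limited complex Gaussian noise in their flow band;
    ``noise_level`` adds white circular complex Gaussian detection noise
    (amplitude relative to the unit tissue amplitude).  Deterministic
    under the seed (``scene.seed`` unless overridden).
    """
    if seed is None:
        seed = scene.seed
    if config is None:
        config = OpticalConfig(n_lateral=scene.image_size,
                               frame_rate=frame_rate)
    n = scene.image_size
    ss = np.random.SeedSequence(seed)
    rng_tissue, rng_vessel, rng_noise = \
        [np.random.default_rng(c) for c in ss.spawn(3)]
    amplitude = np.sqrt(scene.tissue_reflectance)
    if scene.speckle:
        static = amplitude / np.sqrt(2.0) * (
            rng_tissue.standard_normal((n, n))
            + 1j * rng_tissue.standard_normal((n, n)))
    else:
        static = np.full((n, n), amplitude, dtype=np.complex128)
    weight, owner = vessel_maps(scene)
    field = np.broadcast_to(static * (1.0 - weight), (n_frames, n, n)).copy()
    for i, curve in enumerate(scene.vessel_curves):
        pix = owner == i
        if not pix.any():
            continue
        dyn = _band_limited_noise(rng_vessel, n_frames, int(pix.sum()),
                                  frame_rate, curve.flow_band)
        field[:, pix] += curve.brightness * weight[pix] * dyn
    if noise_level > 0:
        field += noise_level / np.sqrt(2.0) * (
            rng_noise.standard_normal((n_frames, n, n))
            + 1j * rng_noise.standard_normal((n_frames, n, n)))
    return ComplexFieldStack(field, Plane.IMAGE, 0.0, config)


def impose_aberration(stack: ComplexFieldStack, ab: AberrationSpec,
                      radius_px: float | None = None,
                      wavelength_um: float = DEFAULT_WAVELENGTH_UM
                      ) -> ComplexFieldStack:
    """Multiply the pupil-plane field by ``exp(i * phase)``.

    The stack is moved to the pupil plane by spatial Fourier transform,
    the known aberration phase screen is applied and the stack is moved
    back; energy is conserved (unit-modulus factor, unitary transforms).
    """
    if stack.plane != Plane.IMAGE:
        raise ValueError("impose_aberration expects an image-plane stack")
    n_px = stack.shape[-1]
    phase = ab.phase_map(n_px, radius_px, wavelength_um)
    pupil = to_pupil(stack)
    pupil.field *= np.exp(1j * phase)
    return from_pupil(pupil)


def inject_replicas(image, offsets, intensities):
    """Add shifted copies so the secondary-peak ratio at each offset
    approximates the requested intensity.

    The copy amplitudes are initialised at the requested ratios and
    refined once against the measured autocorrelation ratios.
    """
    img = np.asarray(getattr(image, "power", image), dtype=np.float64)
    offsets = np.atleast_2d(np.asarray(offsets, dtype=int))
    intensities = np.atleast_1d(np.asarray(intensities, dtype=np.float64))
    if len(offsets) != len(intensities):
        raise ValueError("one intensity per offset required")
    if np.any(intensities < 0):
        raise ValueError("intensities must be >= 0")
    if np.all(intensities == 0):
        return img.copy()
    amps = intensities.astype(np.float64).copy()
    out = img.copy()
    for _ in range(4):
        out = img.copy()
        for off, a in zip(offsets, amps):
            if a > 0:
                out = out + a * translate(img, off)
        measured = secondary_peak_ratio(out, offsets)
        # Newton step (the ratio responds ~1:1 to the copy amplitude);
        # the image's own correlation at an offset may make the target
        # unreachable, in which case the amplitude clamps at zero
        amps += intensities - measured
        np.clip(amps, 0.0, None, out=amps)
    return out


def pulsatile_envelope(n_frames: int, frame_rate: float,
                       depth: float = 0.3,
                       cardiac_hz: float = 1.2) -> np.ndarray:
    """Optional slow amplitude modulation mimicking the cardiac cycle."""
    t = np.arange(n_frames) / frame_rate
    return 1.0 + depth * np.sin(2.0 * np.pi * cardiac_hz * t)
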