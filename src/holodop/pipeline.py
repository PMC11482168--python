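"""End-to-end numerical Shack-Hartmann pipelines.

Chains the building blocks into the aberration-measurement loop: image
stack -> pupil -> subaperture power-Doppler subimages -> correlation
shifts -> wavefront estimate (modal or zonal) -> phase correction ->
corrected rendering.  Also hosts the synthetic recovery experiment used
to validate the sensor against numerically imposed aberrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComplexFieldStack, from_pupil, to_pupil
from .doppler import DopplerBand, PowerDopplerImage, power_doppler, \
    svd_clutter_filter
from .phantom import AberrationSpec, default_scene, \
    generate_phantom_stack, impose_aberration
from .shack_hartmann import ReferenceMode, ReferenceSpec, ShiftField, \
    SubapertureGrid, make_reference, measure_shifts, render_subimages, \
    split_pupil
from .wavefront import DEFAULT_WAVELENGTH_UM, ResidualReport, \
    WavefrontEstimate, ZernikeCoefficients, ZernikeModeSet, \
    apply_correction, build_transition_matrix, integrate_gradient, \
    remove_tip_tilt, residual_metrics, solve_zernike


@dataclass
class SensingResult:
    """Intermediate products of one wavefront-sensing pass."""

    shifts: ShiftField
    grid: SubapertureGrid
    subimages: list
    full_image: PowerDopplerImage
    reference: np.ndarray
    pupil: ComplexFieldStack


def sense_shifts(stack: ComplexFieldStack,
                 n_side: int = 7,
                 reference: ReferenceSpec | None = None,
                 band: DopplerBand | None = None,
                 n_reject: int = 2,
                 window: int | None = None,
                 overlap: int = 0) -> SensingResult:
    """Measure subaperture subimage shifts on an image-plane stack."""
    if reference is None:
        reference = ReferenceSpec()
    pupil = to_pupil(stack)
    grid = SubapertureGrid.for_pupil(stack.shape[-1], n_side)
    subs = split_pupil(pupil, grid)
    subimages = render_subimages(subs, band=band,
                                 frame_rate=stack.config.frame_rate,
                                 n_reject=n_reject, window=window,
                                 overlap=overlap)
    full = power_doppler(svd_clutter_filter(stack, n_reject), band=band,
                         window=window, overlap=overlap)
    ref_image = make_reference(full, subimages[grid.central_index],
                               reference)
    shifts = measure_shifts(subimages, ref_image, reference)
    return SensingResult(shifts, grid, subimages, full, ref_image, pupil)


def estimate_zernike(sensing: SensingResult,
                     orders: tuple = (2, 3),
                     wavelength_um: float = DEFAULT_WAVELENGTH_UM
                     ) -> ZernikeCoefficients:
    """Modal wavefront estimate from a sensing pass (coefficients, um)."""
    modes = ZernikeModeSet.from_radial_orders(*orders)
    tm = build_transition_matrix(sensing.grid, modes, wavelength_um)
    return solve_zernike(tm, sensing.shifts)


def estimate_zonal(sensing: SensingResult,
                   n_px: int | None = None) -> WavefrontEstimate:
    """Zonal (gradient-integration) wavefront estimate in radians."""
    if n_px is None:
        n_px = sensing.pupil.shape[-1]
    w = integrate_gradient(sensing.shifts, sensing.grid, n_px)
    return remove_tip_tilt(w)


def correct_stack(stack: ComplexFieldStack,
                  wavefront: WavefrontEstimate | ZernikeCoefficients,
                  radius_px: float | None = None,
                  wavelength_um: float = DEFAULT_WAVELENGTH_UM
                  ) -> ComplexFieldStack:
    """Apply a wavefront corrector to an image-plane stack.

    The estimated phase is conjugated in the pupil plane (``exp(-i Phi)``)
    and the stack is returned to the image plane.
    """
    n_px = stack.shape[-1]
    if isinstance(wavefront, ZernikeCoefficients):
        wavefront = wavefront.to_wavefront(n_px, radius_px, wavelength_um)
    pupil = to_pupil(stack)
    corrected = apply_correction(pupil, wavefront)
    return from_pupil(corrected)


def sharpness(image) -> float:
    """Normalised gradient energy of an image (higher = sharper)."""
    img = np.asarray(getattr(image, "power", image), dtype=np.float64)
    total = np.sum(img**2)
    if total == 0:
        return 0.0
    gy, gx = np.gradient(img)
    return float(np.sum(gx**2 + gy**2) / total)


def recovery_experiment(seeds,
                        n_side: int = 7,
                        orders: tuple = (2, 3),
                        reference: ReferenceSpec | None = None,
                        coefficient_range: tuple = (-1.0, 1.0),
                        image_size: int = 256,
                        n_frames: int = 128,
                        frame_rate: float = 33e3,
                        n_reject: int = 2,
                        noise_level: float = 0.05,
                        band: DopplerBand | None = None,
                        wavelength_um: float = DEFAULT_WAVELENGTH_UM
                        ) -> list[dict]:
    """Impose-and-recover experiment over a list of seeds.

    For each seed a fresh phantom is generated, a random Zernike phase
    screen (the given radial orders, coefficients uniform in
    ``coefficient_range`` micrometres) is imposed in the pupil plane, the
    full sensing + modal-reconstruction pipeline runs with the given
    configuration, and the residual-RMS fraction of the imposed RMS is
    recorded.  Per-seed failures are recorded, not fatal to the batch.
    """
    if reference is None:
        reference = ReferenceSpec()
    modes = ZernikeModeSet.from_radial_orders(*orders)
    lo, hi = coefficient_range
    results = []
    for seed in seeds:
        row = {"seed": int(seed)}
        try:
            scene = default_scene(image_size=image_size, seed=int(seed))
            stack = generate_phantom_stack(scene, n_frames=n_frames,
                                           frame_rate=frame_rate,
                                           noise_level=noise_level)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 0xAB]))
            c_imposed = rng.uniform(lo, hi, size=modes.p)
            grid = SubapertureGrid.for_pupil(image_size, n_side)
            radius_px = grid.span_px / 2.0
            ab = AberrationSpec([(n, m, c) for (n, m), c
                                 in zip(modes.modes, c_imposed)])
            aberrated = impose_aberration(stack, ab, radius_px,
                                          wavelength_um)
            sensing = sense_shifts(aberrated, n_side=n_side,
                                   reference=reference, band=band,
                                   n_reject=n_reject)
            estimated = estimate_zernike(sensing, orders, wavelength_um)
            imposed = ZernikeCoefficients(c_imposed, modes)
            report = residual_metrics(imposed, estimated, wavelength_um)
            row.update(imposed=imposed, estimated=estimated, report=report,
                       n_valid=sensing.shifts.n_valid)
        except Exception as exc:  # noqa: BLE001 - recorded per seed
            row["error"] = repr(exc)
        results.append(row)
    return results


#: Replica offsets used by the standard injection experiment: one
#: vertical/horizontal pair per intensity level.  The pairs are not
#: antiparallel because the autocorrelation is an even function (a
#: replica at +d also peaks at -d), so mirrored offsets with different
#: intensities could not be measured separately.
REPLICA_EXPERIMENT_OFFSETS = ((-104, 6), (6, -104), (80, -8), (-8, 80))


def replica_attenuation_experiment(seeds,
                                   strong: float = 0.0785,
                                   weak: float = 0.0376,
                                   offsets=None,
                                   image_size: int = 256,
                                   n_frames: int = 64,
                                   n_reject: int = 2) -> dict:
    """Inject-and-remove replica benchmark over a list of seeds.

    For each seed, a capillary-mesh phantom is rendered to a
    power-Doppler image, two replica pairs are injected at the ``strong``
    and ``weak`` secondary-peak intensities, the removal procedure runs
    with the four declared offsets, and the per-offset attenuation
    factors (before / after peak ratio) are recorded.

    Returns a dict with per-seed reports and the mean attenuation of the
    strong and weak pairs.
    """
    from .phantom import inject_replicas, mesh_scene
    from .replicas import ReplicaSet, remove_replicas, secondary_peak_ratio

    if offsets is None:
        offsets = REPLICA_EXPERIMENT_OFFSETS
    offsets = np.asarray(offsets, dtype=int)
    scale = image_size / 256.0
    offsets = np.round(offsets * scale).astype(int)
    intensities = np.array([strong, strong, weak, weak])
    runs = []
    for seed in seeds:
        stack = generate_phantom_stack(
            mesh_scene(image_size=image_size, seed=int(seed)),
            n_frames=n_frames)
        image = power_doppler(svd_clutter_filter(stack, n_reject)).power
        dirty = inject_replicas(image, offsets, intensities)
        before = secondary_peak_ratio(dirty, offsets)
        replicas = ReplicaSet(offsets, np.clip(before, 1e-9, 1 - 1e-9))
        _, report = remove_replicas(dirty, replicas)
        report["seed"] = int(seed)
        runs.append(report)
    attenuation = np.array([r["attenuation"] for r in runs])
    return {
        "runs": runs,
        "offsets": offsets.tolist(),
        "mean_attenuation_strong": float(attenuation[:, :2].mean()),
        "mean_attenuation_weak": float(attenuation[:, 2:].mean()),
    }


def mean_residual_fraction(results: list[dict]) -> float:
    """Mean residual-RMS fraction over the successful runs of a batch."""
    fractions = [r["report"].fraction for r in results if "report" in r
                 and r["report"].fraction_defined]
    if not fractions:
        raise ValueError("no successful runs with a defined fraction")
    return float(np.mean(fractions))
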