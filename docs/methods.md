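# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `holodop`. Empirical statements below are the ones the
test suite and `scripts/acceptance.py` actually compute.

## Optical model and conventions

The recording is modelled as an in-line interferometer: a high-speed
camera (33 kHz, 28 µm pitch, 768² pixels in the clinical-scale
configuration) samples interferograms of near-infrared light (852 nm)
backscattered by the fundus. Derived constants follow directly from the
geometry: transverse magnification `M = f / d_eye`, retinal field of view
`Nx·d / M`, and the aliasing-free angular-spectrum range `z < Nx·d²/λ`.

Conventions used consistently throughout:

* **z sign** — positive `z` propagates from the sensor toward the scene.
* **Pupil plane** — the centred spatial spectrum of the image-plane
  field (`fftshift` convention, zero frequency at index `N // 2`); the
  image↔pupil transforms are unitary, so Parseval's equality holds per
  frame. The angular-spectrum kernel zeroes evanescent components; at
  these pixel pitches (≫ λ/2) no propagating content is lost and the
  transfer function is exactly unitary.
* **Coordinates** — 0-based, pixel centres at integer indices, origin of
  normalised pupil coordinates at index `N // 2`; subaperture windows
  are half-open index ranges. A consequence of the even-grid origin is
  that the rasterised unit disk is one pixel asymmetric; quantities that
  depend on exact disk symmetry (e.g. the pixel mean of defocus) carry
  an O(1/N) discretisation bias, which the piston/tip/tilt removal
  absorbs.
* **Units** — Zernike coefficients in micrometres of optical path, phase
  maps in radians, `phase = 2π · path / λ`. Zernike modes use the
  orthonormal (Noll) normalisation, so the wavefront RMS of a
  combination is the quadrature sum of its coefficients; mode sets are
  declared by radial-order ranges (orders 2–5 ⇒ 18 modes).

## Doppler rendering

Clutter rejection removes the `n_reject` leading singular components of
the `Nt × (Ny·Nx)` Casorati matrix, computed through the `Nt × Nt`
temporal Gram matrix (equivalent to the SVD projection, and cheap at
these frame counts). The power-Doppler image sums `|FFT|²` over the DFT
bins with `f_low ≤ |f| ≤ f_high` (inclusive edges) per short-time
window and averages windows; with the full band and one full-length
window it equals the temporal mean squared modulus.

Defaults: band 3–16.5 kHz, one window spanning the whole sequence (an
acquisition batch is rendered as one block), `n_reject = 30` for
512-frame clinical-scale batches. The synthetic experiments use
`n_reject = 2`: the phantom's static tissue is exactly rank one by
construction, so two components suffice and higher values would only
discard vessel signal from the shorter (128-frame) desk-scale sequences.

## Numerical Shack-Hartmann sensor

The pupil is split into `n_side²` square, non-overlapping, hard-masked
windows. A window's centre in normalised coordinates is
`(2i + 1 − n)/n`; windows whose centre lies farther than half a
subaperture width outside the unit circle (`|c| > 1 + 1/n_side`) are
excluded from wavefront fitting — on a 7×7 grid exactly the four
corners (|c| = √2·6/7 ≈ 1.21), while the edge-adjacent cells
(|c| ≈ 1.03), which still overlap the pupil substantially, are kept.

Each window is inverse-transformed on its own S×S grid, clutter-filtered
and band-integrated, giving a subimage with the full field of view at
resolution reduced by the support ratio. With the centred-spectrum
convention, a pupil phase ramp of slope `a` rad/pupil-pixel translates a
subimage by `−a·S/(2π)` pixels; this single relation calibrates both
reconstruction paths.

**Shift measurement.** Subimages and the reference are cropped by
`crop_margin = 0.25` per edge (the borders' angular composition differs
across the field of view on real data), mean-subtracted, and correlated
with the zero-mean normalised cross-correlation evaluated *over the
overlap region of each lag* (overlap-corrected means and variances,
computed by FFT). The overlap correction matters: at desk scale the
imposed aberrations produce shifts up to ~10 px in 36-px subimages, and
a globally normalised correlation systematically favours small lags.
The search is restricted to lags retaining at least 30 % overlap; the
integer peak is refined by two independent three-point parabola fits
(clamped to ±0.5 px, falling back to the integer peak on flat
neighbourhoods). Subapertures whose peak falls below
`peak_threshold = 0.15` are flagged invalid.

**References.** `central` uses the central subaperture's subimage;
`resized_full` anti-alias-resizes the full-pupil image to subimage
dimensions. Either choice fixes the shift origin only up to a constant
(tip/tilt does not blur the image), so both reconstruction paths project
the measurement onto the zero-mean shift subspace: the mean x- and
y-shift over the used subapertures is subtracted from the data *and*
from the transition-matrix columns, keeping the linear system
self-consistent. Without the matrix-side demeaning the constant would
alias into modes with non-zero mean gradient (coma).

**Modal path.** Column `j` of the transition matrix holds the mean
gradient of mode `Z_j` over each retained window (evaluated numerically
on the pupil grid), scaled to subimage pixels of shift per micrometre of
coefficient via the ramp relation above — both sides of `M c = y` are
then dimensionally identical by construction. The written inverse of the
non-square system is implemented as the least-squares (Moore–Penrose)
solution; rank is checked after dropping invalid rows.

**Zonal path.** Shifts are normalised by the subaperture pixel count and
scaled to slopes (`π·Nx` per unit normalised coordinate, i.e. `2π·s/S`
rad/pupil-pixel), invalid cells are filled by linear interpolation from
their neighbours, the sparse slope grid is interpolated to the full
pupil with a bicubic spline (coordinates clamped to the outer window
centres, i.e. edge-value extrapolation), and the slope field is
integrated by Frankot–Chellappa least squares on mirror-extended slopes
(`gx` odd in x / even in y, `gy` the converse), which discards the curl
component and avoids periodic wrap-around. Piston (and on request
tip/tilt) is removed over the pupil mask. A paraboloid slope field
integrates back to 0.1 % RMS; screens inside the fitted mode set agree
with the modal reconstruction to ≤ 5 % RMS.

## Replica removal

Replica offsets are the off-centre local maxima of the linear
(zero-padded, mean-subtracted) autocorrelation; their strength is the
ratio of the secondary peak to the zero-lag value. An exclusion radius
masks the central lobe; on textured images it should exceed the image's
own correlation length (the tests use 30 px for the mesh phantom).

For removal, copies of the mean-removed image are translated onto each
declared offset; the SVD of this shifted-image basis gives orthonormal
eigenimages carrying the spurious features, and the projection of the
image onto their span is subtracted. Two properties motivated this
formulation over subtracting the leading eigenimage from each shifted
copy and summing: (i) at realistic replica strengths (a few per cent)
the shifted copies are mutually quasi-orthogonal, so the leading
eigenimage is a near-degenerate mixture and subtract-and-sum variants
proved numerically unstable — in our experiments they *amplified* the
replicas; (ii) the projection is a least-squares fit, so the subtraction
can never increase the energy of the mean-removed image. The `rank`
parameter limits how many eigenimages are used (default: all
significant ones). Degenerate bases (constant images, linearly dependent
copies) produce a warning and the unchanged input.

Measured on phantom images with replica pairs injected at 7.85 % and
3.76 % secondary-peak intensity, the procedure attenuates the peaks by
well over an order of magnitude on average (the benchmark in
`scripts/acceptance.py` reports the exact figures per seed set).

## Synthetic phantoms

The generator reproduces the observables of fundus power Doppler, not
the optics of the eye:

* static tissue: a temporally constant complex field, optionally with
  fully developed speckle (circular complex Gaussian);
* vessels: polylines with widths, rasterised with a soft 1.5-px edge;
  vessel pixels carry stationary circular complex Gaussian noise that is
  white inside the declared flow band (default 4–14 kHz) and zero
  outside — the simplest process with the right power-Doppler signature;
* detection noise: additive white circular complex Gaussian at a
  configurable amplitude (default 0.05 of the tissue amplitude);
* optional cardiac-style amplitude modulation for ROI-trace tests.

Two scene families are provided. `default_scene` is an optic-nerve-head
layout (vascular ring plus radiating vessels) used for the
aberration-recovery experiments. `mesh_scene` is an isotropic capillary
mesh of thin short segments used for the replica experiments: the radial
layout has seed-dependent long-range self-similarity (autocorrelation up
to ~9 % at 100-px lags) that would confound the calibration of few-per-
cent injected replica ratios, while the mesh keeps that floor near 1 %.
Replica injection scales translated copies of the image and refines the
amplitudes with a few Newton steps against the measured ratios
(amplitudes clamp at zero if the image's own correlation already exceeds
the target).

All randomness flows from one integer seed through spawned
`numpy.random.SeedSequence` children (tissue, vessels, noise, scene
geometry, imposed coefficients), so every experiment replays
bit-identically.

What the phantom deliberately does not emulate: eye motion and the
frame registration it would require, anisoplanatism (the imposed
aberration is a single pupil phase screen), shot/readout noise
statistics of a 12-bit camera, pulsatile flow dynamics beyond the
optional envelope, and the twin-image/curvature artefacts of on-axis
holography (replicas are injected synthetically rather than produced
optically). Passing recovery tests therefore demonstrate the numerical
chain — rendering, shift measurement, reconstruction, correction — under
realistic speckle and Doppler statistics, not robustness to motion or
model mismatch on real eyes.

## Recovery experiments

The standard desk-scale experiment (also the benchmark in
`scripts/acceptance.py`): 256²-px phantoms, 128 frames at 33 kHz, random
Zernike screens of radial orders 2–3 with coefficients uniform in
[−1, 1] µm imposed in the pupil (pupil radius = half the gridded span,
so imposition and estimation share one coordinate system), 7×7 grid,
fit on orders 2–3. The error metric is the residual coefficient RMS as
a fraction of the imposed RMS. These problem sizes keep a single
recovery run at a few seconds and a ten-seed benchmark around a minute
on one CPU; they are deliberately smaller than a clinical acquisition
(768², 512 frames), which the same code handles by changing the
configuration.

## Known limitations

* Least-squares gradient integration responds to a single corrupted,
  un-flagged slope sample with a dipole-shaped error field decaying like
  1/r: the error a two-subaperture distance away is still ~20 % of the
  local peak. The practical defences are the correlation-peak threshold
  (which flags bad subapertures so their slopes are interpolated from
  neighbours) — and the contrast with the modal path, where the same
  outlier perturbs the reconstruction across the whole pupil.
* The shift model is first order: within a subaperture the phase is
  treated as a tilted plane. Strong high-order content within one
  window blurs its subimage rather than translating it, biasing that
  slope sample.
* `locate_replica_offsets` ranks autocorrelation maxima; replicas weaker
  than the image's own long-range self-similarity cannot be found
  automatically and must be declared by offset.
* The dioptre→micrometre conversion for cylinder lenses requires the
  pupil radius, which the recording geometry alone does not fix; it is
  an explicit argument.
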