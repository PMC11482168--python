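"""Zernike polynomials on the unit disk.

Modes are identified by radial order ``n`` and azimuthal order ``m``
(``|m| <= n``, ``n - |m|`` even); negative ``m`` denotes the sine
harmonic.  The normalisation is orthonormal over the unit disk with the
area-average inner product,

    (1 / pi) * integral_{r<=1} Z_a Z_b dA = delta_ab,

i.e. the Noll normalisation: ``sqrt(n + 1)`` for ``m = 0`` and
``sqrt(2 (n + 1))`` otherwise.  With this choice the root-mean-square
wavefront of a combination equals the quadrature sum of its
coefficients.  Mode sets are declared by *radial-order* ranges; radial
order ``n`` contributes ``n + 1`` modes, so orders 2..5 give 18 modes.
"""

from __future__ import annotations

from math import factorial

import numpy as np

#: Ordering convention used for mode lists: radial order ascending,
#: azimuthal order ascending within each radial order (sine before cosine).
ZERNIKE_ORDERING = "radial-order ascending, azimuthal order ascending"


def validate_nm(n: int, m: int) -> None:
    if n < 0:
        raise ValueError("radial order n must be >= 0")
    if abs(m) > n:
        raise ValueError(f"|m| = {abs(m)} exceeds n = {n}")
    if (n - abs(m)) % 2:
        raise ValueError(f"n - |m| must be even, got (n, m) = ({n}, {m})")


def radial_polynomial(n: int, m: int, r: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^|m|(r), evaluated anywhere.

    Being a polynomial it is defined on the whole plane; values outside
    the unit disk are meaningful only as the analytic continuation.
    """
    validate_nm(n, m)
    m = abs(m)
    r = np.asarray(r, dtype=np.float64)
    out = np.zeros_like(r)
    for k in range((n - m) // 2 + 1):
        coeff = ((-1) ** k * factorial(n - k)
                 / (factorial(k) * factorial((n + m) // 2 - k)
                    * factorial((n - m) // 2 - k)))
        out += coeff * r ** (n - 2 * k)
    return out


def zernike_eval(n: int, m: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the orthonormal Zernike mode (n, m) at normalised pupil
    coordinates (x, y).

    Coordinates are in units of the pupil radius; the polynomial is
    evaluated everywhere (callers mask to the disk as needed).
    """
    validate_nm(n, m)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    norm = np.sqrt(n + 1.0) if m == 0 else np.sqrt(2.0 * (n + 1.0))
    radial = radial_polynomial(n, m, r)
    if m == 0:
        angular = 1.0
    elif m > 0:
        angular = np.cos(m * theta)
    else:
        angular = np.sin(-m * theta)
    return norm * radial * angular


def modes_for_radial_orders(n_lo: int, n_hi: int) -> list[tuple[int, int]]:
    """Ordered (n, m) list for radial orders ``n_lo..n_hi`` inclusive."""
    if not 0 <= n_lo <= n_hi:
        raise ValueError("need 0 <= n_lo <= n_hi")
    return [(n, m) for n in range(n_lo, n_hi + 1)
            for m in range(-n, n + 1, 2)]


def mode_count(n_lo: int, n_hi: int) -> int:
    """Number of modes in radial orders ``n_lo..n_hi``: sum of (n + 1)."""
    if not 0 <= n_lo <= n_hi:
        raise ValueError("need 0 <= n_lo <= n_hi")
    return sum(n + 1 for n in range(n_lo, n_hi + 1))


def synthesize(modes: list[tuple[int, int]],
               coefficients: np.ndarray,
               x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linear combination ``sum_j c_j Z_j(x, y)`` of Zernike modes."""
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if len(coefficients) != len(modes):
        raise ValueError("coefficient count does not match mode count")
    out = np.zeros(np.broadcast(x, y).shape, dtype=np.float64)
    for (n, m), c in zip(modes, coefficients):
        if c != 0.0:
            out += c * zernike_eval(n, m, x, y)
    return out


def unit_disk_grid(n_px: int, radius_px: float | None = None):
    """Normalised pupil coordinate grids (x, y) for an ``n_px`` square array.

    The origin is at index ``n_px // 2`` (the centred-spectrum convention)
    and coordinates are scaled by ``radius_px`` (default ``n_px / 2``, the
    inscribed circle).
    """
    if radius_px is None:
        radius_px = n_px / 2.0
    coords = (np.arange(n_px) - n_px // 2) / radius_px
    return np.meshgrid(coords, coords, indexing="xy")
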