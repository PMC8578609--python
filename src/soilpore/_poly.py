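"""Trivariate polynomial fields on voxel grids.

Shared by the background-removal step (fits a low-order polynomial to a
scan) and the phantom generator (imposes a known smooth shading field).
Coordinates are always normalized to [-1, 1] per axis before building the
monomial basis; at total degree 3 the normal equations on raw voxel indices
are hopelessly ill-conditioned.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["monomial_exponents", "evaluate_field", "fit_field"]


def monomial_exponents(degree: int) -> list[tuple[int, int, int]]:
    """Exponent triples (i, j, k) with i+j+k <= degree, in lexicographic order."""
    if degree < 0:
        raise ValueError("degree must be >= 0")
    return [
        (i, j, k)
        for i, j, k in itertools.product(range(degree + 1), repeat=3)
        if i + j + k <= degree
    ]


def _normalized_axes(shape: tuple[int, int, int]):
    return [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n)
        for n in shape
    ]


def _design_matrix(z: np.ndarray, y: np.ndarray, x: np.ndarray, degree: int) -> np.ndarray:
    cols = [
        (z ** i) * (y ** j) * (x ** k)
        for i, j, k in monomial_exponents(degree)
    ]
    return np.stack(cols, axis=-1)


def evaluate_field(shape: tuple[int, int, int], coeffs: np.ndarray, degree: int) -> np.ndarray:
    """Evaluate sum_c coeffs[c] * z^i y^j x^k over the whole grid.

    Evaluated slice-by-slice along z to keep the peak working set at one
    slice's worth of monomials rather than the full volume's.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    exps = monomial_exponents(degree)
    if coeffs.shape != (len(exps),):
        raise ValueError(f"expected {len(exps)} coefficients for degree {degree}, got {coeffs.shape}")
    az, ay, ax = _normalized_axes(shape)
    yy, xx = np.meshgrid(ay, ax, indexing="ij")
    out = np.empty(shape, dtype=np.float64)
    # precompute per-slice the (j,k) part once per distinct (j,k)
    for zi, zv in enumerate(az):
        acc = np.zeros_like(yy)
        for c, (i, j, k) in zip(coeffs, exps):
            if c != 0.0:
                acc += c * (zv ** i) * (yy ** j) * (xx ** k)
        out[zi] = acc
    return out


def fit_field(values: np.ndarray, degree: int, max_samples: int = 200_000, rng=None):
    """Least-squares fit of a trivariate polynomial to a 3D array.

    The fit runs on a regular decimated sub-grid capped at ``max_samples``
    points (a smooth field needs no more); returns ``(coeffs, step)`` where
    ``step`` is the decimation stride actually used along each axis.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError("expected a 3D array")
    n_coeff = len(monomial_exponents(degree))
    if values.size < n_coeff:
        raise ValueError(
            f"{values.size} voxels cannot determine {n_coeff} polynomial coefficients"
        )
    step = max(1, int(np.ceil((values.size / max_samples) ** (1.0 / 3.0))))
    while np.prod([len(range(0, n, step)) for n in values.shape]) < n_coeff:
        step -= 1  # tiny volumes: fall back toward full sampling
    az, ay, ax = _normalized_axes(values.shape)
    zi, yi, xi = (np.arange(0, n, step) for n in values.shape)
    zz, yy, xx = np.meshgrid(az[zi], ay[yi], ax[xi], indexing="ij")
    a = _design_matrix(zz.ravel(), yy.ravel(), xx.ravel(), degree)
    b = values[np.ix_(zi, yi, xi)].ravel()
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    return coeffs, step
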