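"""Trivariate polynomial coordinate transforms and trilinear sampling.

A warp maps physical coordinates through one polynomial per output axis.  The
basis is the full set of trivariate monomials of total degree <= ``degree``
(``C(degree + 3, 3)`` per axis; 56 per axis and 168 coefficients in total at
degree 5).  Coordinates are normalised per axis to [-1, 1] before the
polynomial is evaluated, which keeps simplex optimisation well conditioned;
the identity transform is exactly representable via the linear monomials.

Monomial order: ascending total degree, ties broken lexicographically by the
exponent tuple ``(i, j, k)`` of ``x**i * y**j * z**k``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid

__all__ = [
    "monomial_exponents",
    "n_monomials",
    "WarpParameters",
    "trilinear_sample",
    "out_of_bounds_mask",
    "apply_polynomial_warp",
]


def n_monomials(degree: int) -> int:
    """Number of trivariate monomials of total degree <= ``degree``."""
    return comb(degree + 3, 3)


def monomial_exponents(degree: int) -> list[tuple[int, int, int]]:
    """Exponent tuples in the documented graded order."""
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")
    exps = [
        e
        for e in itertools.product(range(degree + 1), repeat=3)
        if sum(e) <= degree
    ]
    return sorted(exps, key=lambda e: (sum(e), e))


def _design_matrix(u: np.ndarray, degree: int) -> np.ndarray:
    """Monomial design matrix for normalised coordinates ``u`` of shape (..., 3)."""
    exps = monomial_exponents(degree)
    powers = [
        np.stack([u[..., a] ** k for k in range(degree + 1)], axis=0) for a in range(3)
    ]
    cols = [powers[0][i] * powers[1][j] * powers[2][k] for i, j, k in exps]
    return np.stack(cols, axis=-1)


@dataclass
class WarpParameters:
    """Coefficients of a trivariate polynomial coordinate transform.

    Parameters
    ----------
    degree:
        Total polynomial degree (>= 1).
    coefficients:
        Array of shape ``(3, n_monomials(degree))``; row ``a`` holds the
        coefficients of the polynomial producing normalised output axis ``a``.
    bounds:
        ``(3, 2)`` physical (lo, hi) per axis mapped onto [-1, 1] during
        evaluation.
    """

    degree: int
    coefficients: np.ndarray
    bounds: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        m = n_monomials(self.degree)
        if self.coefficients.shape != (3, m):
            raise ValueError(
                "coefficient count inconsistent with declared polynomial degree "
                f"{self.degree}: expected shape (3, {m}), got {self.coefficients.shape}"
            )
        if self.bounds.shape != (3, 2):
            raise ValueError("bounds must have shape (3, 2)")
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("bounds must satisfy lo < hi per axis")

    @property
    def n_parameters(self) -> int:
        return self.coefficients.size

    @classmethod
    def identity(cls, degree: int, bounds: np.ndarray) -> "WarpParameters":
        """The identity transform, exact in the monomial basis."""
        exps = monomial_exponents(degree)
        coeffs = np.zeros((3, len(exps)))
        for a in range(3):
            unit = tuple(1 if b == a else 0 for b in range(3))
            coeffs[a, exps.index(unit)] = 1.0
        return cls(degree=degree, coefficients=coeffs, bounds=np.asarray(bounds, float))

    def normalize(self, points: np.ndarray) -> np.ndarray:
        lo = self.bounds[:, 0]
        hi = self.bounds[:, 1]
        return 2.0 * (np.asarray(points, float) - lo) / (hi - lo) - 1.0

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        lo = self.bounds[:, 0]
        hi = self.bounds[:, 1]
        return (u + 1.0) / 2.0 * (hi - lo) + lo

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply the warp to physical points of shape (..., 3)."""
        u = self.normalize(points)
        v = _design_matrix(u, self.degree) @ self.coefficients.T
        return self.denormalize(v)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "bounds": self.bounds.tolist(),
            "monomial_order": "graded lexicographic in exponents (i, j, k) of x^i y^j z^k",
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpParameters":
        return cls(
            degree=int(d["degree"]),
            coefficients=np.asarray(d["coefficients"], float),
            bounds=np.asarray(d["bounds"], float),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "WarpParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def trilinear_sample(volume: VolumeGrid, points: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of ``volume`` at physical ``points``.

    Points outside the bounding box take the declared ``fill`` value.  A
    single point may be passed as a length-3 sequence.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    idx = volume.physical_to_index(pts).reshape(-1, 3)
    vals = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), idx.T, order=1, mode="constant", cval=fill
    )
    if single:
        return float(vals[0])
    return vals.reshape(pts.shape[:-1])


def out_of_bounds_mask(volume: VolumeGrid, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points falling outside the volume's index bounding box."""
    idx = volume.physical_to_index(np.asarray(points, float))
    shape = np.asarray(volume.spatial_shape, dtype=float)
    return np.any((idx < 0) | (idx > shape - 1), axis=-1)


def apply_polynomial_warp(
    volume: VolumeGrid, warp_params: WarpParameters, fill: float = 0.0
) -> VolumeGrid:
    """Resample ``volume`` through a polynomial warp.

    The output voxel at physical position ``x`` takes the trilinearly
    interpolated input intensity at ``f(x)``; out-of-domain samples take
    ``fill``.
    """
    pts = volume.grid_points()
    warped = warp_params.transform(pts)
    vals = trilinear_sample(volume, warped, fill=fill)
    return VolumeGrid(data=vals, voxel_size=volume.voxel_size)
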