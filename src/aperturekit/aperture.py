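"""Aperture size and shape: perimeter and 3D elliptic Fourier analysis.

Each aperture ring is a closed 3D outline.  Size is its perimeter (mm).
Shape is captured by elliptic Fourier analysis (EFA) extended to three
coordinates: x(t), y(t) and z(t) are each expanded as a truncated
Fourier series in the cumulative chord-length parameter t of the closed
polygon, using the piecewise-linear outline integrals, so no equal
spacing of outline points is assumed.  Five harmonics of six
coefficients each (a_n, b_n per coordinate) describe an outline with 30
numbers; normalisation removes size, 3D orientation and starting-vertex
effects while preserving chirality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

AXES = "xyz"


@dataclass
class ApertureRing:
    """A closed loop of Y outline points (mm); the last point connects
    back to the first implicitly."""

    points: np.ndarray
    ring_index: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("ring points must be an (Y, 3) array")
        if len(self.points) < 3:
            raise ValueError("aperture ring needs at least 3 points")


@dataclass
class EFACoefficientSet:
    """Truncated 3D Fourier description of one closed outline.

    ``coefficients`` has shape (n_harmonics, 3, 2): harmonic n, axis
    (x, y, z), then (a_n, b_n).  ``dc_term`` is the outline's mean
    position; it is dropped by normalisation.
    """

    n_harmonics: int
    coefficients: np.ndarray
    dc_term: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normalised: bool = False

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.n_harmonics, 3, 2):
            raise ValueError(
                f"coefficients must have shape ({self.n_harmonics}, 3, 2)"
            )

    def as_vector(self) -> np.ndarray:
        """Flat length-6n vector ordered a1x,b1x,a1y,b1y,a1z,b1z,a2x,..."""
        # (harmonic, axis, ab) -> flatten with axis-major inside harmonic
        return self.coefficients.reshape(self.n_harmonics, 6).ravel()

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, n_harmonics: int, normalised: bool = False
    ) -> "EFACoefficientSet":
        vec = np.asarray(vec, dtype=float)
        if vec.size != 6 * n_harmonics:
            raise ValueError(f"expected {6 * n_harmonics} values, got {vec.size}")
        return cls(
            n_harmonics=n_harmonics,
            coefficients=vec.reshape(n_harmonics, 3, 2),
            normalised=normalised,
        )

    def harmonic_power(self) -> np.ndarray:
        """Per-harmonic power, sum over axes of (a^2 + b^2) / 2."""
        return 0.5 * (self.coefficients**2).sum(axis=(1, 2))

    def column_names(self) -> list[str]:
        return [
            f"{ab}{n + 1}{ax}"
            for n in range(self.n_harmonics)
            for ax in AXES
            for ab in "ab"
        ]


def perimeter(ring: ApertureRing) -> float:
    """Outline perimeter (mm): sum of edge lengths including the closing
    edge.  Duplicate consecutive points contribute zero length (warned)."""
    pts = ring.points
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(edges, axis=1)
    if np.any(lengths < 1e-12):
        warnings.warn(
            f"ring {ring.ring_index}: duplicate consecutive outline points",
            stacklevel=2,
        )
    return float(lengths.sum())


def efa3d(ring: ApertureRing, n_harmonics: int = 5) -> EFACoefficientSet:
    """Raw 3D elliptic Fourier coefficients of a closed outline.

    Each coordinate is expanded as
        coord(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    with t the cumulative chord length and T the perimeter, using the
    closed-form integrals for a piecewise-linear outline, which makes the
    result robust to unequally spaced outline points.
    """
    pts = ring.points
    if len(pts) < 4:
        raise ValueError("elliptic Fourier analysis needs at least 4 outline points")
    d = np.roll(pts, -1, axis=0) - pts  # (Y, 3) edge vectors
    dt = np.linalg.norm(d, axis=1)
    keep = dt > 1e-12
    d, dt = d[keep], dt[keep]
    if len(dt) < 4:
        raise ValueError("fewer than 4 distinct outline points")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T  # (k+1,) angles at segment boundaries

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, k)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    slope = d / dt[:, None]  # (k, 3) derivative of each coordinate wrt t
    factor = T / (2.0 * np.pi**2 * n**2)  # (H, 1)
    a = factor * (dcos @ slope)  # (H, 3)
    b = factor * (dsin @ slope)

    # DC term: mean position along arc length of the piecewise-linear path
    seg_mid = pts[keep] + 0.5 * d
    dc = (seg_mid * dt[:, None]).sum(axis=0) / T

    coeffs = np.stack([a, b], axis=-1)  # (H, 3, 2)
    return EFACoefficientSet(
        n_harmonics=n_harmonics, coefficients=coeffs, dc_term=dc, normalised=False
    )


def _phase_rotate(coeffs: np.ndarray, phi: float) -> np.ndarray:
    """Shift the parameter origin by phase phi: harmonic n picks up the
    rotation [[cos n phi, sin n phi], [-sin n phi, cos n phi]] acting on
    (a_n, b_n)."""
    H = coeffs.shape[0]
    out = np.empty_like(coeffs)
    for k in range(H):
        c, s = np.cos((k + 1) * phi), np.sin((k + 1) * phi)
        a, b = coeffs[k, :, 0], coeffs[k, :, 1]
        out[k, :, 0] = c * a + s * b
        out[k, :, 1] = -s * a + c * b
    return out


def _candidate(coeffs: np.ndarray, phi: float) -> np.ndarray | None:
    """Normalised coefficient array for one phase branch, or None if the
    branch does not put the start on the semi-major axis."""
    rot = _phase_rotate(coeffs, phi)
    A, B = rot[0, :, 0], rot[0, :, 1]
    a_len, b_len = np.linalg.norm(A), np.linalg.norm(B)
    if a_len < b_len:  # this branch starts on the minor axis
        return None
    normal = np.cross(A, B)
    n_len = np.linalg.norm(normal)
    if n_len < 1e-12 * a_len**2:
        # degenerate (flat) first-harmonic ellipse: build any orthonormal
        # frame completing the major axis
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(A / a_len, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        y_axis = np.cross(ref, A)
        y_axis /= np.linalg.norm(y_axis)
        normal = np.cross(A / a_len, y_axis)
        R = np.vstack([A / a_len, y_axis, normal])
    else:
        R = np.vstack([A / a_len, B / b_len, normal / n_len])
    # rotate every harmonic's a- and b-vectors into the canonical frame,
    # then scale by the semi-major axis length
    out = np.einsum("fc,hcs->hfs", R, rot) / a_len
    return out


def normalise_efa(coeffs: EFACoefficientSet) -> EFACoefficientSet:
    """Normalise for starting point, 3D orientation and size.

    (1) the parameter origin is rotated so the first-harmonic trace
    starts on its semi-major axis; (2) a rigid rotation takes the
    semi-major axis to +x and the first-harmonic ellipse normal to +z;
    (3) all coefficients are divided by the semi-major axis length and
    the DC term is dropped.  The two admissible phase branches (start at
    either end of the major axis) are disambiguated lexicographically,
    so the result is deterministic and invariant to the input's size,
    orientation and starting vertex.  Reflections are NOT normalised
    away: chirality is preserved.
    """
    if coeffs.normalised:
        return coeffs
    c = coeffs.coefficients
    A, B = c[0, :, 0], c[0, :, 1]
    aa, bb, ab = np.dot(A, A), np.dot(B, B), np.dot(A, B)
    if max(aa, bb) < 1e-24:
        raise ValueError("degenerate first harmonic: zero major axis")
    # phase that extremises the first-harmonic radius
    phi0 = 0.5 * np.arctan2(2.0 * ab, aa - bb)
    cands = []
    for phi in (phi0, phi0 + 0.5 * np.pi, phi0 + np.pi, phi0 + 1.5 * np.pi):
        out = _candidate(c, phi)
        if out is not None:
            cands.append(out)
    if not cands:
        raise ValueError("degenerate first harmonic: no major-axis phase found")
    # deterministic branch choice: lexicographically largest flat vector
    best = max(cands, key=lambda arr: tuple(np.round(arr.ravel(), 9)))
    return EFACoefficientSet(
        n_harmonics=coeffs.n_harmonics,
        coefficients=best,
        dc_term=np.zeros(3),
        normalised=True,
    )


def reconstruct_outline(coeffs: EFACoefficientSet, n_points: int) -> ApertureRing:
    """Evaluate the truncated Fourier series at equal parameter steps.

    For raw coefficients the reconstruction converges to the input
    outline as the harmonic count grows; for normalised coefficients it
    yields the canonical-frame unit-size outline.
    """
    if n_points < 3:
        raise ValueError("need at least 3 reconstruction points")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = np.broadcast_to(coeffs.dc_term, (n_points, 3)).copy()
    for k in range(coeffs.n_harmonics):
        n = k + 1
        a, b = coeffs.coefficients[k, :, 0], coeffs.coefficients[k, :, 1]
        pts += np.outer(np.cos(n * t), a) + np.outer(np.sin(n * t), b)
    return ApertureRing(points=pts, ring_index=0)
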