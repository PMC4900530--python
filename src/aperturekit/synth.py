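"""Synthetic helicospiral shells with known analytic geometry.

Gastropod shells grow accretionarily: the aperture sweeps along a
helicospiral trajectory while expanding.  This module generates
retopologised shell meshes from such an idealised model — an
exponentially expanding spiral axis carrying an elliptical generating
curve — together with the exact curvature, torsion and arc length of
the axis, so every estimator in the package can be checked against
closed-form (or machine-precision integrated) truth.  It also produces
the affine-transformed variants (half-size, elongated, depressed) and
the two-shell composite used to probe the method's behaviour under size
and shape manipulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .mesh_io import RetopologisedShellMesh, grid_quads


@dataclass(frozen=True)
class HelicospiralSpec:
    """Parameters of the idealised shell.

    The axis is c(theta) = (R cos theta, +/- R sin theta, z(theta)) with
    R = r0 * exp(k * theta) and z = pitch * (exp(k*theta) - 1) / k
    (-> pitch * theta as k -> 0), the self-similar logarithmic
    helicospiral; k = 0 gives a circular helix, pitch = 0 a planispiral.

    Parameters
    ----------
    r0 : float
        Initial spiral radius, mm.
    k : float
        Exponential expansion rate per radian (whorl expansion).
    pitch : float
        Vertical rise per radian at theta = 0, mm.
    n_whorls : float
        Total number of turns.
    n_apertures, ring_size : int
        Grid dimensions X and Y.
    aperture_axes : (float, float)
        Semi-axes (a, b) of the elliptical generating curve at theta=0, mm.
    aperture_growth : float or None
        Per-radian scale factor of the ellipse; None means exp(k)
        (self-similar growth).
    chirality : str
        "right" (positive torsion) or "left".
    constriction : (float, float, float) or None
        Optional aperture constriction (centre fraction of ontogeny,
        depth, width fraction): a localised Gaussian dip in aperture
        size, stronger on the minor axis so aperture shape changes
        through it, as in shells whose last whorl narrows before the
        final aperture.
    jitter_sd : float
        Optional Gaussian coordinate noise, mm (default 0).
    seed : int
        Seed for the jitter.
    """

    r0: float = 1.0
    k: float = 0.06
    pitch: float = 0.35
    n_whorls: float = 4.5
    n_apertures: int = 90
    ring_size: int = 16
    aperture_axes: tuple[float, float] = (0.6, 0.5)
    aperture_growth: float | None = None
    chirality: str = "right"
    constriction: tuple[float, float, float] | None = None
    jitter_sd: float = 0.0
    seed: int = 0
    shell_id: str = "synthetic"

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n_apertures < 3:
            raise ValueError("need at least 3 apertures")
        if self.ring_size < 4:
            raise ValueError("need at least 4 vertices per ring")
        if min(self.aperture_axes) <= 0:
            raise ValueError("aperture semi-axes must be positive")
        if self.chirality not in ("right", "left"):
            raise ValueError("chirality must be 'right' or 'left'")
        if self.n_whorls <= 0:
            raise ValueError("n_whorls must be positive")


@dataclass
class AnalyticTruth:
    """Exact axis curvature, torsion and arc length per aperture."""

    kappa: np.ndarray
    tau: np.ndarray
    arc_length: np.ndarray
    theta: np.ndarray


def _axis_derivatives(spec: HelicospiralSpec, theta: np.ndarray):
    """Analytic c, c', c'', c''' of the helicospiral axis, shape (n, 3)."""
    k, r0, pitch = spec.k, spec.r0, spec.pitch
    sign = 1.0 if spec.chirality == "right" else -1.0
    R = r0 * np.exp(k * theta)
    ct, st = np.cos(theta), np.sin(theta)

    c = np.column_stack([R * ct, sign * R * st, np.zeros_like(theta)])
    d1 = np.column_stack(
        [R * (k * ct - st), sign * R * (k * st + ct), np.zeros_like(theta)]
    )
    d2 = np.column_stack(
        [
            R * ((k**2 - 1) * ct - 2 * k * st),
            sign * R * ((k**2 - 1) * st + 2 * k * ct),
            np.zeros_like(theta),
        ]
    )
    d3 = np.column_stack(
        [
            R * ((k**3 - 3 * k) * ct - (3 * k**2 - 1) * st),
            sign * R * ((k**3 - 3 * k) * st + (3 * k**2 - 1) * ct),
            np.zeros_like(theta),
        ]
    )
    e = np.exp(k * theta)
    if abs(k) > 1e-12:
        c[:, 2] = pitch * (e - 1.0) / k
    else:
        c[:, 2] = pitch * theta
    d1[:, 2] = pitch * e
    d2[:, 2] = pitch * k * e
    d3[:, 2] = pitch * k**2 * e
    return c, d1, d2, d3


def analytic_truth(spec: HelicospiralSpec, theta: np.ndarray) -> AnalyticTruth:
    """Exact curvature/torsion from the analytic derivatives; arc length
    integrated to machine precision."""
    _, d1, d2, d3 = _axis_derivatives(spec, theta)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(d1, axis=1)
    kappa = cross_norm / speed**3
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.einsum("ij,ij->i", cross, d3) / cross_norm**2
    tau = np.where(cross_norm < 1e-14, 0.0, tau)

    def speed_at(th: float) -> float:
        _, d1s, _, _ = _axis_derivatives(spec, np.array([th]))
        return float(np.linalg.norm(d1s[0]))

    arc = np.zeros(len(theta))
    for i in range(1, len(theta)):
        seg, _ = quad(speed_at, theta[i - 1], theta[i], epsabs=1e-12, epsrel=1e-12)
        arc[i] = arc[i - 1] + seg
    return AnalyticTruth(kappa=kappa, tau=tau, arc_length=arc, theta=theta)


def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimising normal/binormal fields along unit tangents
    (double-reflection parallel transport)."""
    T = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    n = len(T)
    N = np.zeros((n, 3))
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(T[0], ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    N[0] = np.cross(T[0], ref)
    N[0] /= np.linalg.norm(N[0])
    for i in range(n - 1):
        # double reflection (Wang et al.): reflect in the bisecting planes
        v1 = T[i + 1] - T[i]  # works with positions replaced by tangents
        c1 = np.dot(v1, v1)
        if c1 < 1e-30:
            N[i + 1] = N[i]
            continue
        nL = N[i] - (2.0 / c1) * np.dot(v1, N[i]) * v1
        tL = T[i] - (2.0 / c1) * np.dot(v1, T[i]) * v1
        v2 = T[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            N[i + 1] = nL
        else:
            N[i + 1] = nL - (2.0 / c2) * np.dot(v2, nL) * v2
        N[i + 1] -= np.dot(N[i + 1], T[i + 1]) * T[i + 1]
        N[i + 1] /= np.linalg.norm(N[i + 1])
    B = np.cross(T, N)
    return N, B


def generate_shell(spec: HelicospiralSpec) -> tuple[RetopologisedShellMesh, AnalyticTruth]:
    """Build the ring-grid mesh and its exact axis geometry.

    Aperture rings are ellipses in the axis's rotation-minimising normal
    plane, placed so that vertex 0 of every ring lies exactly on the
    axis curve — the marker-vertex trajectory therefore *is* the
    analytic helicospiral and the returned truth applies to it directly.
    """
    X, Y = spec.n_apertures, spec.ring_size
    theta = np.linspace(0.0, 2.0 * np.pi * spec.n_whorls, X)
    truth = analytic_truth(spec, theta)
    c, d1, _, _ = _axis_derivatives(spec, theta)
    N, B = _transport_frames(d1)

    growth = spec.aperture_growth if spec.aperture_growth is not None else np.exp(spec.k)
    scales = growth**theta
    a, b = spec.aperture_axes
    a_fac = np.ones(X)
    b_fac = np.ones(X)
    if spec.constriction is not None:
        centre, depth, width = spec.constriction
        frac = theta / theta[-1]
        dip = depth * np.exp(-0.5 * ((frac - centre) / width) ** 2)
        a_fac = 1.0 - 0.5 * dip  # minor axis narrows roughly twice as much
        b_fac = 1.0 - dip
    phi = 2.0 * np.pi * np.arange(Y) / Y

    rings = np.empty((X, Y, 3))
    for i in range(X):
        # vertex 0 (phi=0) coincides with the axis point c[i]
        offsets = (
            scales[i] * a * a_fac[i] * (np.cos(phi) - 1.0)[:, None] * N[i]
            + scales[i] * b * b_fac[i] * np.sin(phi)[:, None] * B[i]
        )
        rings[i] = c[i] + offsets
    verts = rings.reshape(X * Y, 3)
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(0.0, spec.jitter_sd, size=verts.shape)
    mesh = RetopologisedShellMesh(
        shell_id=spec.shell_id,
        vertices=verts,
        n_apertures=X,
        ring_size=Y,
        faces=grid_quads(X, Y),
    )
    return mesh, truth


def transform_shell(
    mesh: RetopologisedShellMesh, scale, shell_id: str | None = None
) -> RetopologisedShellMesh:
    """Axis-wise affine scaling: (0.5, 0.5, 0.5) halves the shell,
    (0.5, 0.5, 2) elongates it, (1.5, 1.5, 0.5) depresses it."""
    return mesh.transformed(scale, shell_id=shell_id)


def concatenate_shells(
    base: RetopologisedShellMesh, scale_factor: float, shell_id: str | None = None
) -> RetopologisedShellMesh:
    """Composite shell: a uniformly enlarged copy grown from the aperture.

    The copy (scaled by ``scale_factor`` > 0) is translated so its first
    ring centroid lands on the base's last ring centroid; the copy's
    first ring is then identified with the base's last ring, giving
    2X - 1 apertures in total.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X, Y = base.n_apertures, base.ring_size
    rings = base.rings
    copy = rings * scale_factor
    shift = rings[-1].mean(axis=0) - copy[0].mean(axis=0)
    copy = copy + shift
    verts = np.vstack([rings.reshape(-1, 3), copy[1:].reshape(-1, 3)])
    X_total = 2 * X - 1
    return RetopologisedShellMesh(
        shell_id=shell_id or f"{base.shell_id}_composite",
        vertices=verts,
        n_apertures=X_total,
        ring_size=Y,
        faces=grid_quads(X_total, Y),
    )


def reference_shell_set(seed: int = 0) -> list[RetopologisedShellMesh]:
    """An eight-shell study set mirroring the real + transformed design.

    Four base shells spanning regular to strongly distorted coiling,
    plus a half-size copy of the first, elongated and depressed variants
    of the third, and a composite of the fourth grown into an enlarged
    copy of itself.
    """
    base_specs = [
        replace(
            HelicospiralSpec(),
            constriction=(0.78, 0.30, 0.08),
            shell_id="shell_A_regular",
            seed=seed,
        ),
        replace(
            HelicospiralSpec(),
            r0=0.8,
            k=0.08,
            pitch=0.45,
            n_whorls=4.0,
            aperture_axes=(0.55, 0.4),
            constriction=(0.72, 0.25, 0.10),
            shell_id="shell_B_slight",
            seed=seed + 1,
        ),
        replace(
            HelicospiralSpec(),
            r0=1.2,
            k=0.05,
            pitch=0.25,
            n_whorls=5.0,
            aperture_axes=(0.7, 0.6),
            constriction=(0.85, 0.35, 0.06),
            shell_id="shell_C_strong",
            seed=seed + 2,
        ),
        replace(
            HelicospiralSpec(),
            r0=0.9,
            k=0.10,
            pitch=0.6,
            n_whorls=3.5,
            n_apertures=85,
            aperture_axes=(0.5, 0.45),
            constriction=(0.70, 0.40, 0.09),
            shell_id="shell_D_distorted",
            seed=seed + 3,
        ),
    ]
    meshes = [generate_shell(s)[0] for s in base_specs]
    meshes.append(transform_shell(meshes[0], (0.5, 0.5, 0.5), "shell_A_half"))
    meshes.append(transform_shell(meshes[2], (0.5, 0.5, 2.0), "shell_C_elongated"))
    meshes.append(transform_shell(meshes[2], (1.5, 1.5, 0.5), "shell_C_depressed"))
    meshes.append(concatenate_shells(meshes[3], 2.0, "shell_D_composite"))
    return meshes


def export_theoretical_datasets(
    mesh: RetopologisedShellMesh, outdir, markers=(0,)
) -> dict[str, Path]:
    """Raw-coordinate exports for theoretical shell modelling.

    Writes three CSVs: the generating-curve dataset (every ring's
    outline coordinates), the helicospiral-axis dataset (one or several
    marker-vertex trajectories), and the growth-vector dataset
    (vertex displacements between consecutive rings).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X, Y = mesh.n_apertures, mesh.ring_size
    rings = mesh.rings

    ring_idx = np.repeat(np.arange(X), Y)
    vert_idx = np.tile(np.arange(Y), X)
    gen = pd.DataFrame(
        {
            "ring_index": ring_idx,
            "vertex_index": vert_idx,
            "x_mm": mesh.vertices[:, 0],
            "y_mm": mesh.vertices[:, 1],
            "z_mm": mesh.vertices[:, 2],
        }
    )

    axis_rows = []
    for mk in markers:
        traj = rings[:, mk]
        axis_rows.append(
            pd.DataFrame(
                {
                    "marker_index": mk,
                    "ring_index": np.arange(X),
                    "x_mm": traj[:, 0],
                    "y_mm": traj[:, 1],
                    "z_mm": traj[:, 2],
                }
            )
        )
    axes = pd.concat(axis_rows, ignore_index=True)

    disp = rings[1:] - rings[:-1]  # (X-1, Y, 3)
    gv = pd.DataFrame(
        {
            "ring_index": np.repeat(np.arange(X - 1), Y),
            "vertex_index": np.tile(np.arange(Y), X - 1),
            "dx_mm": disp[..., 0].ravel(),
            "dy_mm": disp[..., 1].ravel(),
            "dz_mm": disp[..., 2].ravel(),
        }
    )

    paths = {
        "generating_curve": outdir / f"{mesh.shell_id}_generating_curve.csv",
        "ontogeny_axes": outdir / f"{mesh.shell_id}_ontogeny_axes.csv",
        "growth_vectors": outdir / f"{mesh.shell_id}_growth_vectors.csv",
    }
    gen.to_csv(paths["generating_curve"], index=False)
    axes.to_csv(paths["ontogeny_axes"], index=False)
    gv.to_csv(paths["growth_vectors"], index=False)
    return paths
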