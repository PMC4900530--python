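"""Aperture ontogeny profiles: assembly, shape PCA, standardisation, plots.

An aperture ontogeny profile records, for every aperture stage of a
shell, the growth-trajectory curvature and torsion, the aperture
perimeter, and (after a pooled PCA of the normalised Fourier
coefficients) one or more aperture shape scores, all parametrised by
cumulative ontogeny-axis length.  Profiles of different shells are made
comparable by resampling each variable at 50 equal fractions of the
shell's own axis length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import aperture as ap
from . import trajectory as tj
from .mesh_io import RetopologisedShellMesh, shell_volume

PROFILE_VARIABLES = ("curvature", "torsion", "aperture_size", "shape_score_1")


@dataclass
class ApertureOntogenyProfile:
    """Per-aperture measurements of one shell, indexed by arc length.

    ``data`` columns: arc_length_mm, curvature, torsion, aperture_size,
    then shape_score_1.. once scores are attached.  ``efa_vectors`` holds
    the normalised Fourier coefficient vector per aperture (rows) so a
    pooled PCA can be fitted across shells.
    """

    shell_id: str
    data: pd.DataFrame
    efa_vectors: np.ndarray
    n_harmonics: int
    volume_mm3: float | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def arc_length(self) -> np.ndarray:
        return self.data["arc_length_mm"].to_numpy()

    def with_scores(self, scores: np.ndarray) -> "ApertureOntogenyProfile":
        """Copy with shape_score_i columns attached (one per PCA column)."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[0] != len(self):
            raise ValueError("score rows must match aperture count")
        data = self.data.copy()
        for k in range(scores.shape[1]):
            data[f"shape_score_{k + 1}"] = scores[:, k]
        return ApertureOntogenyProfile(
            shell_id=self.shell_id,
            data=data,
            efa_vectors=self.efa_vectors,
            n_harmonics=self.n_harmonics,
            volume_mm3=self.volume_mm3,
        )


@dataclass
class ShapePCAModel:
    """Pooled PCA of normalised Fourier coefficient vectors.

    Components are retained up to the smallest k whose cumulative
    explained-variance fraction exceeds 0.90; loadings carry a
    deterministic sign (largest-magnitude loading positive).
    """

    mean: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_fractions: np.ndarray
    n_selected: int

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Scores on the retained components, shape (rows, n_selected)."""
        vectors = np.atleast_2d(vectors)
        return (vectors - self.mean) @ self.loadings[: self.n_selected].T


@dataclass
class OntogenyProfileMatrix:
    """A profile standardised to k points at fractions i/k of axis length."""

    shell_id: str
    data: pd.DataFrame  # k rows; columns: fraction + profile variables
    k: int = 50

    def __len__(self) -> int:
        return len(self.data)

    def series(self, variable: str) -> np.ndarray:
        return self.data[variable].to_numpy()


def build_profile(
    mesh: RetopologisedShellMesh,
    q: int | None = None,
    n_harmonics: int = 5,
    marker_index: int = 0,
    with_volume: bool = True,
) -> ApertureOntogenyProfile:
    """Measure trajectory and aperture variables for every ring.

    ``q`` defaults to the 10%-of-apertures window rule.  Shape scores are
    not attached here: they require a pooled PCA across shells (see
    :func:`fit_shape_pca` / :func:`attach_shape_scores`).
    """
    axis = tj.extract_ontogeny_axis(mesh, marker_index)
    if q is None:
        q = tj.default_window(len(axis))
    traj = tj.estimate_curvature_torsion(axis, q)

    perims = np.empty(mesh.n_apertures)
    vecs = np.empty((mesh.n_apertures, 6 * n_harmonics))
    for i in range(mesh.n_apertures):
        ring = ap.ApertureRing(points=mesh.ring(i), ring_index=i)
        perims[i] = ap.perimeter(ring)
        vecs[i] = ap.normalise_efa(ap.efa3d(ring, n_harmonics)).as_vector()

    data = pd.DataFrame(
        {
            "arc_length_mm": traj.arc_length,
            "curvature": traj.curvature,
            "torsion": traj.torsion,
            "aperture_size": perims,
        }
    )
    vol = shell_volume(mesh).volume if with_volume else None
    return ApertureOntogenyProfile(
        shell_id=mesh.shell_id,
        data=data,
        efa_vectors=vecs,
        n_harmonics=n_harmonics,
        volume_mm3=vol,
    )


def fit_shape_pca(coeff_rows: np.ndarray, variance_threshold: float = 0.90) -> ShapePCAModel:
    """Centred (covariance) PCA of pooled normalised coefficient vectors.

    Retains the smallest number of components whose cumulative explained
    variance exceeds ``variance_threshold``.  Coefficients are
    dimensionless and commensurate after normalisation, so no variable
    scaling is applied.
    """
    X = np.atleast_2d(np.asarray(coeff_rows, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 coefficient rows")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("zero variance: all aperture outlines identical")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.copy()
    for row in loadings:  # deterministic sign: largest |loading| positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    fractions = pca.explained_variance_ratio_
    n_selected = int(
        np.searchsorted(np.cumsum(fractions), variance_threshold, side="right") + 1
    )
    n_selected = min(n_selected, len(fractions))
    return ShapePCAModel(
        mean=pca.mean_,
        loadings=loadings,
        explained_variance_fractions=fractions,
        n_selected=n_selected,
    )


def attach_shape_scores(
    profiles: list[ApertureOntogenyProfile], model: ShapePCAModel | None = None
) -> tuple[list[ApertureOntogenyProfile], ShapePCAModel]:
    """Fit (or reuse) the pooled shape PCA and attach scores per shell.

    Scores are context-dependent: they change when other shells'
    apertures enter the pooled analysis, so profiles meant to be
    compared must be scored against one shared model.
    """
    if model is None:
        pooled = np.vstack([p.efa_vectors for p in profiles])
        model = fit_shape_pca(pooled)
    return [p.with_scores(model.transform(p.efa_vectors)) for p in profiles], model


def resample_profile(profile: ApertureOntogenyProfile, k: int = 50) -> OntogenyProfileMatrix:
    """Linearly interpolate each variable at fractions i/k of axis length.

    Fractions run i/k for i = 1..k (excluding 0, including 1), so the
    undefined pre-growth state is not duplicated and the final aperture
    is always included.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profile) < 2:
        raise ValueError("profile needs at least 2 rows")
    s = profile.arc_length
    total = s[-1]
    fractions = np.arange(1, k + 1) / k
    targets = fractions * total
    out = {"fraction": fractions}
    for col in profile.data.columns:
        if col == "arc_length_mm":
            continue
        out[col] = np.interp(targets, s, profile.data[col].to_numpy())
    return OntogenyProfileMatrix(
        shell_id=profile.shell_id, data=pd.DataFrame(out), k=k
    )


def plot_profile(
    profiles,
    path,
    shared_axes: bool = True,
    n_shape_scores: int = 1,
):
    """Vertical multi-panel scatter of profile variables vs ontogeny axis.

    One stacked panel per variable (curvature, torsion, aperture size,
    then the requested shape scores) against cumulative axis length.
    With ``shared_axes`` the per-variable y-limits are identical across
    shells, so profiles can be compared side by side.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(profiles, ApertureOntogenyProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("need at least one profile")
    variables = ["curvature", "torsion", "aperture_size"] + [
        f"shape_score_{i + 1}" for i in range(n_shape_scores)
    ]
    for p in profiles:
        for v in variables:
            if v not in p.data:
                raise ValueError(
                    f"profile {p.shell_id!r} has no column {v!r}; "
                    "attach shape scores first"
                )
    labels = {
        "curvature": "curvature (mm$^{-1}$)",
        "torsion": "torsion (mm$^{-1}$)",
        "aperture_size": "aperture size (mm)",
    }
    limits = {}
    if shared_axes:
        for v in variables:
            vals = np.concatenate(
                [p.data[v].to_numpy() for p in profiles if v in p.data]
            )
            pad = 0.05 * (vals.max() - vals.min() or 1.0)
            limits[v] = (vals.min() - pad, vals.max() + pad)

    written = []
    for p in profiles:
        fig, axes = plt.subplots(
            len(variables), 1, figsize=(6, 2.2 * len(variables)), sharex=True
        )
        axes = np.atleast_1d(axes)
        for axp, v in zip(axes, variables):
            if v not in p.data:
                raise ValueError(
                    f"profile {p.shell_id!r} has no column {v!r}; "
                    "attach shape scores first"
                )
            axp.scatter(p.arc_length, p.data[v], s=8)
            axp.set_ylabel(labels.get(v, v.replace("_", " ")))
            if shared_axes:
                axp.set_ylim(*limits[v])
        axes[-1].set_xlabel("ontogeny axis (mm)")
        axes[0].set_title(p.shell_id)
        fig.tight_layout()
        from pathlib import Path

        base = Path(path)
        out = base if len(profiles) == 1 else base.with_name(
            f"{base.stem}_{p.shell_id}{base.suffix}"
        )
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
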