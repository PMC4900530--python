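"""Read, write and validate retopologised shell meshes.

A retopologised shell mesh is a stack of X aperture rings, each with Y
vertices, stored row-major (ring 0 = earliest post-protoconch aperture).
Consecutive rings are stitched with quad faces, so every interior vertex
has exactly four neighbours.  The on-disk format is ASCII PLY with quad
faces; a ``comment aperturekit ring_size=<Y>`` line records the ring size
on export and is honoured on import.  Coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class MeshFormatError(ValueError):
    """Raised for unreadable or unsupported PLY input."""


class GridStructureError(ValueError):
    """Raised when a mesh does not form a valid X-by-Y aperture-ring grid."""


@dataclass
class RetopologisedShellMesh:
    """An X-by-Y aperture-ring grid of 3D vertices (mm).

    Parameters
    ----------
    shell_id : str
        Label carried through profiles and dissimilarity matrices.
    vertices : (X*Y, 3) float array
        Row-major by ring: vertex ``i*Y + j`` is vertex ``j`` of ring ``i``.
    n_apertures : int
        X, the number of aperture rings (ontogeny stages).
    ring_size : int
        Y, vertices per ring.
    faces : (n_faces, 4) int array, optional
        Quad connectivity.  Regenerated from the grid when omitted.
    """

    shell_id: str
    vertices: np.ndarray
    n_apertures: int
    ring_size: int
    faces: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.faces is None:
            self.faces = grid_quads(self.n_apertures, self.ring_size)
        else:
            self.faces = np.asarray(self.faces, dtype=int)
        validate_grid(self)

    @property
    def rings(self) -> np.ndarray:
        """Vertices reshaped to (X, Y, 3)."""
        return self.vertices.reshape(self.n_apertures, self.ring_size, 3)

    def ring(self, i: int) -> np.ndarray:
        """The (Y, 3) vertex loop of aperture ring ``i``."""
        return self.rings[i]

    def transformed(self, scale, shell_id: str | None = None) -> "RetopologisedShellMesh":
        """Axis-wise scaled copy; ``scale`` is a scalar or (sx, sy, sz)."""
        s = np.broadcast_to(np.asarray(scale, dtype=float), (3,))
        if np.any(s <= 0):
            raise ValueError("scale factors must be positive")
        return RetopologisedShellMesh(
            shell_id=shell_id or f"{self.shell_id}_scaled",
            vertices=self.vertices * s,
            n_apertures=self.n_apertures,
            ring_size=self.ring_size,
            faces=self.faces.copy(),
        )


@dataclass(frozen=True)
class VolumeResult:
    """Shell volume in mm^3 from the end-capped, consistently oriented mesh."""

    volume: float
    was_capped: bool = True


def grid_quads(n_apertures: int, ring_size: int) -> np.ndarray:
    """Quad faces stitching consecutive rings of an X-by-Y grid.

    Quad ``(i, j)`` connects vertex ``j`` and ``j+1 (mod Y)`` of ring ``i``
    to the matching pair of ring ``i+1``; (X-1)*Y quads in total.
    """
    X, Y = n_apertures, ring_size
    i = np.repeat(np.arange(X - 1), Y)
    j = np.tile(np.arange(Y), X - 1)
    jn = (j + 1) % Y
    return np.column_stack([i * Y + j, i * Y + jn, (i + 1) * Y + jn, (i + 1) * Y + j])


def validate_grid(mesh: RetopologisedShellMesh) -> None:
    """Check the aperture-ring grid invariants; raise GridStructureError."""
    X, Y = mesh.n_apertures, mesh.ring_size
    if X < 3:
        raise GridStructureError(f"need at least 3 aperture rings, got {X}")
    if Y < 4:
        raise GridStructureError(f"need at least 4 vertices per ring, got {Y}")
    if mesh.vertices.ndim != 2 or mesh.vertices.shape[1] != 3:
        raise GridStructureError("vertices must be an (N, 3) array")
    if mesh.vertices.shape[0] != X * Y:
        raise GridStructureError(
            f"vertex count {mesh.vertices.shape[0]} != X*Y = {X}*{Y} = {X * Y}"
        )
    if not np.all(np.isfinite(mesh.vertices)):
        raise GridStructureError("non-finite vertex coordinates")
    if mesh.faces.ndim != 2 or mesh.faces.shape[1] != 4:
        raise GridStructureError("faces must be quads (4 vertex indices each)")
    if mesh.faces.shape[0] != (X - 1) * Y:
        raise GridStructureError(
            f"face count {mesh.faces.shape[0]} != (X-1)*Y = {(X - 1) * Y}"
        )
    if mesh.faces.min() < 0 or mesh.faces.max() >= X * Y:
        raise GridStructureError("face index out of range")
    # each quad must span exactly two consecutive rings
    ring_of = mesh.faces // Y
    lo, hi = ring_of.min(axis=1), ring_of.max(axis=1)
    if np.any(hi - lo != 1):
        raise GridStructureError("a quad does not connect two consecutive rings")
    centroids = mesh.rings.mean(axis=1)
    gaps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    if np.any(gaps < 1e-12):
        raise GridStructureError("two consecutive ring centroids coincide")


def _quads_consistent(Y: int, faces: np.ndarray) -> bool:
    """True when every quad fits the X-by-Y grid under candidate Y."""
    ring_of = faces // Y
    if np.any(ring_of.max(axis=1) - ring_of.min(axis=1) != 1):
        return False
    # each cyclic quad edge is either intra-ring (same ring, adjacent j)
    # or inter-ring (rings differ by 1); exactly two of each per quad
    a, b = faces, np.roll(faces, -1, axis=1)
    same_ring = (a // Y) == (b // Y)
    adjacent = np.isin((a % Y - b % Y) % Y, (1, Y - 1))
    if np.any(same_ring & ~adjacent):
        return False
    return bool(np.all(same_ring.sum(axis=1) == 2))


def _infer_ring_size(n_vertices: int, faces: np.ndarray) -> int:
    """Infer Y from quad connectivity.

    Intra-ring quad edges connect cyclically adjacent indices within one
    ring; the unique Y under which every quad spans exactly two consecutive
    rings with two intra-ring edges wins.
    """
    candidates = [
        Y
        for Y in range(4, n_vertices // 3 + 1)
        if n_vertices % Y == 0 and _quads_consistent(Y, faces)
    ]
    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        raise GridStructureError(
            f"no ring size is consistent with the quad connectivity "
            f"({n_vertices} vertices); pass ring_size_hint"
        )
    raise GridStructureError(
        f"ambiguous ring size, candidates {candidates}; pass ring_size_hint"
    )


def read_retopo_ply(path, ring_size_hint: int | None = None) -> RetopologisedShellMesh:
    """Read a retopologised shell mesh from ASCII PLY.

    The ring size Y is taken from an ``aperturekit ring_size=`` comment if
    present, else from ``ring_size_hint``, else inferred from the quad
    connectivity.  Pairs of triangles forming a grid quad are accepted as
    an equivalent dialect and merged back into quads.

    Raises
    ------
    MeshFormatError
        For binary PLY or malformed headers.
    GridStructureError
        When the vertex/face lists do not form an X-by-Y ring grid.
    """
    path = Path(path)
    with open(path, "r", errors="replace") as fh:
        first = fh.readline().strip()
        if first != "ply":
            raise MeshFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        n_vertices = n_faces = 0
        comment_ring_size = None
        elements = []  # (name, count) in declaration order
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise MeshFormatError(
                        f"{path}: binary PLY is not supported; export as ASCII"
                    )
            elif tok[0] == "comment":
                if len(tok) >= 3 and tok[1] == "aperturekit":
                    for item in tok[2:]:
                        if item.startswith("ring_size="):
                            comment_ring_size = int(item.split("=", 1)[1])
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2])))
                if tok[1] == "vertex":
                    n_vertices = int(tok[2])
                elif tok[1] == "face":
                    n_faces = int(tok[2])
            elif tok[0] == "end_header":
                break
        else:
            raise MeshFormatError(f"{path}: unterminated PLY header")
        if n_vertices == 0 or n_faces == 0:
            raise MeshFormatError(f"{path}: header must declare vertex and face elements")
        if [name for name, _ in elements] != ["vertex", "face"]:
            raise MeshFormatError(f"{path}: expected vertex element followed by face element")

        verts = np.empty((n_vertices, 3), dtype=float)
        for i in range(n_vertices):
            tok = fh.readline().split()
            if len(tok) < 3:
                raise MeshFormatError(f"{path}: truncated vertex list at line {i}")
            verts[i] = [float(tok[0]), float(tok[1]), float(tok[2])]
        raw_faces = []
        for i in range(n_faces):
            tok = fh.readline().split()
            if not tok:
                raise MeshFormatError(f"{path}: truncated face list at face {i}")
            k = int(tok[0])
            if k not in (3, 4):
                raise GridStructureError(
                    f"{path}: face {i} has {k} vertices; only quads "
                    f"(or triangle pairs forming quads) are supported"
                )
            raw_faces.append([int(v) for v in tok[1 : 1 + k]])

    quads = [f for f in raw_faces if len(f) == 4]
    tris = [f for f in raw_faces if len(f) == 3]
    Y = comment_ring_size or ring_size_hint
    if tris:
        if quads:
            raise GridStructureError(f"{path}: mixed triangle and quad faces")
        if Y is None:
            Y = _infer_ring_size_tris(n_vertices, np.asarray(tris))
        quads = _merge_triangle_pairs(np.asarray(tris), Y)
    faces = np.asarray(quads, dtype=int)

    if Y is None:
        Y = _infer_ring_size(n_vertices, faces)
    if n_vertices % Y:
        raise GridStructureError(
            f"{path}: vertex count {n_vertices} not divisible by ring size {Y}"
        )
    X = n_vertices // Y
    return RetopologisedShellMesh(
        shell_id=path.stem, vertices=verts, n_apertures=X, ring_size=Y, faces=faces
    )


def _is_grid_edge(a: int, b: int, Y: int) -> bool:
    """True for intra-ring (adjacent j, same ring) or vertical (same j,
    consecutive rings) edges of the X-by-Y grid; False for diagonals."""
    ra, rb, ja, jb = a // Y, b // Y, a % Y, b % Y
    if ra == rb:
        return (ja - jb) % Y in (1, Y - 1)
    if abs(ra - rb) == 1:
        return ja == jb
    return False


def _merge_triangle_pairs(tris: np.ndarray, Y: int) -> list[list[int]]:
    """Merge triangle pairs sharing a quad diagonal back into grid quads.

    Under a known ring size Y each grid triangle has exactly one non-grid
    edge, the quad diagonal; the two triangles sharing it form the quad.
    """
    by_diag: dict[tuple[int, int], list[np.ndarray]] = {}
    for t in tris:
        diags = [
            tuple(sorted((int(a), int(b))))
            for a, b in zip(t, np.roll(t, -1))
            if not _is_grid_edge(int(a), int(b), Y)
        ]
        if len(diags) != 1:
            raise GridStructureError(
                f"triangle {t.tolist()} does not have exactly one quad "
                f"diagonal under ring size {Y}"
            )
        by_diag.setdefault(diags[0], []).append(t)
    quads = []
    for (d0, d1), pair in sorted(by_diag.items()):
        if len(pair) != 2:
            raise GridStructureError("triangle faces do not pair up into grid quads")
        v1 = next(int(v) for v in pair[0] if int(v) not in (d0, d1))
        v2 = next(int(v) for v in pair[1] if int(v) not in (d0, d1))
        quads.append([d0, v1, d1, v2])
    return quads


def _infer_ring_size_tris(n_vertices: int, tris: np.ndarray) -> int:
    """Infer Y for the triangle dialect: the unique divisor under which
    every triangle has exactly one non-grid (diagonal) edge."""
    candidates = []
    for Y in range(4, n_vertices // 3 + 1):
        if n_vertices % Y:
            continue
        try:
            _merge_triangle_pairs(tris, Y)
        except GridStructureError:
            continue
        candidates.append(Y)
    if len(candidates) == 1:
        return candidates[0]
    kind = "no" if not candidates else f"ambiguous ({candidates})"
    raise GridStructureError(
        f"{kind} ring size consistent with triangle connectivity; pass ring_size_hint"
    )


def write_retopo_ply(mesh: RetopologisedShellMesh, path) -> Path:
    """Write a mesh as ASCII PLY with quad faces.

    Round-trips through :func:`read_retopo_ply` up to the 9-significant-
    digit text precision used for coordinates.
    """
    validate_grid(mesh)
    path = Path(path)
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment aperturekit ring_size={mesh.ring_size}",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines.extend(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices)
    lines.extend("4 " + " ".join(map(str, f)) for f in mesh.faces)
    path.write_text("\n".join(lines) + "\n")
    return path


def shell_volume(mesh: RetopologisedShellMesh) -> VolumeResult:
    """Shell volume (mm^3) with both end rings closed by centroid fans.

    The open tube is capped with a centroid-fan triangulation at each end
    ring, face orientation is made globally consistent, and the volume is
    the absolute signed-tetrahedra sum against the origin (divergence
    theorem).  Self-intersecting caps are not detected.
    """
    validate_grid(mesh)
    rings = mesh.rings
    for end in (0, -1):
        loop = rings[end]
        e = loop - np.roll(loop, 1, axis=0)
        area_vec = 0.5 * np.cross(loop, np.roll(loop, -1, axis=0)).sum(axis=0)
        if np.linalg.norm(area_vec) < 1e-12 or np.all(np.linalg.norm(e, axis=1) < 1e-12):
            raise ValueError("degenerate (zero-area) end ring; cannot cap")

    Y = mesh.ring_size
    n = len(mesh.vertices)
    verts = np.vstack([mesh.vertices, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    tris = []
    for quad in mesh.faces:
        a, b, c, d = quad
        tris.append([a, b, c])
        tris.append([a, c, d])
    c0, c1 = n, n + 1
    first = np.arange(Y)
    last = np.arange(n - Y, n)
    for j in range(Y):
        tris.append([c0, first[j], first[(j + 1) % Y]])
        tris.append([c1, last[(j + 1) % Y], last[j]])
    tm = trimesh.Trimesh(vertices=verts, faces=np.asarray(tris), process=False)
    trimesh.repair.fix_normals(tm)
    return VolumeResult(volume=abs(tm.volume), was_capped=True)
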