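"""Delaunay tessellation of residue points.

The tessellation is built on the full point set with no distance cutoff;
the distance screen (default 9 Å for three-body contacts) is applied
afterwards to select biochemically relevant triangles, leaving the surface
topology — and hence buriedness — untouched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .structure_io import ResiduePoint, coordinates

Face = tuple[int, int, int]
Edge = tuple[int, int]


@dataclass(frozen=True)
class Tessellation:
    """Tetrahedra over residue points plus derived subsimplices.

    Faces are sorted residue-index triples with an occurrence count in
    {1, 2}: a Delaunay triangle is shared by at most two tetrahedra.
    """

    points: tuple[ResiduePoint, ...]
    tetrahedra: tuple[tuple[int, int, int, int], ...]
    face_counts: dict[Face, int]
    edges: tuple[Edge, ...]
    vertices: tuple[int, ...]

    @property
    def faces(self) -> list[Face]:
        return sorted(self.face_counts)

    @property
    def T(self) -> int:
        return len(self.tetrahedra)

    def coords(self) -> np.ndarray:
        return coordinates(list(self.points))

    def edge_length(self, edge: Edge) -> float:
        xyz = self.coords()
        return float(np.linalg.norm(xyz[edge[0]] - xyz[edge[1]]))


def delaunay_tessellation(
    points: list[ResiduePoint],
    *,
    jitter: float | None = None,
    jitter_seed: int = 0,
) -> Tessellation:
    """Compute the Delaunay tessellation (quickhull via Qhull).

    Tetrahedra satisfy the empty-circumsphere property.  ``jitter``, if
    given, adds a deterministic perturbation of that magnitude (Å) to break
    cospherical/degenerate configurations reproducibly.
    """
    if len(points) < 4:
        raise ValueError(f"need at least 4 points, got {len(points)}")
    xyz = coordinates(points)
    if jitter:
        rng = np.random.default_rng(jitter_seed)
        xyz = xyz + rng.normal(scale=jitter, size=xyz.shape)
    try:
        tri = Delaunay(xyz)
    except QhullError as exc:
        raise ValueError(
            "degenerate point set (coplanar or coincident points); "
            "consider the jitter option"
        ) from exc
    if tri.simplices.shape[1] != 4:
        raise ValueError("input points are coplanar; no 3D tessellation exists")

    tetrahedra = tuple(
        tuple(sorted(int(i) for i in simplex)) for simplex in tri.simplices
    )
    face_counts: dict[Face, int] = {}
    edges: set[Edge] = set()
    for tet in tetrahedra:
        for face in itertools.combinations(tet, 3):
            face_counts[face] = face_counts.get(face, 0) + 1
        for edge in itertools.combinations(tet, 2):
            edges.add(edge)
    bad = {f: n for f, n in face_counts.items() if n > 2}
    if bad:
        raise ValueError(f"invalid tessellation: faces in >2 tetrahedra: {bad}")
    vertices = tuple(sorted({i for tet in tetrahedra for i in tet}))
    return Tessellation(
        points=tuple(points),
        tetrahedra=tetrahedra,
        face_counts=face_counts,
        edges=tuple(sorted(edges)),
        vertices=vertices,
    )


def screen_faces(tess: Tessellation, cutoff: float = 9.0) -> list[Face]:
    """Faces all three of whose edge lengths are at most ``cutoff`` Å.

    Purely a selection: buriedness flags are unaffected.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = tess.coords()
    kept = []
    for face in tess.faces:
        i, j, k = face
        if (
            np.linalg.norm(xyz[i] - xyz[j]) <= cutoff
            and np.linalg.norm(xyz[i] - xyz[k]) <= cutoff
            and np.linalg.norm(xyz[j] - xyz[k]) <= cutoff
        ):
            kept.append(face)
    return kept
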