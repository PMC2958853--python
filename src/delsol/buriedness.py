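"""Combinatorial buriedness of Delaunay contacts.

A triangle is *Delaunay buried* iff it belongs to two tetrahedra of the
tessellation; a triangle in at most one tetrahedron is on the surface
(non-buried).  An edge or vertex is non-buried iff it belongs to at least
one non-buried triangle.  From these flags every two-body contact falls in
one of 4 buriedness classes (0-3) and every three-body contact in one of 9
classes (0-8), from fully surface to fully buried.  Connectivity classes
(0-2) count backbone-bonded pairs within a triangle.

Class index convention for three-body contacts: the 9 valid buried/surface
configurations of a triangle's 7 component simplices are sorted by total
number of buried components ascending, ties broken by number of buried
edges ascending.  This reproduces the anchors fixed by the definitions:
class 0 fully surface, class 1 only the face buried, class 5 all vertices
on the surface with edges and face buried, class 8 fully buried.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .tessellation import Edge, Face, Tessellation


@dataclass
class BuriednessMap:
    """Buried / non-buried flag per face, edge, and vertex (True = buried)."""

    face_buried: dict[Face, bool]
    edge_buried: dict[Edge, bool]
    vertex_buried: dict[int, bool]


def assign_buriedness(tess: Tessellation) -> BuriednessMap:
    """Assign buriedness flags in a constant number of passes over the faces.

    Pass 1 splits the triangles into buried and surface lists from their
    occurrence counts; pass 2 first marks every subsimplex of a buried face
    as buried, then overrides with non-buried for every subsimplex of a
    surface face (a vertex/edge is non-buried if ANY containing triangle
    is non-buried).  Class assignment is the third pass, done on demand.
    O(T) time and space in the number of tetrahedra.
    """
    buried_faces = []
    surface_faces = []
    for face, n in tess.face_counts.items():
        (buried_faces if n == 2 else surface_faces).append(face)

    edge_buried = {e: False for e in tess.edges}
    vertex_buried = {v: False for v in tess.vertices}
    for face in buried_faces:
        for e in itertools.combinations(face, 2):
            edge_buried[e] = True
        for v in face:
            vertex_buried[v] = True
    for face in surface_faces:
        for e in itertools.combinations(face, 2):
            edge_buried[e] = False
        for v in face:
            vertex_buried[v] = False

    face_buried = {f: tess.face_counts[f] == 2 for f in tess.face_counts}
    return BuriednessMap(face_buried, edge_buried, vertex_buried)


def two_body_class(edge: Edge, bmap: BuriednessMap) -> int:
    """Buriedness class 0-3 of an edge: number of buried component simplices."""
    edge = tuple(sorted(edge))
    if edge not in bmap.edge_buried:
        raise KeyError(f"edge {edge} not in tessellation")
    n = int(bmap.edge_buried[edge])
    n += int(bmap.vertex_buried[edge[0]]) + int(bmap.vertex_buried[edge[1]])
    return n


# (face buried, n buried edges, n buried vertices) -> class index; see module
# docstring for the ordering rule.
_TRIANGLE_CLASS = {
    (False, 0, 0): 0,
    (True, 0, 0): 1,
    (True, 1, 0): 2,
    (True, 2, 0): 3,
    (True, 2, 1): 4,
    (True, 3, 0): 5,
    (True, 3, 1): 6,
    (True, 3, 2): 7,
    (True, 3, 3): 8,
}


def three_body_class(face: Face, bmap: BuriednessMap) -> int:
    """Buriedness class 0-8 of a triangle."""
    face = tuple(sorted(face))
    if face not in bmap.face_buried:
        raise KeyError(f"face {face} not in tessellation")
    fb = bmap.face_buried[face]
    ne = sum(
        bmap.edge_buried[e] for e in itertools.combinations(face, 2)
    )
    nv = sum(bmap.vertex_buried[v] for v in face)
    try:
        return _TRIANGLE_CLASS[(fb, ne, nv)]
    except KeyError:
        raise ValueError(
            f"invalid buriedness configuration for face {face}: "
            f"face_buried={fb}, buried_edges={ne}, buried_vertices={nv} "
            "(corrupted buriedness map)"
        ) from None


def connectivity_class(face: Face) -> int:
    """Connectivity class 0-2: number of sequence-adjacent residue pairs."""
    r1, r2, r3 = sorted(face)
    if len({r1, r2, r3}) != 3:
        raise ValueError(f"face indices must be distinct: {face}")
    return sum(b - a == 1 for a, b in [(r1, r2), (r2, r3), (r1, r3)])


def classify_faces(
    tess: Tessellation, bmap: BuriednessMap, faces: list[Face] | None = None
) -> list[tuple[Face, int, int]]:
    """(face, connectivity c, buriedness b) for the given (or all) faces."""
    if faces is None:
        faces = tess.faces
    return [(f, connectivity_class(f), three_body_class(f, bmap)) for f in faces]


def enumerate_triangle_classes() -> list[tuple[bool, tuple[bool, ...], tuple[bool, ...]]]:
    """All valid triangle buriedness configurations, modulo triangle symmetry.

    A configuration assigns buried/non-buried to the face, 3 edges and 3
    vertices subject to: a non-buried face forces everything non-buried,
    and a non-buried edge forces both its endpoints non-buried.  Exactly 9
    symmetry classes exist.  Returned as (face_buried, edge_flags,
    vertex_flags) canonical representatives, in class-index order.
    """
    # vertices 0,1,2; edge m is opposite vertex m, i.e. joins the other two
    edge_pairs = [(1, 2), (0, 2), (0, 1)]
    perms = list(itertools.permutations(range(3)))
    seen = set()
    configs = []
    for fb in (False, True):
        for eflags in itertools.product((False, True), repeat=3):
            for vflags in itertools.product((False, True), repeat=3):
                if not fb and (any(eflags) or any(vflags)):
                    continue  # surface face forces all components surface
                if fb:
                    ok = all(
                        eflags[m] or not (vflags[a] or vflags[b])
                        for m, (a, b) in enumerate(edge_pairs)
                    )
                    if not ok:
                        continue
                # canonicalize under the symmetric group on vertices
                orbit = min(
                    (
                        tuple(eflags[p[m]] for m in range(3)),
                        tuple(vflags[p[m]] for m in range(3)),
                    )
                    for p in perms
                )
                if (fb, orbit) in seen:
                    continue
                seen.add((fb, orbit))
                configs.append((fb, orbit[0], orbit[1]))
    configs.sort(
        key=lambda cfg: (int(cfg[0]) + sum(cfg[1]) + sum(cfg[2]), sum(cfg[1]))
    )
    return configs


def enumerate_edge_classes() -> list[tuple[bool, tuple[bool, ...]]]:
    """All valid edge buriedness configurations (4), modulo endpoint swap."""
    seen = set()
    configs = []
    for eb in (False, True):
        for vflags in itertools.product((False, True), repeat=2):
            if not eb and any(vflags):
                continue
            orbit = tuple(sorted(vflags))
            if (eb, orbit) in seen:
                continue
            seen.add((eb, orbit))
            configs.append((eb, orbit))
    configs.sort(key=lambda cfg: int(cfg[0]) + sum(cfg[1]))
    return configs
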