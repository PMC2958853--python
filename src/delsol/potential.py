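"""Three-body knowledge-based potential over buriedness classes.

The score of a triangle with amino acids i, j, k, connectivity class c and
buriedness class b is the log-likelihood ratio

    Q(ijk, c, b) = ln[ f(ijk,c,b) / (C(ijk) * a_i * a_j * a_k * p_cb) ]

where f is the observed frequency of that composition within the (c, b)
stratum, a_i the background amino-acid frequencies over the reference
structure set, p_cb the fraction of all counted triplets in stratum (c, b),
and C the combinatorial multiplicity factor (6, 3 or 1 distinct orderings
of the composition).  Natural logarithm; the base only rescales scores.

The total score of a conformation sums w_t * Q_t over triangles in the five
most surface-exposed buriedness classes (b in 0-4); buried classes 5-8 never
contribute.  A mutation is scored as mutant total minus WT total, computed
on the WT geometry over only the triangles whose composition changes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from .buriedness import assign_buriedness, classify_faces
from .structure_io import AMINO_ACIDS, MutationRecord, ResiduePoint, resolve_substitutions
from .tessellation import Face, delaunay_tessellation, screen_faces

logger = logging.getLogger(__name__)

#: triplet type: (aa1, aa2, aa3, c, b) with aa1 <= aa2 <= aa3
TripletKey = tuple[str, str, str, int, int]

#: buriedness classes contributing to the (surface) score
SURFACE_CLASSES = (0, 1, 2, 3, 4)

DEFAULT_CUTOFF = 9.0


def combinatorial_factor(aa_multiset: tuple[str, str, str]) -> int:
    """Distinct orderings of the composition: 3!/prod(multiplicities!)."""
    counts = Counter(aa_multiset)
    denom = 1
    for m in counts.values():
        denom *= math.factorial(m)
    return math.factorial(3) // denom


@dataclass
class StructureAnalysis:
    """A structure carried through tessellation, buriedness, and the screen."""

    points: list[ResiduePoint]
    classified_faces: list[tuple[Face, int, int]]  # (face, c, b), screened

    @property
    def aa_of(self) -> dict[int, str]:
        return {p.seq_index: p.aa for p in self.points}


def analyze_structure(
    points: list[ResiduePoint],
    cutoff: float = DEFAULT_CUTOFF,
    *,
    jitter: float | None = None,
    jitter_seed: int = 0,
) -> StructureAnalysis:
    """Tessellate, assign buriedness on the full tessellation, then screen."""
    tess = delaunay_tessellation(points, jitter=jitter, jitter_seed=jitter_seed)
    bmap = assign_buriedness(tess)
    kept = screen_faces(tess, cutoff)
    return StructureAnalysis(points=points, classified_faces=classify_faces(tess, bmap, kept))


def triplet_key(aas: tuple[str, str, str], c: int, b: int) -> TripletKey:
    a1, a2, a3 = sorted(aas)
    return (a1, a2, a3, c, b)


@dataclass
class PotentialTable:
    """Counts and log-likelihood scores keyed by triplet type."""

    counts: dict[TripletKey, int]
    a: dict[str, float]  # background amino-acid frequencies
    p_cb: dict[tuple[int, int], float]  # stratum fractions
    Q: dict[TripletKey, float] = field(default_factory=dict)
    pseudocount: float = 0.0

    def q(self, key: TripletKey) -> float:
        """Score of a triplet type; unobserved types are neutral (Q = 0)."""
        return self.Q.get(key, 0.0)

    def rows(self) -> dict[TripletKey, tuple[int, float]]:
        keys = set(self.counts) | set(self.Q)
        return {k: (self.counts.get(k, 0), self.Q.get(k, 0.0)) for k in keys}


def count_triplets(structures: list[StructureAnalysis]) -> PotentialTable:
    """Accumulate triplet counts, AA composition, and stratum fractions."""
    if not structures:
        raise ValueError("empty structure list")
    counts: Counter[TripletKey] = Counter()
    aa_counts: Counter[str] = Counter()
    cb_counts: Counter[tuple[int, int]] = Counter()
    for s in structures:
        aa = s.aa_of
        for p in s.points:
            aa_counts[p.aa] += 1
        for face, c, b in s.classified_faces:
            key = triplet_key(tuple(aa[i] for i in face), c, b)
            counts[key] += 1
            cb_counts[(c, b)] += 1
    n_aa = sum(aa_counts.values())
    n_trip = sum(cb_counts.values())
    if n_trip == 0:
        raise ValueError("structures contribute no screened triplets")
    a = {aa: n / n_aa for aa, n in aa_counts.items()}
    p_cb = {cb: n / n_trip for cb, n in cb_counts.items()}
    return PotentialTable(counts=dict(counts), a=a, p_cb=p_cb)


def log_likelihood(table: PotentialTable, pseudocount: float = 0.0) -> PotentialTable:
    """Fill in Q for every observed triplet type.

    Types never observed in the reference set stay neutral (Q = 0) so they
    carry no information, rather than an infinite penalty; an additive
    pseudocount (default off) spreads mass over the full composition space
    of each observed stratum instead.
    """
    strata: Counter[tuple[int, int]] = Counter()
    for (a1, a2, a3, c, b), n in table.counts.items():
        strata[(c, b)] += n
    n_compositions = None
    if pseudocount:
        from itertools import combinations_with_replacement

        n_compositions = sum(1 for _ in combinations_with_replacement(AMINO_ACIDS, 3))
    q: dict[TripletKey, float] = {}
    n_zero = 0
    for key, n in table.counts.items():
        a1, a2, a3, c, b = key
        stratum_total = strata[(c, b)]
        if pseudocount:
            f = (n + pseudocount) / (stratum_total + pseudocount * n_compositions)
        else:
            if n == 0:
                n_zero += 1
                continue
            f = n / stratum_total
        expected = (
            combinatorial_factor((a1, a2, a3))
            * table.a.get(a1, 0.0)
            * table.a.get(a2, 0.0)
            * table.a.get(a3, 0.0)
            * table.p_cb[(c, b)]
        )
        q[key] = math.log(f / expected)
    if n_zero:
        logger.info("%d zero-count triplet types left neutral (Q = 0)", n_zero)
    return PotentialTable(
        counts=table.counts, a=table.a, p_cb=table.p_cb, Q=q, pseudocount=pseudocount
    )


def estimate_potential(
    structure_sets: list[list[ResiduePoint]],
    cutoff: float = DEFAULT_CUTOFF,
    pseudocount: float = 0.0,
) -> PotentialTable:
    """Convenience pipeline: analyze structures, count, and score."""
    analyses = [analyze_structure(pts, cutoff) for pts in structure_sets]
    return log_likelihood(count_triplets(analyses), pseudocount)


def _weight(weights: dict[TripletKey, float] | None, key: TripletKey) -> float:
    if weights is None:
        return 1.0
    return weights.get(key, 1.0)  # types unseen in training keep weight 1


def total_surface_score(
    analysis: StructureAnalysis,
    potential: PotentialTable,
    weights: dict[TripletKey, float] | None = None,
    *,
    substitutions: dict[int, str] | None = None,
) -> float:
    """Sum of w_t * Q_t over screened faces with b in 0-4.

    ``substitutions`` (seq_index -> mutant AA) rescores the same geometry
    with a mutated sequence — the full-rescoring route used to cross-check
    the delta computation.
    """
    aa = dict(analysis.aa_of)
    if substitutions:
        aa.update(substitutions)
    total = 0.0
    for face, c, b in analysis.classified_faces:
        if b not in SURFACE_CLASSES:
            continue
        key = triplet_key(tuple(aa[i] for i in face), c, b)
        total += _weight(weights, key) * potential.q(key)
    return total


def changed_triplets(
    analysis: StructureAnalysis, substitutions: dict[int, str]
) -> tuple[Counter, Counter]:
    """Triplet types (b 0-4) whose composition changes: (mutant, WT) multisets."""
    aa = analysis.aa_of
    mut_keys: Counter[TripletKey] = Counter()
    wt_keys: Counter[TripletKey] = Counter()
    for face, c, b in analysis.classified_faces:
        if b not in SURFACE_CLASSES:
            continue
        if not any(i in substitutions for i in face):
            continue
        wt_key = triplet_key(tuple(aa[i] for i in face), c, b)
        mut_key = triplet_key(tuple(substitutions.get(i, aa[i]) for i in face), c, b)
        if mut_key == wt_key:
            continue  # composition unchanged (e.g. identity or swapped AAs)
        wt_keys[wt_key] += 1
        mut_keys[mut_key] += 1
    return mut_keys, wt_keys


def mutation_score(
    analysis: StructureAnalysis,
    mutation: MutationRecord | dict[int, str],
    potential: PotentialTable,
    weights: dict[TripletKey, float] | None = None,
) -> float:
    """Score of a mutation: weighted mutant total minus WT total.

    WT geometry is reused for the mutant (side-chain centers unchanged,
    residue identities swapped), so only triangles touching a mutated site
    can contribute; single- and multiple-point mutants are handled uniformly.
    Equals the difference of full rescorings.
    """
    if isinstance(mutation, MutationRecord):
        subs = resolve_substitutions(analysis.points, mutation)
    else:
        subs = mutation
    mut_keys, wt_keys = changed_triplets(analysis, subs)
    s = 0.0
    for key, n in mut_keys.items():
        s += n * _weight(weights, key) * potential.q(key)
    for key, n in wt_keys.items():
        s -= n * _weight(weights, key) * potential.q(key)
    return s
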