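"""Synthetic structures, planted mutant datasets, and brute-force oracles.

The structure generator emits well-separated 3D residue point sets with a
backbone ordering (consecutive residues within bonding distance) so that
all connectivity classes occur; it makes no attempt at physically realistic
protein geometry or side-chain packing.  The planted-dataset generator
builds mutant sets whose labels are determined by a designated subset of
triplet types, giving the trainer a recoverable ground truth.
"""

from __future__ import annotations

import io
import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .buriedness import BuriednessMap
from .potential import (
    PotentialTable,
    StructureAnalysis,
    TripletKey,
    changed_triplets,
)
from .structure_io import AMINO_ACIDS, ONE_TO_THREE, MutationRecord, ResiduePoint
from .tessellation import Tessellation
from .training import LPInstance

#: maximum distance between consecutive residue points (pseudo-bond), Å
BACKBONE_STEP = 4.5


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Parameters of the random-structure generator.

    Defaults give a compact 60-residue chain with residue points at least
    3.5 Å apart (about the side-chain center spacing of folded proteins)
    inside a 30 Å box, which tessellates to a few hundred tetrahedra.
    """

    n_residues: int = 60
    min_separation: float = 3.5
    box_size: float = 30.0
    seed: int = 0
    aa_probs: dict[str, float] | None = None  # default: uniform over 20 AAs


def generate_structure(
    spec: SyntheticStructureSpec, chain_id: str = "A"
) -> list[ResiduePoint]:
    """Self-avoiding random walk of residue points inside a box.

    Deterministic given the spec's seed.  Consecutive points are placed
    within BACKBONE_STEP so sequence-adjacent residues are usually Delaunay
    neighbours, exercising connectivity classes 1 and 2.
    """
    if spec.min_separation > BACKBONE_STEP:
        raise ValueError(
            f"min_separation {spec.min_separation} exceeds the backbone step "
            f"{BACKBONE_STEP}; consecutive residues could not be placed"
        )
    rng = np.random.default_rng(spec.seed)
    aas = list(AMINO_ACIDS)
    if spec.aa_probs is None:
        probs = None
    else:
        probs = np.array([spec.aa_probs.get(a, 0.0) for a in aas])
        probs = probs / probs.sum()

    for _ in range(50):  # whole-walk restarts
        coords = [rng.uniform(spec.min_separation, spec.box_size - spec.min_separation, 3)]
        ok = True
        for _i in range(1, spec.n_residues):
            placed = False
            for _try in range(300):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                step = rng.uniform(spec.min_separation, BACKBONE_STEP)
                cand = coords[-1] + step * direction
                if np.any(cand < 0.0) or np.any(cand > spec.box_size):
                    continue
                dists = np.linalg.norm(np.asarray(coords) - cand, axis=1)
                if np.all(dists >= spec.min_separation):
                    coords.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            "could not place all residues; increase box_size or lower min_separation"
        )

    seq = rng.choice(aas, size=spec.n_residues, p=probs)
    points = []
    for i, (xyz, aa) in enumerate(zip(coords, seq)):
        center = tuple(round(float(v), 3) for v in xyz)  # PDB fixed-width precision
        points.append(
            ResiduePoint(
                chain_id=chain_id,
                seq_index=i,
                author_resnum=str(i + 1),
                aa=str(aa),
                center=center,
            )
        )
    return points


def to_pdb_text(points: list[ResiduePoint]) -> str:
    """Serialize residue points as a minimal PDB file.

    Each residue gets a CA atom at its point and, for non-glycine, a CB at
    the same coordinate so the side-chain centroid read back equals the
    point (synthetic convention, not physical geometry).
    """
    n_atoms = sum(1 if p.aa == "G" else 2 for p in points)
    arr = struc.AtomArray(n_atoms)
    k = 0
    for p in points:
        names = ["CA"] if p.aa == "G" else ["CA", "CB"]
        for name in names:
            arr.chain_id[k] = p.chain_id
            arr.res_id[k] = int(p.author_resnum)
            arr.res_name[k] = ONE_TO_THREE[p.aa]
            arr.atom_name[k] = name
            arr.element[k] = "C"
            arr.hetero[k] = False
            arr.coord[k] = p.center
            k += 1
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Brute-force oracles

def brute_force_buriedness(tess: Tessellation) -> BuriednessMap:
    """Buriedness flags by naive per-simplex membership recount.

    For every face, count containing tetrahedra by subset test over the
    whole tetrahedron list; a vertex or edge is non-buried iff some
    containing face is non-buried.  Quadratic; oracle only.
    """
    face_buried = {}
    for face in tess.face_counts:
        n = sum(1 for tet in tess.tetrahedra if set(face) <= set(tet))
        face_buried[face] = n == 2
    edge_buried = {}
    for edge in tess.edges:
        containing = [f for f in tess.face_counts if set(edge) <= set(f)]
        edge_buried[edge] = all(face_buried[f] for f in containing)
    vertex_buried = {}
    for v in tess.vertices:
        containing = [f for f in tess.face_counts if v in f]
        vertex_buried[v] = all(face_buried[f] for f in containing)
    return BuriednessMap(face_buried, edge_buried, vertex_buried)


def circumsphere_contains(tet_coords: np.ndarray, point: np.ndarray, tol: float = 1e-9) -> bool:
    """Strict in-circumsphere predicate via the standard 5x5 determinant."""
    rows = []
    for p in [*tet_coords, point]:
        rows.append([*p, float(np.dot(p, p)), 1.0])
    mat = np.asarray(rows)
    orient = np.linalg.det(mat[:4, [0, 1, 2, 4]])
    det = np.linalg.det(mat)
    # sign convention depends on tetrahedron orientation
    val = det * np.sign(orient)
    scale = max(abs(det), 1.0)
    return val > tol * scale


# ---------------------------------------------------------------------------
# Planted mutant datasets

@dataclass(frozen=True)
class PlantedMutantSpec:
    """Parameters of the planted-signal mutant generator.

    ``effect_size`` is the minimum |planted score| a mutant must reach to
    enter the dataset; at >= 1 the planted weights certify the margin
    constraints, so the dataset is linearly separable by construction when
    ``noise_sd`` is 0.
    """

    n_mutants: int = 24
    n_informative_triplets: int = 8
    effect_size: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    site_pool: int = 8  # candidate mutation sites shared across mutants
    mut_alphabet: tuple[str, ...] = ("A", "E", "K", "W")


@dataclass
class PlantedDataset:
    structure_id: str
    records: list[MutationRecord]
    instances: list[LPInstance]
    informative_types: list[TripletKey]
    planted_weights: dict[TripletKey, float]
    planted_scores: list[float] = field(default_factory=list)


def _random_substitutions(rng, sites, aa_of, alphabet, max_sites: int = 3) -> dict[int, str]:
    n_sites = int(rng.integers(1, max_sites + 1))
    chosen = rng.choice(len(sites), size=min(n_sites, len(sites)), replace=False)
    subs = {}
    for ix in chosen:
        site = sites[int(ix)]
        options = [a for a in alphabet if a != aa_of[site]]
        subs[site] = str(rng.choice(options))
    return subs


def generate_planted_dataset(
    spec: PlantedMutantSpec,
    potential: PotentialTable,
    analysis: StructureAnalysis,
    structure_id: str = "SYN1",
) -> PlantedDataset:
    """Mutant dataset whose labels follow a planted triplet-type signal.

    A small pool of mutation sites is reused across mutants so triplet
    types recur (few singletons).  The pool is split into "increase" sites,
    each with a designated mutant amino acid whose mutant-side triplet types
    carry the positive signal, and "decrease" sites whose WT-side types
    carry the negative signal; those one-sided types form the informative
    set and get planted weight 2 (all others 0).  Every candidate mutant is
    labelled by thresholding its planted score (plus optional Gaussian
    noise) at zero; candidates with |planted score| < effect_size are
    rejected, so with effect_size >= 1 and no noise the planted weights
    certify the max-margin constraints.  Classes are filled to balance
    within one count.
    """
    if spec.n_informative_triplets < 1:
        raise ValueError("need at least one informative triplet type")
    rng = np.random.default_rng(spec.seed)
    aa_of = analysis.aa_of
    n_res = len(analysis.points)
    sites = sorted(
        int(i) for i in rng.choice(n_res, size=min(spec.site_pool, n_res), replace=False)
    )

    # per-site changed types: WT side is fixed by the site, mutant side
    # depends on the substituted amino acid
    wt_types: dict[int, set] = {}
    mut_types: dict[tuple[int, str], set] = {}
    for s in sites:
        options = [a for a in spec.mut_alphabet if a != aa_of[s]]
        for a in options:
            m, w = changed_triplets(analysis, {s: a})
            wt_types[s] = {t for t in w if potential.q(t) != 0.0}
            mut_types[(s, a)] = {t for t in m if potential.q(t) != 0.0}
    all_wt = set().union(*wt_types.values()) if wt_types else set()

    # split the pool; designate the best mutant AA per increase site
    inc_sites = sites[0::2]
    dec_sites = sites[1::2]
    all_mut = set().union(*mut_types.values()) if mut_types else set()
    # informative types must be reachable from one site group only, so that
    # an increase proposal can never be dragged down by informative WT-side
    # types of its own sites (and vice versa)
    dec_mut = set().union(
        *(mut_types[(s, a)] for (s, a) in mut_types if s in dec_sites), set()
    )
    inc_wt = set().union(*(wt_types[s] for s in inc_sites), set())
    dec_wt = set().union(*(wt_types[s] for s in dec_sites), set())

    designated: dict[int, str] = {}
    inf_m_by_site: dict[int, list] = {}
    for s in inc_sites:
        best, best_q, best_types = None, 0.0, None
        for a in spec.mut_alphabet:
            if (s, a) not in mut_types:
                continue
            one_sided = mut_types[(s, a)] - all_wt - dec_mut
            qsum = sum(potential.q(t) for t in one_sided)
            if qsum > best_q:
                best, best_q, best_types = a, qsum, one_sided
        if best is not None:
            designated[s] = best
            inf_m_by_site[s] = sorted(best_types)
    inf_w_by_site: dict[int, list] = {}
    designated_dec: dict[int, str] = {}
    for s in dec_sites:
        one_sided = wt_types[s] - all_mut - inc_wt
        if not one_sided:
            continue
        inf_w_by_site[s] = sorted(one_sided)
        # deterministic mutant AA whose one-sided mutant types contribute
        # least, keeping the decrease signal on the WT side
        options = [
            (sum(potential.q(t) for t in mut_types[(s, a)] - all_wt - dec_wt), a)
            for a in spec.mut_alphabet
            if (s, a) in mut_types
        ]
        designated_dec[s] = min(options)[1]

    # trim to the requested budget, then drop sites that lost all their
    # informative types so every proposal carries live signal
    half = spec.n_informative_triplets - spec.n_informative_triplets // 2
    inf_m = [t for s in sorted(inf_m_by_site) for t in inf_m_by_site[s]]
    inf_w = []
    for s in sorted(inf_w_by_site):
        inf_w.extend(t for t in inf_w_by_site[s] if t not in inf_w)
    informative = inf_m[:half] + inf_w[: spec.n_informative_triplets - min(half, len(inf_m))]
    if not informative:
        raise ValueError("no one-sided informative triplet types found")
    kept = set(informative)
    designated = {
        s: a for s, a in designated.items() if set(inf_m_by_site[s]) & kept
    }
    designated_dec = {
        s: a for s, a in designated_dec.items() if set(inf_w_by_site[s]) & kept
    }
    planted = {t: 2.0 for t in informative}

    def planted_score(m: Counter, w: Counter) -> float:
        s = 0.0
        for t, n in m.items():
            s += n * planted.get(t, 0.0) * potential.q(t)
        for t, n in w.items():
            s -= n * planted.get(t, 0.0) * potential.q(t)
        return s

    def propose(want: str) -> dict[int, str]:
        if want == "I" and designated:
            n_pick = min(int(rng.integers(1, 4)), len(designated))
            chosen = rng.choice(sorted(designated), size=n_pick, replace=False)
            return {int(s): designated[int(s)] for s in chosen}
        if want == "D" and designated_dec:
            n_pick = min(int(rng.integers(1, 4)), len(designated_dec))
            chosen = rng.choice(sorted(designated_dec), size=n_pick, replace=False)
            return {int(s): designated_dec[int(s)] for s in chosen}
        return _random_substitutions(rng, sites, aa_of, spec.mut_alphabet)

    quota_i = spec.n_mutants // 2 + spec.n_mutants % 2
    quota_d = spec.n_mutants // 2
    records, instances, scores = [], [], []
    attempts = 0
    while len(records) < spec.n_mutants:
        attempts += 1
        if attempts > 200 * spec.n_mutants:
            raise RuntimeError(
                "could not generate enough separable mutants; "
                "lower effect_size or enlarge the site pool"
            )
        n_i = sum(r.label == "I" for r in records)
        want = "I" if n_i < quota_i else "D"
        subs = propose(want)
        m, w = changed_triplets(analysis, subs)
        z = planted_score(m, w)
        if abs(z) < spec.effect_size:
            continue
        noisy = z + (rng.normal(scale=spec.noise_sd) if spec.noise_sd else 0.0)
        label = "I" if noisy > 0 else "D"
        if label == "I" and n_i >= quota_i:
            continue
        if label == "D" and sum(r.label == "D" for r in records) >= quota_d:
            continue
        rec = MutationRecord(
            structure_id=structure_id,
            chain_id=analysis.points[0].chain_id,
            substitutions=tuple(
                (analysis.points[i].author_resnum, aa_of[i], mut)
                for i, mut in sorted(subs.items())
            ),
            label=label,
        )
        records.append(rec)
        instances.append(
            LPInstance(mutant_id=f"{rec.mutant_id}#{len(records)}", m_counts=m, w_counts=w, label=label)
        )
        scores.append(z)
    return PlantedDataset(
        structure_id=structure_id,
        records=records,
        instances=instances,
        informative_types=informative,
        planted_weights=planted,
        planted_scores=scores,
    )


#: alphabet of the planted world — small enough that mutant compositions are
#: observed in the reference set, so both score signs occur
PLANTED_ALPHABET = ("A", "E", "K", "W", "G", "L")


def planted_world(
    seed: int = 0,
    *,
    n_structures: int = 4,
    n_mutants: int = 24,
    noise_sd: float = 0.0,
) -> tuple[list[StructureAnalysis], PotentialTable, PlantedDataset]:
    """Canonical self-contained world for training experiments.

    Builds ``n_structures`` synthetic chains over a 6-letter alphabet,
    estimates the triplet potential from them, and plants a mutant dataset
    on the first chain.  Deterministic given ``seed``.
    """
    from .potential import analyze_structure, count_triplets, log_likelihood

    probs = {a: 1.0 / len(PLANTED_ALPHABET) for a in PLANTED_ALPHABET}
    analyses = [
        analyze_structure(
            generate_structure(
                SyntheticStructureSpec(seed=seed * 100 + s, aa_probs=probs)
            )
        )
        for s in range(n_structures)
    ]
    table = log_likelihood(count_triplets(analyses))
    dataset = generate_planted_dataset(
        PlantedMutantSpec(
            n_mutants=n_mutants,
            seed=seed,
            noise_sd=noise_sd,
            mut_alphabet=PLANTED_ALPHABET[:4],
        ),
        table,
        analyses[0],
    )
    return analyses, table, dataset
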