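"""Read PDB structures into the unified-residue point representation.

Each amino acid is reduced to a single labelled 3D point: the centroid of its
side-chain heavy atoms, falling back to CA for glycine or residues with no
resolved side-chain atoms.  This module also parses mutant tables and
round-trips the potential / weight tables used by the scoring and training
modules.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AMINO_ACIDS = tuple(sorted(ONE_TO_THREE))

#: backbone atoms excluded from the side-chain centroid
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResiduePoint:
    """One amino acid as a labelled point in 3D space.

    ``seq_index`` is the 0-based position in the chain's ordered residue
    list (file order); ``author_resnum`` is the PDB residue number plus any
    insertion code, kept as text for mutant-site lookup.
    """

    chain_id: str
    seq_index: int
    author_resnum: str
    aa: str
    center: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.aa not in ONE_TO_THREE:
            raise ValueError(f"not a standard amino-acid code: {self.aa!r}")


@dataclass(frozen=True)
class MutationRecord:
    """A mutant instance: one or more point substitutions plus an I/D label."""

    structure_id: str
    chain_id: str
    substitutions: tuple[tuple[str, str, str], ...]  # (author_resnum, wt, mut)
    label: str  # 'I' (increase) or 'D' (decrease)

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise ValueError("substitutions must be non-empty")
        if self.label not in ("I", "D"):
            raise ValueError(f"label must be 'I' or 'D', got {self.label!r}")
        if all(wt == mut for _, wt, mut in self.substitutions):
            raise ValueError("at least one substitution must change the residue")

    @property
    def mutant_id(self) -> str:
        subs = "/".join(f"{wt}{pos}{mut}" for pos, wt, mut in self.substitutions)
        return f"{self.structure_id}:{self.chain_id}:{subs}"


def read_structure(pdb_text: str, chain_id: str) -> list[ResiduePoint]:
    """Parse ATOM records of one chain into ordered residue points.

    Only the first model is considered; HETATM records, waters, and
    non-standard residues are excluded (the latter with a warning); for
    altloc conformers the first one is kept.  The residue center is the
    centroid of side-chain heavy atoms, or CA when none are resolved.
    """
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(model=1, altloc="first")
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError("no ATOM records found")
    chains = sorted(set(atoms.chain_id))
    if chain_id not in chains:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {', '.join(chains)}"
        )
    atoms = atoms[atoms.chain_id == chain_id]
    # elements may be absent in minimal files; drop explicit hydrogens only
    atoms = atoms[(atoms.element != "H") & (atoms.element != "D")]

    points: list[ResiduePoint] = []
    for start in struc.get_residue_starts(atoms):
        res_id = atoms.res_id[start]
        ins = atoms.ins_code[start]
        res_name = atoms.res_name[start]
        mask = (atoms.res_id == res_id) & (atoms.ins_code == ins)
        res_atoms = atoms[mask & (atoms.res_name == res_name)]
        if res_name not in THREE_TO_ONE:
            logger.warning("skipping non-standard residue %s %s%s", res_name, res_id, ins)
            continue
        side = res_atoms[~np.isin(res_atoms.atom_name, list(_BACKBONE))]
        if side.array_length() > 0:
            center = side.coord.mean(axis=0)
        else:
            ca = res_atoms[res_atoms.atom_name == "CA"]
            if ca.array_length() == 0:
                logger.warning("residue %s%s has no side chain and no CA; skipped", res_id, ins)
                continue
            center = ca.coord[0]
        points.append(
            ResiduePoint(
                chain_id=chain_id,
                seq_index=len(points),
                author_resnum=f"{res_id}{ins}".strip(),
                aa=THREE_TO_ONE[res_name],
                center=tuple(float(x) for x in center),
            )
        )
    if not points:
        raise ValueError(f"chain {chain_id!r} contains no standard residues")
    return points


def coordinates(points: list[ResiduePoint]) -> np.ndarray:
    """(n, 3) array of residue centers in seq_index order."""
    return np.asarray([p.center for p in points], dtype=float)


def sequence(points: list[ResiduePoint]) -> str:
    return "".join(p.aa for p in points)


_MUT_TOKEN = re.compile(r"^([A-Z])\s*(\d+[A-Za-z]?)\s*([A-Z])$")


def parse_mutation_field(text: str) -> tuple[tuple[str, str, str], ...]:
    """Parse compact mutation notation: ``K97R`` or ``(T17S/N68D/I77V)``."""
    text = text.strip()
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1]
    subs = []
    for token in text.split("/"):
        # tolerate spaces inside tokens as they appear in published tables
        m = _MUT_TOKEN.match(token.replace(" ", ""))
        if not m:
            raise ValueError(f"malformed mutation token: {token!r}")
        wt, pos, mut = m.group(1), m.group(2), m.group(3)
        if wt not in ONE_TO_THREE or mut not in ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid code in token {token!r}")
        subs.append((pos, wt, mut))
    return tuple(subs)


def read_mutant_table(csv_text: str) -> list[MutationRecord]:
    """Read a mutant table: CSV with header structure_id,chain,mutations,label."""
    df = pd.read_csv(io.StringIO(csv_text), dtype=str)
    expected = ["structure_id", "chain", "mutations", "label"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"mutant table missing columns {missing}; expected {expected}")
    records = []
    for i, row in df.iterrows():
        try:
            subs = parse_mutation_field(row["mutations"])
            rec = MutationRecord(
                structure_id=row["structure_id"].strip(),
                chain_id=row["chain"].strip(),
                substitutions=subs,
                label=row["label"].strip(),
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 2}: {exc}") from exc
        records.append(rec)
    return records


def write_mutant_table(records: list[MutationRecord]) -> str:
    rows = []
    for r in records:
        muts = "/".join(f"{wt}{pos}{mut}" for pos, wt, mut in r.substitutions)
        if len(r.substitutions) > 1:
            muts = f"({muts})"
        rows.append((r.structure_id, r.chain_id, muts, r.label))
    df = pd.DataFrame(rows, columns=["structure_id", "chain", "mutations", "label"])
    return df.to_csv(index=False)


# ---------------------------------------------------------------------------
# Potential / weight tables (TSV, full float precision)

_POTENTIAL_COLS = ["aa1", "aa2", "aa3", "c", "b", "count", "Q"]
_WEIGHT_COLS = ["aa1", "aa2", "aa3", "c", "b", "w"]


def _validate_key(aa1: str, aa2: str, aa3: str, c: int, b: int) -> None:
    if not aa1 <= aa2 <= aa3:
        raise ValueError(f"amino acids must be sorted: {aa1}{aa2}{aa3}")
    for aa in (aa1, aa2, aa3):
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown amino acid {aa!r}")
    if c not in (0, 1, 2):
        raise ValueError(f"connectivity class out of range: {c}")
    if not 0 <= b <= 8:
        raise ValueError(f"buriedness class out of range: {b}")


def write_potential_table(rows: dict[tuple, tuple[int, float]]) -> str:
    """Serialize {(aa1,aa2,aa3,c,b): (count, Q)} to TSV at full precision."""
    lines = ["\t".join(_POTENTIAL_COLS)]
    for key in sorted(rows):
        count, q = rows[key]
        lines.append("\t".join([*key[:3], str(key[3]), str(key[4]), str(count), repr(float(q))]))
    return "\n".join(lines) + "\n"


def read_potential_table(tsv_text: str) -> dict[tuple, tuple[int, float]]:
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    missing = [c for c in _POTENTIAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"potential table missing columns {missing}; expected {_POTENTIAL_COLS}")
    out = {}
    for _, row in df.iterrows():
        c, b = int(row["c"]), int(row["b"])
        _validate_key(row["aa1"], row["aa2"], row["aa3"], c, b)
        key = (row["aa1"], row["aa2"], row["aa3"], c, b)
        out[key] = (int(row["count"]), float(row["Q"]))
    return out


def write_weight_table(weights: dict[tuple, float]) -> str:
    lines = ["\t".join(_WEIGHT_COLS)]
    for key in sorted(weights):
        lines.append("\t".join([*key[:3], str(key[3]), str(key[4]), repr(float(weights[key]))]))
    return "\n".join(lines) + "\n"


def read_weight_table(tsv_text: str) -> dict[tuple, float]:
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    missing = [c for c in _WEIGHT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"weight table missing columns {missing}; expected {_WEIGHT_COLS}")
    out = {}
    for _, row in df.iterrows():
        c, b = int(row["c"]), int(row["b"])
        _validate_key(row["aa1"], row["aa2"], row["aa3"], c, b)
        w = float(row["w"])
        if not 0.0 <= w <= 2.0:
            raise ValueError(f"weight out of bounds [0, 2]: {w}")
        out[(row["aa1"], row["aa2"], row["aa3"], c, b)] = w
    return out


def resolve_substitutions(
    points: list[ResiduePoint], record: MutationRecord
) -> dict[int, str]:
    """Map a record's author-numbered substitutions to seq_index -> mutant AA.

    The record's WT amino acid must match the structure, guarding against
    numbering offsets.
    """
    by_resnum = {p.author_resnum: p for p in points}
    out: dict[int, str] = {}
    for pos, wt, mut in record.substitutions:
        p = by_resnum.get(pos)
        if p is None:
            raise ValueError(f"mutation site {pos} not found in chain {record.chain_id}")
        if p.aa != wt:
            raise ValueError(
                f"WT mismatch at {pos}: structure has {p.aa}, record says {wt}"
            )
        out[p.seq_index] = mut
    return out
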