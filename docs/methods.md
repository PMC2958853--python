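# Methods

## Unified residue representation

A chain is reduced to one labelled point per standard residue: the centroid
of the side-chain heavy atoms (every non-hydrogen atom except N, CA, C, O,
OXT). Glycine and residues with no resolved side-chain atoms fall back to CA.
Only the first model of a file is read; the first altloc conformer is kept;
HETATM records, waters, and non-standard residues are excluded (the latter
with a warning). Residues are indexed two ways: `seq_index` (0-based file
order, used for connectivity, i.e. backbone bonding) and `author_resnum`
(PDB numbering plus insertion code, used to resolve mutation sites; the
record's WT amino acid must match the structure, which catches numbering
offsets).

## Tessellation and buriedness

The Delaunay tessellation is computed by Qhull (scipy.spatial.Delaunay) on
the full point set with **no distance cutoff**. Cospherical degeneracies can
be broken by an optional deterministic jitter (magnitude configurable,
suggested 1e-6 Å, fixed seed, default off).

Buriedness is a topological property of the whole tessellation and is
assigned before any screening, in the constant-pass list algorithm: pass 1
splits triangles into buried (occurrence count 2) and surface lists; pass 2
marks subsimplices of buried faces buried, then overrides subsimplices of
surface faces to non-buried (a vertex or edge is non-buried iff *some*
containing triangle is non-buried); class assignment is the third pass. This
is O(T) time and space in the number of tetrahedra.

The 9 three-body classes are the valid assignments of buried/non-buried to a
triangle's 7 component simplices modulo triangle symmetry, ordered by total
buried components ascending with ties broken by buried edges ascending:

| b | face | buried edges | buried vertices |
|---|------|--------------|-----------------|
| 0 | no   | 0 | 0 |
| 1 | yes  | 0 | 0 |
| 2 | yes  | 1 | 0 |
| 3 | yes  | 2 | 0 |
| 4 | yes  | 2 | 1 |
| 5 | yes  | 3 | 0 |
| 6 | yes  | 3 | 1 |
| 7 | yes  | 3 | 2 |
| 8 | yes  | 3 | 3 |

This ordering reproduces every anchor fixed by the definitions (0 fully
surface; 1 only the face buried; 5 vertices on the surface with edges and
face buried; 8 fully buried). If a downstream user needs a different
intermediate-class numbering, the table above is the single place to remap.

The 9 Å screen is applied *after* buriedness assignment and tests the three
edges of each triangle; it only selects which triangles are counted and
scored, leaving the surface topology intact. The ordering of screen vs.
flag assignment is a design choice of this package (documented here because
alternatives exist); screening first would relabel interior triangles near
long edges as surface.

## Potential

Scores use the natural logarithm (the base uniformly rescales scores and the
LP, so nothing downstream depends on it). Triplet types never observed in
the estimation set are **neutral** (Q = 0) rather than infinitely penalized —
an unobserved type carries no information; an optional additive pseudocount
(default off) spreads stratum mass over the 1540 compositions instead.
Mutation scores are computed over only the b 0–4 triangles whose composition
changes; triangles whose composition is unchanged (identity substitutions,
or paired swaps within one triangle) are skipped, which also makes the
identity mutation exactly 0.0 rather than a rounding residue. The delta
computation is verified against full rescoring to 1e-9 in the tests.

## Training LP

Variables: one weight per triplet type seen in training (bounds [0, 2]), one
free margin ε_i per mutant, and μ. Objective: maximize μ subject to
score_i ≥ 1 + ε_i for increase mutants, score_i ≤ −1 − ε_i for decrease
mutants, μ ≤ ε_i. The decrease-class constraint is the symmetric-margin
form: with the asymmetric variant "≤ −1 + ε_i" the decrease-class slacks are
only bounded below, so the max-min objective ignores that class entirely
(and is unbounded when no increase mutant is present); that variant remains
available via `printed_d_sign=True` for comparison. ε_i are free, so μ < 0
diagnoses an inseparable training set; μ ≥ 0 certifies perfect separation.
Solved with HiGHS at 1e-8 feasibility tolerances; weights are clipped to
[0, 2] after solving to absorb solver round-off. At prediction, types absent
from training default to weight 1, and a test score of exactly 0 is called D
with a logged tie flag (the decision rule is defined only by strict
inequalities; a fixed convention keeps reports deterministic).

MCC with a zero denominator is reported as 0; an undefined per-class
precision is reported as None rather than an arbitrary number.

## Hydrophobicity baseline

`hydrophobicity_change` averages a pluggable 20-value scale over a 7-residue
window centered at each mutated site (truncated at the termini), takes
mutant minus WT, and averages over sites for multi-point mutants. No scale
is hard-wired into the comparison; the Kyte–Doolittle values ship as a named
convenience constant only.

## Synthetic world

`generate_structure` performs a self-avoiding random walk: points at least
`min_separation` (default 3.5 Å, roughly the side-chain center spacing of
folded proteins) apart, consecutive points within 4.5 Å so sequence
neighbours are usually Delaunay neighbours and all three connectivity
classes occur, inside a 30 Å box (default 60 residues). Coordinates are
rounded to 3 decimals at generation so the emitted PDB round-trips exactly.
The emitted files place CA and (for non-glycine) CB on the same coordinate —
a deliberate synthetic convention so the side-chain centroid read back is
the generated point; the generator makes no claim of physical geometry,
side-chain packing, or realistic composition, so green tests establish
algorithmic correctness, not biophysical validity.

`generate_planted_dataset` builds mutant sets with recoverable ground truth.
A pool of 8 sites is split into "increase" sites — each with a designated
mutant amino acid whose mutant-side triplet types (reachable from no other
site group) carry the positive signal — and "decrease" sites whose WT-side
types carry the negative signal. The informative set is these one-sided
types (budget `n_informative_triplets`, default 8); planted weights are 2 on
informative types and 0 elsewhere, and every candidate mutant is labelled by
the sign of its planted score plus optional Gaussian noise. Candidates with
|planted score| below `effect_size` (default 1.0) are rejected, so with zero
noise the planted weights themselves satisfy every LP margin constraint:
the dataset is linearly separable by construction and μ ≥ 0 is guaranteed,
not empirical. Sites and mutant amino acids recur across mutants so that
singleton triplets are rare — the regime in which LP weights are learnable.
`planted_world` fixes the remaining free choices once: 4 structures over a
6-letter alphabet (so mutant-side compositions are observed in the reference
set and both score signs occur), 24 mutants balanced within one count.

Known limitations: the planted world's type space is tiny (hundreds of
types, not 23100), its Q values are extreme because the estimation set is
four chains, and duplicate mutants can occur; none of this affects the
correctness properties the tests assert, but absolute score magnitudes are
not comparable to those from a realistic nonredundant structure set.
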