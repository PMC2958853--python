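# delsol

Structure-based prediction of how point mutations change protein
**solubility**, using Delaunay tessellation, combinatorial buriedness of
three-body contacts, and a bounded max-margin linear program.

## The model

Each residue is reduced to one point in 3D — the centroid of its side-chain
heavy atoms (CA for glycine). The Delaunay tessellation (DT) of these points
partitions the convex hull into tetrahedra; every triangle of the DT is a
**three-body contact**. A triangle shared by two tetrahedra is *Delaunay
buried*; one in at most a single tetrahedron is on the surface. Propagating
these flags to edges and vertices (a subsimplex is non-buried iff it belongs
to at least one non-buried triangle) yields exactly **9 buriedness classes**
b = 0..8 per triangle, from fully surface-exposed to fully buried, and
**3 connectivity classes** c = 0..2 counting sequence-adjacent residue pairs.
Triangles with any edge longer than 9 Å are screened out as biochemically
irrelevant contacts.

Each screened triangle of composition (i, j, k) with classes (c, b) carries a
log-likelihood score estimated from a nonredundant structure set:

    Q(ijk,c,b) = ln [ f(ijk,c,b) / ( C · a_i · a_j · a_k · p_cb ) ]

with f the observed within-stratum frequency, a the background amino-acid
frequencies, p_cb the stratum fraction, and C ∈ {1, 3, 6} the multiplicity of
the composition. The solubility-relevant **total score** of a conformation
sums w_t·Q_t over the five most exposed classes (b 0–4). A mutation is scored
on the WT geometry as mutant total minus WT total — only triangles whose
composition changes contribute — and s > 0 predicts a solubility **increase**
(label I), s < 0 a **decrease** (D).

The weights w_t ∈ [0, 2] are trained on labelled mutants by a linear program
that maximizes the minimum margin μ subject to each increase-mutant scoring
≥ 1 + ε_i and each decrease-mutant ≤ −1 − ε_i, with μ ≤ ε_i. Triplet types
never seen in training ("singleton triplets") keep the neutral weight 1 at
prediction time. Evaluation reports accuracy, Matthews correlation
coefficient, and per-class precision under LOO, k-fold, or file-defined
cross-validation.

## Worked example

Everything below runs on synthetic fixtures — no downloads:

```sh
delsol fixtures make-dataset --seed 0 --n-mutants 24 --out mutants.csv --pdb-out SYN1.pdb
echo "SYN1.pdb A" > chains.txt
delsol train-potential --list chains.txt --pdb-dir . --out potential.tsv
# 336 triplet types from 1 chains -> potential.tsv

delsol score --pdb SYN1.pdb --chain A --mutations "M35K" --potential potential.tsv
# score      -8.629629
# prediction D
```

The unweighted score of the mutant M35K is −8.63: rescoring only the
Delaunay triangles around residue 35 (surface classes b 0–4), the lysine
compositions are less favoured than the WT methionine ones, so without
training the model calls a solubility decrease. Training the LP and
cross-validating recovers the planted labels perfectly:

```sh
delsol train-lp --mutants mutants.csv --pdb-dir . --potential potential.tsv --out weights.tsv
# mu  12.750450        <- optimal minimum margin; >= 0 means perfect separation
delsol crossval --mutants mutants.csv --pdb-dir . --potential potential.tsv \
    --scheme loo --report report.json
# accuracy  1.000
# mcc       1.000
```

The same steps work on real PDB files (`delsol tessellate`, `delsol
buriedness` expose the intermediate face lists and class assignments).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs the
whole pipeline from scratch — synthetic structure set, potential estimation,
planted mutant dataset, LP training, and LOO/10-fold/3-fold cross-validation —
printing a summary and writing the results JSON.
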