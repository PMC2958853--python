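"""Max-margin training of triplet weights by linear programming.

Each training mutant i contributes the changed triplet types on the mutant
side (M_i) and the WT side (W_i).  The LP finds weights w_t in [0, 2]
maximizing the minimum margin mu:

    max mu
    s.t.  sum_{t in M_i} w_t Q_t - sum_{t in W_i} w_t Q_t >= 1 + eps_i   (i in I)
          sum_{t in M_i} w_t Q_t - sum_{t in W_i} w_t Q_t <= -1 - eps_i  (i in D)
          mu <= eps_i for all i;  0 <= w_t <= 2.

eps_i are free, so mu < 0 signals that no perfect separation exists; when
one exists mu >= 0.  At prediction, triplet types never seen in training
(singleton triplets) keep the default weight 1, and the test score
s_j = sum_{M_j} w_t Q_t - sum_{W_j} w_t Q_t predicts increased solubility
when positive, decreased when negative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .potential import PotentialTable, TripletKey, analyze_structure, changed_triplets
from .structure_io import MutationRecord, ResiduePoint, resolve_substitutions

logger = logging.getLogger(__name__)


@dataclass
class LPInstance:
    """One mutant reduced to its changed triplet types (b 0-4) and label."""

    mutant_id: str
    m_counts: Counter  # triplet type -> multiplicity on the mutant side
    w_counts: Counter  # same for the WT side
    label: str | None = None  # 'I', 'D', or None for unlabelled test instances

    def net_coefficients(self, q: PotentialTable) -> dict[TripletKey, float]:
        """Coefficient of w_t in this instance's score: (m - w multiplicity) * Q_t."""
        coeffs: dict[TripletKey, float] = {}
        for t in set(self.m_counts) | set(self.w_counts):
            coeffs[t] = (self.m_counts.get(t, 0) - self.w_counts.get(t, 0)) * q.q(t)
        return coeffs

    @property
    def types(self) -> set:
        return set(self.m_counts) | set(self.w_counts)


@dataclass
class WeightVector:
    """Trained per-triplet-type weights with the LP's margin diagnostics."""

    w: dict[TripletKey, float]
    mu: float
    eps: dict[str, float]  # per-instance margins, keyed by mutant_id

    def weight(self, t: TripletKey) -> float:
        return self.w.get(t, 1.0)  # singleton triplets default to 1


def build_instances(
    structures: dict[str, list[ResiduePoint]],
    records: list[MutationRecord],
    cutoff: float = 9.0,
) -> list[LPInstance]:
    """Reduce mutant records to LP instances against their WT structures."""
    analyses = {sid: analyze_structure(pts, cutoff) for sid, pts in structures.items()}
    instances = []
    for rec in records:
        if rec.structure_id not in analyses:
            raise ValueError(f"no structure provided for {rec.structure_id}")
        analysis = analyses[rec.structure_id]
        subs = resolve_substitutions(analysis.points, rec)
        m_counts, w_counts = changed_triplets(analysis, subs)
        instances.append(
            LPInstance(
                mutant_id=rec.mutant_id,
                m_counts=m_counts,
                w_counts=w_counts,
                label=rec.label,
            )
        )
    return instances


def build_and_solve_lp(
    instances: list[LPInstance],
    q: PotentialTable,
    *,
    printed_d_sign: bool = False,
    tol: float = 1e-8,
) -> WeightVector:
    """Solve the bounded max-min-margin LP over the training instances.

    ``printed_d_sign`` switches the decrease-class constraint to the
    asymmetric "<= -1 + eps_i" variant, in which the objective ignores the
    D class; kept for comparison only.
    """
    if not instances:
        raise ValueError("need at least one training instance")
    if any(inst.label not in ("I", "D") for inst in instances):
        raise ValueError("all training instances must be labelled I or D")

    types = sorted({t for inst in instances for t in inst.types})
    t_index = {t: k for k, t in enumerate(types)}
    n_w, n_i = len(types), len(instances)
    # variables: [w_0..w_{n_w-1}, eps_0..eps_{n_i-1}, mu]
    n_var = n_w + n_i + 1
    c = np.zeros(n_var)
    c[-1] = -1.0  # maximize mu

    rows, rhs = [], []
    for k, inst in enumerate(instances):
        row = np.zeros(n_var)
        for t, coeff in inst.net_coefficients(q).items():
            row[t_index[t]] = coeff
        if inst.label == "I":
            # score >= 1 + eps  ->  -score + eps <= -1
            r = -row
            r[n_w + k] = 1.0
        else:
            r = row.copy()
            # score <= -1 - eps  ->  score + eps <= -1 (symmetric margin)
            # printed variant: score <= -1 + eps  ->  score - eps <= -1
            r[n_w + k] = -1.0 if printed_d_sign else 1.0
        rows.append(r)
        rhs.append(-1.0)
        # mu <= eps_k
        r2 = np.zeros(n_var)
        r2[-1] = 1.0
        r2[n_w + k] = -1.0
        rows.append(r2)
        rhs.append(0.0)

    bounds = [(0.0, 2.0)] * n_w + [(None, None)] * (n_i + 1)
    res = linprog(
        c,
        A_ub=np.asarray(rows),
        b_ub=np.asarray(rhs),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    if res.status == 3:
        raise RuntimeError(
            "LP unbounded — this indicates a modelling bug "
            f"(printed_d_sign={printed_d_sign} with no I instances?)"
        )
    if not res.success:
        raise RuntimeError(f"LP solver failed: status {res.status}: {res.message}")

    w = {t: float(np.clip(res.x[t_index[t]], 0.0, 2.0)) for t in types}
    eps = {inst.mutant_id: float(res.x[n_w + k]) for k, inst in enumerate(instances)}
    return WeightVector(w=w, mu=float(res.x[-1]), eps=eps)


@dataclass
class Prediction:
    mutant_id: str
    score: float
    label: str
    tie: bool = False


def predict(instance: LPInstance, weights: WeightVector, q: PotentialTable) -> Prediction:
    """Score a test mutant and call I/D; singleton types weigh exactly 1.

    A score of exactly zero is called D with the tie flag set (the decision
    rule is defined only by strict inequalities).
    """
    s = 0.0
    for t, coeff in instance.net_coefficients(q).items():
        s += weights.weight(t) * coeff
    if s > 0:
        return Prediction(instance.mutant_id, s, "I")
    if s < 0:
        return Prediction(instance.mutant_id, s, "D")
    logger.info("tie score (s = 0) for %s; predicting D", instance.mutant_id)
    return Prediction(instance.mutant_id, s, "D", tie=True)


@dataclass
class EvaluationReport:
    """Confusion matrix (I = positive) and derived statistics."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    mcc: float
    precision_i: float | None
    precision_d: float | None
    folds: list["EvaluationReport"] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        d = {
            "confusion": {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn},
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "precision_I": self.precision_i,
            "precision_D": self.precision_d,
        }
        if self.folds:
            d["folds"] = [f.to_dict() for f in self.folds]
        return d


def evaluate(pred_labels: list[str], true_labels: list[str]) -> EvaluationReport:
    """Accuracy, Matthews correlation coefficient, and per-class precision.

    MCC with a zero denominator is reported as 0; an undefined precision
    (no predictions for that class) is reported as None.
    """
    if not pred_labels:
        raise ValueError("empty prediction list")
    if len(pred_labels) != len(true_labels):
        raise ValueError("prediction/truth length mismatch")
    bad = [l for l in [*pred_labels, *true_labels] if l not in ("I", "D")]
    if bad:
        raise ValueError(f"labels must be I or D, got {bad[:3]}")
    tp = sum(p == "I" and t == "I" for p, t in zip(pred_labels, true_labels))
    tn = sum(p == "D" and t == "D" for p, t in zip(pred_labels, true_labels))
    fp = sum(p == "I" and t == "D" for p, t in zip(pred_labels, true_labels))
    fn = sum(p == "D" and t == "I" for p, t in zip(pred_labels, true_labels))
    n = tp + tn + fp + fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / denom**0.5 if denom > 0 else 0.0
    return EvaluationReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / n,
        mcc=mcc,
        precision_i=tp / (tp + fp) if tp + fp > 0 else None,
        precision_d=tn / (tn + fn) if tn + fn > 0 else None,
    )


def loo_folds(n: int) -> list[list[int]]:
    return [[i] for i in range(n)]


def kfold_folds(n: int, k: int, seed: int) -> list[list[int]]:
    """Deterministic shuffled k-fold partition of range(n)."""
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n={n}], got {k}")
    order = np.random.default_rng(seed).permutation(n)
    return [sorted(int(i) for i in order[j::k]) for j in range(k)]


def folds_from_assignment(
    instances: list[LPInstance], assignment: dict[str, str]
) -> list[list[int]]:
    """Folds from a mutant_id -> fold_id mapping (e.g. sequence-similarity folds)."""
    ids = {inst.mutant_id for inst in instances}
    unknown = set(assignment) - ids
    if unknown:
        raise ValueError(f"fold file references unknown mutants: {sorted(unknown)[:5]}")
    missing = ids - set(assignment)
    if missing:
        raise ValueError(f"fold file misses mutants: {sorted(missing)[:5]}")
    by_fold: dict[str, list[int]] = {}
    for i, inst in enumerate(instances):
        by_fold.setdefault(assignment[inst.mutant_id], []).append(i)
    return [by_fold[f] for f in sorted(by_fold)]


def read_fold_file(tsv_text: str) -> dict[str, str]:
    """TSV with two columns: mutant_id, fold_id (no header)."""
    out = {}
    for line in tsv_text.strip().splitlines():
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"fold file line not 'mutant_id<TAB>fold_id': {line!r}")
        out[parts[0]] = parts[1]
    return out


def cross_validate(
    instances: list[LPInstance],
    q: PotentialTable,
    scheme: str = "loo",
    *,
    k: int | None = None,
    seed: int = 0,
    fold_assignment: dict[str, str] | None = None,
) -> tuple[EvaluationReport, list[Prediction]]:
    """Train on each fold's complement, predict the fold, pool the results.

    ``scheme`` is ``"loo"``, ``"kfold"`` (with ``k`` and ``seed``), or
    ``"file"`` (with ``fold_assignment``).  Returns the pooled report, with
    per-fold reports attached, plus the per-mutant predictions in dataset
    order.
    """
    n = len(instances)
    if scheme == "loo":
        folds = loo_folds(n)
    elif scheme == "kfold":
        if k is None:
            raise ValueError("kfold scheme requires k")
        folds = kfold_folds(n, k, seed)
    elif scheme == "file":
        if fold_assignment is None:
            raise ValueError("file scheme requires a fold assignment")
        folds = folds_from_assignment(instances, fold_assignment)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    predictions: dict[int, Prediction] = {}
    fold_reports = []
    for fold in folds:
        test_ix = set(fold)
        train = [inst for i, inst in enumerate(instances) if i not in test_ix]
        weights = build_and_solve_lp(train, q)
        fold_preds = [predict(instances[i], weights, q) for i in sorted(test_ix)]
        for i, p in zip(sorted(test_ix), fold_preds):
            predictions[i] = p
        fold_reports.append(
            evaluate([p.label for p in fold_preds], [instances[i].label for i in sorted(test_ix)])
        )
    ordered = [predictions[i] for i in range(n)]
    pooled = evaluate([p.label for p in ordered], [inst.label for inst in instances])
    pooled.folds = fold_reports
    return pooled, ordered


# ---------------------------------------------------------------------------
# Hydrophobicity baseline

#: Kyte-Doolittle hydropathy values; a convenience scale only — callers may
#: supply any mapping of the 20 amino acids to numbers.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

WINDOW = 7  # residues per averaging window


def hydrophobicity_change(
    sequence: str,
    substitutions: list[tuple[int, str]],
    scale: dict[str, float],
) -> float:
    """Mean change in window-averaged hydrophobicity over the mutation sites.

    For each mutated site j (0-based), the per-residue average H_av(j) is
    the mean scale value over the 7-residue window centered at j, truncated
    at the termini; the change is mutant minus WT with all substitutions
    applied, and multi-site mutants average the per-site changes.
    """
    seq = list(sequence)
    mut = list(sequence)
    for pos, aa in substitutions:
        if not 0 <= pos < len(seq):
            raise ValueError(f"site {pos} out of range for sequence of length {len(seq)}")
        mut[pos] = aa

    def h_av(s: list[str], j: int) -> float:
        lo, hi = max(0, j - WINDOW // 2), min(len(s), j + WINDOW // 2 + 1)
        return sum(scale[a] for a in s[lo:hi]) / (hi - lo)

    deltas = [h_av(mut, pos) - h_av(seq, pos) for pos, _ in substitutions]
    return sum(deltas) / len(deltas)
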