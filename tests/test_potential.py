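import math

import numpy as np
import pytest

from delsol.potential import (
    PotentialTable,
    StructureAnalysis,
    analyze_structure,
    changed_triplets,
    combinatorial_factor,
    count_triplets,
    log_likelihood,
    mutation_score,
    total_surface_score,
    triplet_key,
)
from delsol.structure_io import MutationRecord
from delsol.synthetic import SyntheticStructureSpec, generate_structure

from conftest import make_points

# regular-ish tetrahedron with its centroid: tessellates into 4 tetrahedra;
# the 4 outer faces are fully surface (b=0) and the 6 inner faces, each an
# outer edge plus the center, come out face+2-edges+1-vertex buried (b=4)
STAR = [(0.0, 0.0, 0.0), (6.0, 0.0, 0.0), (3.0, 5.2, 0.0), (3.0, 1.7, 4.9),
        (3.0, 2.2, 1.2)]


@pytest.mark.parametrize(
    "aas,expected",
    [(("A", "G", "V"), 6), (("A", "A", "G"), 3), (("A", "A", "A"), 1),
     (("G", "A", "A"), 3)],
)
def test_combinatorial_factor(aas, expected):
    assert combinatorial_factor(aas) == expected


class TestCountTriplets:
    def test_single_face_structure(self):
        analysis = StructureAnalysis(
            points=make_points([(0, 0, 0), (4, 0, 0), (2, 3, 0)], aas="AAG"),
            classified_faces=[((0, 1, 2), 2, 0)],
        )
        table = count_triplets([analysis])
        assert table.counts == {("A", "A", "G", 2, 0): 1}
        assert table.p_cb == {(2, 0): 1.0}
        assert table.a == {"A": pytest.approx(2 / 3), "G": pytest.approx(1 / 3)}

    def test_p_cb_normalized_and_additive(self):
        pts = [generate_structure(SyntheticStructureSpec(seed=s)) for s in (1, 2)]
        analyses = [analyze_structure(p) for p in pts]
        t1 = count_triplets([analyses[0]])
        t2 = count_triplets([analyses[1]])
        both = count_triplets(analyses)
        assert math.isclose(sum(both.p_cb.values()), 1.0)
        assert math.isclose(sum(both.a.values()), 1.0)
        for key, n in both.counts.items():
            assert n == t1.counts.get(key, 0) + t2.counts.get(key, 0)

    def test_stratum_frequencies_sum_to_one(self, potential_60):
        by_stratum = {}
        for (a1, a2, a3, c, b), n in potential_60.counts.items():
            by_stratum.setdefault((c, b), []).append(n)
        for counts in by_stratum.values():
            total = sum(counts)
            assert math.isclose(sum(n / total for n in counts), 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            count_triplets([])


class TestLogLikelihood:
    def test_q_definition(self, potential_60):
        strata = {}
        for (a1, a2, a3, c, b), n in potential_60.counts.items():
            strata[(c, b)] = strata.get((c, b), 0) + n
        for key, q in potential_60.Q.items():
            a1, a2, a3, c, b = key
            f = potential_60.counts[key] / strata[(c, b)]
            expected = (
                combinatorial_factor((a1, a2, a3))
                * potential_60.a[a1] * potential_60.a[a2] * potential_60.a[a3]
                * potential_60.p_cb[(c, b)]
            )
            assert q == pytest.approx(math.log(f / expected), rel=1e-12)

    def test_unobserved_key_neutral(self, potential_60):
        assert potential_60.q(("W", "W", "W", 2, 8)) == 0.0

    def test_single_key_stratum(self):
        analysis = StructureAnalysis(
            points=make_points([(0, 0, 0), (4, 0, 0), (2, 3, 0)], aas="AAG"),
            classified_faces=[((0, 1, 2), 2, 0)],
        )
        table = log_likelihood(count_triplets([analysis]))
        key = ("A", "A", "G", 2, 0)
        # f = 1 for the stratum's only key, so Q = -log(C * a_A^2 * a_G * p_cb)
        expected = -math.log(3 * (2 / 3) ** 2 * (1 / 3) * 1.0)
        assert table.q(key) == pytest.approx(expected)

    def test_q_zero_when_observed_matches_expected(self):
        # one face of three identical AAs: f=1, a_A=1, C=1, p_cb=1 -> Q = 0
        analysis = StructureAnalysis(
            points=make_points([(0, 0, 0), (4, 0, 0), (2, 3, 0)], aas="AAA"),
            classified_faces=[((0, 1, 2), 2, 0)],
        )
        table = log_likelihood(count_triplets([analysis]))
        assert table.q(("A", "A", "A", 2, 0)) == pytest.approx(0.0)


class TestTotalSurfaceScore:
    def test_buried_classes_contribute_nothing(self, potential_60):
        analysis = StructureAnalysis(
            points=make_points([(0, 0, 0), (4, 0, 0), (2, 3, 0)], aas="AAG"),
            classified_faces=[((0, 1, 2), 2, b) for b in (5, 6, 7, 8)],
        )
        assert total_surface_score(analysis, potential_60) == 0.0

    def test_identity_weights_equal_unweighted_sum(self, analysis_60, potential_60):
        ones = {k: 1.0 for k in potential_60.Q}
        assert total_surface_score(analysis_60, potential_60, ones) == pytest.approx(
            total_surface_score(analysis_60, potential_60)
        )

    def test_star_fixture_by_hand(self):
        pts = make_points(STAR, aas="AAGVG")
        analysis = analyze_structure(pts, cutoff=9.0)
        tess_faces = {f: (c, b) for f, c, b in analysis.classified_faces}
        outer = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        inner = [(0, 1, 4), (0, 2, 4), (0, 3, 4), (1, 2, 4), (1, 3, 4), (2, 3, 4)]
        assert set(tess_faces) == set(outer + inner)
        for f in outer:
            assert tess_faces[f][1] == 0
        for f in inner:
            assert tess_faces[f][1] == 4
        table = log_likelihood(count_triplets([analysis]))
        aa = analysis.aa_of
        expected = sum(
            table.q(triplet_key(tuple(aa[i] for i in f), *tess_faces[f]))
            for f in outer + inner
        )
        assert total_surface_score(analysis, table) == pytest.approx(expected)


class TestMutationScore:
    def test_identity_substitution_scores_zero(self, analysis_60, potential_60):
        aa5 = analysis_60.points[5].aa
        assert mutation_score(analysis_60, {5: aa5}, potential_60) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_delta_equals_full_rescoring(self, seed, analysis_60, potential_60):
        rng = np.random.default_rng(seed)
        n = len(analysis_60.points)
        sites = rng.choice(n, size=rng.integers(1, 5), replace=False)
        subs = {}
        for s in sites:
            wt = analysis_60.points[int(s)].aa
            subs[int(s)] = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != wt])
        delta = mutation_score(analysis_60, subs, potential_60)
        full = total_surface_score(
            analysis_60, potential_60, substitutions=subs
        ) - total_surface_score(analysis_60, potential_60)
        assert delta == pytest.approx(full, abs=1e-9)

    def test_sites_sharing_a_triangle_counted_once(self, analysis_60, potential_60):
        # find two sequence-adjacent residues sharing a surface triangle
        for i in range(len(analysis_60.points) - 1):
            shared = [
                f for f, c, b in analysis_60.classified_faces
                if i in f and i + 1 in f and b <= 4
            ]
            if shared:
                break
        assert shared, "fixture should have shared triangles"
        wt_i, wt_j = analysis_60.points[i].aa, analysis_60.points[i + 1].aa
        subs = {
            i: "W" if wt_i != "W" else "Y",
            i + 1: "W" if wt_j != "W" else "Y",
        }
        mut_keys, wt_keys = changed_triplets(analysis_60, subs)
        assert sum(mut_keys.values()) == sum(wt_keys.values())
        delta = mutation_score(analysis_60, subs, potential_60)
        full = total_surface_score(
            analysis_60, potential_60, substitutions=subs
        ) - total_surface_score(analysis_60, potential_60)
        assert delta == pytest.approx(full, abs=1e-9)

    def test_order_invariance(self, analysis_60, potential_60):
        p10, p20 = analysis_60.points[10], analysis_60.points[20]
        m1 = "W" if p10.aa != "W" else "Y"
        m2 = "C" if p20.aa != "C" else "S"
        rec_a = MutationRecord(
            "S", "A",
            ((p10.author_resnum, p10.aa, m1), (p20.author_resnum, p20.aa, m2)), "I",
        )
        rec_b = MutationRecord("S", "A", tuple(reversed(rec_a.substitutions)), "I")
        assert mutation_score(analysis_60, rec_a, potential_60) == pytest.approx(
            mutation_score(analysis_60, rec_b, potential_60)
        )

    def test_only_surface_classes_contribute(self, analysis_60, potential_60):
        subs = {0: "W" if analysis_60.points[0].aa != "W" else "Y"}
        mut_keys, wt_keys = changed_triplets(analysis_60, subs)
        for key in list(mut_keys) + list(wt_keys):
            assert key[4] in (0, 1, 2, 3, 4)
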