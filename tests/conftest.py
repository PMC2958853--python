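import pytest

from delsol.potential import analyze_structure, count_triplets, log_likelihood
from delsol.structure_io import ResiduePoint
from delsol.synthetic import SyntheticStructureSpec, generate_structure, planted_world


def make_points(coords, aas=None, chain="A"):
    """Residue points from raw coordinates, defaulting to poly-alanine."""
    if aas is None:
        aas = "A" * len(coords)
    return [
        ResiduePoint(
            chain_id=chain,
            seq_index=i,
            author_resnum=str(i + 1),
            aa=aas[i],
            center=tuple(float(x) for x in c),
        )
        for i, c in enumerate(coords)
    ]


@pytest.fixture(scope="session")
def structure_60():
    return generate_structure(SyntheticStructureSpec(seed=7))


@pytest.fixture(scope="session")
def analysis_60(structure_60):
    return analyze_structure(structure_60)


@pytest.fixture(scope="session")
def potential_60(analysis_60):
    return log_likelihood(count_triplets([analysis_60]))


@pytest.fixture(scope="session")
def planted():
    """Canonical planted world: analyses, potential table, mutant dataset."""
    return planted_world(seed=0)
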