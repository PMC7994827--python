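"""Shared fixtures: toy PDB texts, the helix fixture, and the hinge-shift pair."""

import numpy as np
import pytest

import hingeshift as hs

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   2.500   3.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.500   3.500   3.000  1.00  0.00           O
ATOM      5  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      6  CA  SER A   3       7.000   8.000  10.000  1.00  0.00           C
END
"""

# model 2 rigidly shifted by +1 in x
TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.500   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.700  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   0.500   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       8.600   0.000   0.700  1.00  0.00           C
ENDMDL
END
"""

# four residues, the third (PRO 3) has no Cα record
MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.500   0.100  1.00  0.00           C
ATOM      3  N   PRO A   3       6.000   1.000   0.000  1.00  0.00           N
ATOM      4  CA  SER A   4       7.600   0.100   0.800  1.00  0.00           C
END
"""

# altloc B has the higher occupancy and must win
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.500   0.100  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.100   0.800  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    def write(text, name="test.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return write


@pytest.fixture(scope="session")
def helix10():
    return hs.make_structure(hs.FixtureSpec(topology="helix", n_residues=10))


@pytest.fixture(scope="session")
def helix10_cov(helix10):
    h = hs.build_hessian(helix10)
    return hs.covariance_from_hessian(h)


# canonical hinge-shift pair: stiffen two mid-flexibility positions, soften
# the two strongest hinges, plus one dynamics-neutral substitution
PAIR_SPEC = dict(topology="two-domain", n_residues=30, seed=5)
PAIR_STIFFEN = [3, 20]
PAIR_SOFTEN = [19, 4]
PAIR_MUTATE_ONLY = [26]


@pytest.fixture(scope="session")
def shift_pair():
    spec = hs.FixtureSpec(**PAIR_SPEC)
    return hs.make_hinge_shift_pair(spec, stiffen=PAIR_STIFFEN, soften=PAIR_SOFTEN,
                                    mutate_only=PAIR_MUTATE_ONLY)


@pytest.fixture(scope="session")
def shift_pair_analysis(shift_pair):
    """Profiles, hinge table and pairwise couplings of the canonical pair."""
    a_a = hs.response_matrix(shift_pair.cov_a)
    a_b = hs.response_matrix(shift_pair.cov_b)
    prof_a = hs.dfi(a_a, label="A")
    prof_b = hs.dfi(a_b, label="B")
    amap = hs.align_sequences(shift_pair.structure_a.aa, shift_pair.structure_b.aa)
    table = hs.classify_hinges(prof_a, prof_b, amap)
    return dict(prof_a=prof_a, prof_b=prof_b, amap=amap, table=table,
                pw_a=hs.pairwise_dci(a_a), pw_b=hs.pairwise_dci(a_b))


def toy_response_matrix():
    """Hand-written 4×4 response matrix for arithmetic oracles."""
    return hs.ResponseMatrix(
        matrix=np.array([
            [4.0, 1.0, 2.0, 1.0],
            [1.0, 3.0, 1.0, 1.0],
            [2.0, 1.0, 5.0, 2.0],
            [1.0, 1.0, 2.0, 4.0],
        ]),
        force_model="closed_form",
    )
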