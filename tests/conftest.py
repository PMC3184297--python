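import numpy as np
import pytest

from loco.potential import LoCoParams, accumulate_counts, compile_potential
from loco.synthetic import ideal_helix, make_training_corpus

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.143  -4.937  1.00  0.00           C
ATOM      4  N   GLY A   2      12.647   8.110  -5.855  1.00  0.00           N
ATOM      5  CA  GLY A   2      13.600   9.210  -5.800  1.00  0.00           C
ATOM      6  C   GLY A   2      13.900  10.000  -7.100  1.00  0.00           C
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture(scope="session")
def helix_corpus():
    """Small all-helical training corpus (lengths 25-40)."""
    return make_training_corpus(60, length_range=(25, 40),
                                mixture={"helix": 1.0}, seed=7)


@pytest.fixture(scope="session")
def mixed_corpus():
    """Mixed secondary-structure corpus for counting/scoring oracles."""
    return make_training_corpus(40, length_range=(20, 40), seed=11)


@pytest.fixture(scope="session")
def helix_db(helix_corpus):
    """Potential trained on the helical corpus at default parameters."""
    return compile_potential(accumulate_counts(helix_corpus, LoCoParams()),
                             provenance="test-helix-corpus")


@pytest.fixture(scope="session")
def mixed_db(mixed_corpus):
    return compile_potential(accumulate_counts(mixed_corpus, LoCoParams()),
                             provenance="test-mixed-corpus")


@pytest.fixture(scope="session")
def helix20():
    return ideal_helix(20, id="helix20")


def random_rigid_transform(rng):
    """A uniformly random proper rotation + translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(0, 20, 3)
    return rot.as_matrix(), t


def apply_rigid(structure, rot, t):
    """Return a copy of the structure with x -> rot @ x + t."""
    from loco.structures import MainChainStructure, Residue
    residues = [
        Residue(index=r.index, aa=r.aa, n=rot @ r.n + t, ca=rot @ r.ca + t,
                c=rot @ r.c + t,
                cb=None if r.cb is None else rot @ r.cb + t,
                seq_num=r.seq_num)
        for r in structure.residues
    ]
    return MainChainStructure(id=structure.id + "_rigid", residues=residues,
                              breaks=structure.breaks)


def mirror_structure(structure):
    """Reflect every coordinate through the x=0 plane."""
    from loco.structures import MainChainStructure, Residue
    m = np.diag([-1.0, 1.0, 1.0])
    residues = [
        Residue(index=r.index, aa=r.aa, n=m @ r.n, ca=m @ r.ca, c=m @ r.c,
                cb=None if r.cb is None else m @ r.cb, seq_num=r.seq_num)
        for r in structure.residues
    ]
    return MainChainStructure(id=structure.id + "_mirror", residues=residues,
                              breaks=structure.breaks)


def random_residue(rng, aa="A"):
    """A geometrically valid random residue (non-collinear N/CA/C)."""
    from loco.structures import Residue
    while True:
        ca = rng.normal(0, 10, 3)
        n = ca + _random_bond(rng, 1.46)
        c = ca + _random_bond(rng, 1.53)
        cr = np.cross(n - ca, c - ca)
        if np.linalg.norm(cr) > 1e-3:
            return Residue(index=0, aa=aa, n=n, ca=ca, c=c, seq_num=1)


def _random_bond(rng, length):
    v = rng.normal(0, 1, 3)
    return length * v / np.linalg.norm(v)
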