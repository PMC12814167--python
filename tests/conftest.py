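import warnings

import pytest

from twostate.fixtures import FixtureSpec, make_fixture_bundle


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Fixture geometry sometimes triggers benign advisory warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(
        n_per_lobe=20, msa_rows=20, n_candidates=80, seed=7, closure_angle=35.0
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """One fully generated synthetic protein: pair, truth, MSA, ΔΔG tables."""
    return make_fixture_bundle(small_spec)


@pytest.fixture(scope="session")
def small_pair(small_bundle):
    return small_bundle.pair


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return small_bundle.truth


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.040  1.00  0.00           C
END
"""

MIXED_PDB = """\
ATOM      1  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
HETATM    2  O   HOH A 101      13.000   7.000  -5.000  1.00  0.00           O
HETATM    3  C1  LIG A 201      14.000   8.000  -4.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb() -> str:
    return MINIMAL_PDB


@pytest.fixture
def mixed_pdb() -> str:
    return MIXED_PDB
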