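import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from depsitools.chem import default_acyl_chains, default_residues
from depsitools.fragments import parse_peptide
from depsitools.simulate import PAENIDEPSIN_A, paenidepsin_scaffold


@pytest.fixture(scope="session")
def residues():
    return default_residues()


@pytest.fixture(scope="session")
def acyl_chains():
    return default_acyl_chains()


@pytest.fixture(scope="session")
def peptide_a():
    """The flagship 12-residue acyl depsipeptide (ring-opened)."""
    return parse_peptide(PAENIDEPSIN_A)


@pytest.fixture(scope="session")
def scaffold():
    """Des-hydroxy congener scaffold (Trp7, C17 acyl)."""
    return paenidepsin_scaffold()
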