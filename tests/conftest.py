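import pytest

from subpatterns import parse_rst, simulate, write_rst


@pytest.fixture(scope="session")
def small_log():
    """Small simulated history shared by parser/classifier tests."""
    return simulate(n_tips=6, length_codons=60, kappa=2.0,
                    events_per_branch=6, seed=11)


@pytest.fixture(scope="session")
def oracle_log():
    """The oracle-equivalence history: 10 tips, 300 codons, ~20/branch."""
    return simulate(n_tips=10, length_codons=300, kappa=2.0,
                    events_per_branch=20, seed=7)


@pytest.fixture(scope="session")
def oracle_doc(oracle_log):
    return parse_rst(write_rst(oracle_log, dialect="codeml"))
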