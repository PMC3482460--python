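import pytest

from mcfp import (
    MonomerAlphabet,
    PeptideRecord,
    build_alphabet,
    compute_mcfp,
    fixture_table5,
    monomer_universe,
)


@pytest.fixture(scope="session")
def table5_records():
    """The five published peptides shipped as a fixture."""
    return fixture_table5()


@pytest.fixture(scope="session")
def alphabet_526():
    """A 526-code alphabet: placeholder codes padded with the real codes
    used by the worked fingerprint example."""
    codes = monomer_universe(522) + ["NAc-Leu", "Aib", "Leu", "Pheol"]
    return build_alphabet(codes)


@pytest.fixture(scope="session")
def peptaibolin():
    return PeptideRecord(
        id="NOR01028",
        name="peptaibolin",
        activities=frozenset({"antibiotic"}),
        composition=("NAc-Leu", "Aib", "Leu", "Aib", "Pheol"),
    )


@pytest.fixture()
def small_alphabet():
    return MonomerAlphabet.from_codes(["A", "B", "C", "D"])


def fp_from_counts(counts, alphabet):
    """Build an MCFP directly from a dense count list (test helper)."""
    from mcfp import MCFP

    return MCFP({i: c for i, c in enumerate(counts) if c}, alphabet)


@pytest.fixture()
def make_fp(small_alphabet):
    def _make(counts, alphabet=None):
        return fp_from_counts(counts, alphabet or small_alphabet)

    return _make
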