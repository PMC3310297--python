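import pytest

from genowave import NUCLEOTIDES, SymbolSequence, load_codon_table


def nt(text: str, identifier: str = "test") -> SymbolSequence:
    """Nucleotide sequence from a bare string."""
    return SymbolSequence.from_string(text, identifier, NUCLEOTIDES)


@pytest.fixture(scope="session")
def codon_table():
    return load_codon_table()
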