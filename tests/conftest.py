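import pytest

from yeastburden import ProteomeSimConfig, generate_proteome


@pytest.fixture(scope="session")
def codon_proteome():
    """Large proteome drawn i.i.d. from codon-expected frequencies (no
    abundance coupling); ~1e6 residues. Shared across tests for speed."""
    config = ProteomeSimConfig(n_proteins=2500, cys_coupling=0.0, seed=11)
    return generate_proteome(config)


@pytest.fixture(scope="session")
def coupled_proteome():
    """Proteome with strong cysteine depletion in abundant proteins."""
    config = ProteomeSimConfig(n_proteins=1500, cys_coupling=-0.5, seed=7)
    return generate_proteome(config)
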