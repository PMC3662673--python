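import pytest

from mitocomp.synthetic_data import (
    AlignmentSpec,
    generate_alignment,
    generate_genome,
    langii_like_spec,
    wc_swapped_spec,
)


@pytest.fixture(scope="session")
def langii_genome():
    """Lacewing-like synthetic genome with its truth record (fixed seed)."""
    return generate_genome(langii_like_spec(seed=11))


@pytest.fixture(scope="session")
def swapped_genome():
    """Genome with the derived tRNA-Trp/tRNA-Cys transposition."""
    return generate_genome(wc_swapped_spec(seed=11))


@pytest.fixture(scope="session")
def outlier_alignment():
    """11-taxon alignment with one strongly AT-biased taxon planted."""
    deltas = tuple([0.0] * 10 + [0.8])
    return generate_alignment(
        AlignmentSpec(n_taxa=11, n_codons=300, deltas=deltas, seed=42)
    )
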