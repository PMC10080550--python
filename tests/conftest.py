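import pytest

from silbind import PeptideSequence, generate_ms_titration, generate_nmr_series
from silbind.synthetic import load_preset


@pytest.fixture(scope="session")
def sp2_sequence() -> PeptideSequence:
    """16-residue SilE fragment spanning protein residues 77-92."""
    return PeptideSequence("ADAHQKMVESHQRMMG", numbering_offset=77)


@pytest.fixture(scope="session")
def sp3_sequence() -> PeptideSequence:
    """19-residue SilE fragment spanning protein residues 107-125."""
    return PeptideSequence("AMNEHERAAVAHEFMNNGQ", numbering_offset=107)


@pytest.fixture(scope="session")
def sp2_preset():
    return load_preset("sp2-paper")


@pytest.fixture(scope="session")
def sp2_series(sp2_preset):
    """Noiseless phenomenological two-mode TOCSY titration series."""
    return generate_nmr_series(sp2_preset)


@pytest.fixture(scope="session")
def sp3_preset():
    return load_preset("sp3-paper")


@pytest.fixture(scope="session")
def sp3_spectra(sp3_preset):
    """Noiseless ESI-MS titration: 100 uM peptide at 0, 0.5, 1, 2 equivalents."""
    return generate_ms_titration(sp3_preset)
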