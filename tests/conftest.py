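import pytest

from imrescore import synthetic as syn
from imrescore.io import Psm


@pytest.fixture(scope="session")
def small_peptides():
    return syn.generate_peptides(60, (8, 16), modification_alphabet=(), seed=42)


@pytest.fixture(scope="session")
def small_benchmark():
    """A benchmark small enough for unit tests (use q=0.05 thresholds)."""
    config = syn.BenchmarkConfig(n_correct=300, n_incorrect=300, n_decoys=600)
    return syn.build_benchmark(config, seed=11)


@pytest.fixture()
def law_psms_spectra():
    """Noise-free spectra simulated from the intensity law, one per peptide."""
    peps = syn.generate_peptides(80, (8, 16), modification_alphabet=(), seed=5)
    spectra = {}
    psms = []
    for i, p in enumerate(peps):
        sid = f"s{i}"
        spectra[sid] = syn.simulate_spectrum(
            p, noise_sigma=0.0, n_noise_peaks=0, seed=i, identifier=sid
        )
        psms.append(Psm(sid, p, score=1.0))
    return psms, spectra
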