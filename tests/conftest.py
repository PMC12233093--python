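import numpy as np
import pytest

from jestr.chem import parse_molecule
from jestr.encoders import EncoderParams, init_weights
from jestr.spectra import Peak, Spectrum
from jestr.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_params():
    """Small encoder configuration for fast unit tests."""
    return EncoderParams(gcn_layers=2, hidden_dim=16, embed_dim=8, seed=7)


@pytest.fixture(scope="session")
def tiny_weights(tiny_params):
    return init_weights(tiny_params)


@pytest.fixture(scope="session")
def ethanol():
    return parse_molecule("CCO", "ethanol")


@pytest.fixture
def simple_spectrum():
    return Spectrum(
        spectrum_id="s1",
        peaks=[Peak(57.2, 499.5), Peak(150.4, 999.0), Peak(301.9, 120.0)],
        molecule_id="m1",
        adduct="[M+H]+",
        precursor_mz=302.1,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small but non-trivial synthetic dataset shared across test modules."""
    return generate_dataset(GeneratorConfig(n_molecules=60, seed=11))


def random_spectra(n, rng, max_peaks=40):
    """Random valid spectra with peaks straddling the 1000 Da cutoff."""
    out = []
    for i in range(n):
        k = int(rng.integers(1, max_peaks))
        mz = rng.uniform(10.0, 1100.0, size=k)
        inten = rng.uniform(0.1, 500.0, size=k)
        out.append(
            Spectrum(
                spectrum_id=f"r{i}",
                peaks=[Peak(float(m), float(x)) for m, x in zip(mz, inten)],
            )
        )
    return out
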