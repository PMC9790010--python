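from pathlib import Path

import numpy as np
import pytest

import ramanmatch as rm

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def preprocessor() -> rm.RamanPreprocessor:
    return rm.RamanPreprocessor().fit()


@pytest.fixture(scope="session")
def sim_library() -> rm.SimulatedLibrary:
    """Small simulated library reused across tests (4 classes x 2 reps)."""
    return rm.simulate_library(n_classes=4, reps_per_class=2, seed=11)


@pytest.fixture(scope="session")
def processed_library(sim_library, preprocessor) -> rm.SpectrumLibrary:
    spectra = [preprocessor.transform_spectrum(s) for s in sim_library.spectra]
    meta = [
        rm.SpecimenMetadata(
            unique_id=s.specimen_id,
            polymer=label,
            category="pristine anthropogenic",
            parent_grp="laboratory",
        )
        for s, label in zip(sim_library.spectra, sim_library.truth)
    ]
    return rm.SpectrumLibrary.from_spectra(spectra, meta)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_raw_spectrum(rng: np.random.Generator, n: int = 400,
                        cover_grid: bool = True) -> rm.RawSpectrum:
    """Random positive spectrum on an irregular axis (helper, not fixture)."""
    if cover_grid:
        w = np.sort(rng.uniform(190.0, 3410.0, n - 2))
        w = np.concatenate([[185.0], w, [3415.0]])
    else:
        w = np.sort(rng.uniform(400.0, 3000.0, n))
    w = np.unique(w)
    y = rng.uniform(0.5, 5.0, w.size) + 3.0
    return rm.RawSpectrum("rand", w, y)
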