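import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from evir.spectra_io import Spectrum, SpectralDataset  # noqa: E402
from evir import synthetic_data as sd  # noqa: E402


@pytest.fixture(scope="session")
def instrument_grid() -> np.ndarray:
    """650–4000 cm⁻¹ at 2 cm⁻¹ (the acquisition grid)."""
    return 650.0 + 2.0 * np.arange(1676)


@pytest.fixture(scope="session")
def planted_cohort() -> SpectralDataset:
    """Study-condition spectral cohort with the published group effects."""
    return sd.generate_cohort(sd.default_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def null_cohort() -> SpectralDataset:
    """Spectral cohort with no group effects at all."""
    return sd.generate_cohort(sd.null_cohort_spec(seed=12))


def make_spectrum(wn, ab, subject_id="s", group="unknown") -> Spectrum:
    return Spectrum(np.asarray(wn, float), np.asarray(ab, float), subject_id, group)


@pytest.fixture
def toy_dataset(instrument_grid) -> SpectralDataset:
    """Three labelled smooth spectra on the instrument grid."""
    g = instrument_grid
    return SpectralDataset(
        [
            make_spectrum(g, 1e-3 + np.exp(-0.5 * ((g - 1650) / 20) ** 2), "a", "control"),
            make_spectrum(g, 2e-3 + np.exp(-0.5 * ((g - 1655) / 22) ** 2), "b", "case"),
            make_spectrum(g, 1.5e-3 + 0.9 * np.exp(-0.5 * ((g - 1652) / 21) ** 2), "c", "control"),
        ]
    )
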