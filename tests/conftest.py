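import numpy as np
import pytest

from dermafluor import (
    GeneratorConfig,
    make_lesion_scan,
    make_spectrum,
    train_svm,
)
from dermafluor.preprocessing import truncate_spectrum
from dermafluor.synthetic_data import raw_wavelength_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_config():
    """Small photo/lesion for fast fixture generation."""
    return GeneratorConfig(photo_size_px=(64, 64), lesion_axes_px=(12, 8))


@pytest.fixture(scope="session")
def melanoma_scan(small_config):
    return make_lesion_scan(
        1, small_config, np.random.default_rng(7), lesion_id="mel-fix"
    )


@pytest.fixture(scope="session")
def spectrum_kind_model(small_config):
    """SVM trained to separate malignant-type from benign-type spectra.

    Labels here are the true spectrum kinds (no lesion-label noise), so the
    model is a near-perfect kind detector on fresh draws.
    """
    rng = np.random.default_rng(99)
    raw = raw_wavelength_grid()
    X = []
    y = []
    for kind, label in (("benign", 0), ("malignant", 1)):
        for _ in range(40):
            X.append(truncate_spectrum(make_spectrum(kind, small_config, rng), raw))
            y.append(label)
    return train_svm(np.array(X), np.array(y), C=0.165, scale=1000.0, degree=3)
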