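import numpy as np
import pytest

from spectradiet import (
    PreprocessConfig,
    Spectrum,
    SyntheticConfig,
    build_feature_table,
    default_class_profiles,
    generate_dataset,
    preprocess_sample,
)
from spectradiet.pipeline import _group_replicates


@pytest.fixture(scope="session")
def profiles():
    return default_class_profiles()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free generation: pure Gaussian sums on the default grid."""
    return SyntheticConfig(
        noise_sd=0.0, baseline_amplitude=0.0, sample_jitter_cv=0.0,
        n_samples_per_class=2, n_replicates=2, seed=0,
    )


@pytest.fixture(scope="session")
def small_config():
    """Small noisy dataset: 8 classes x 6 samples x 3 replicates."""
    return SyntheticConfig(n_samples_per_class=6, n_replicates=3, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Preprocessed feature tables (part and taxon-part labelings) of the
    small noisy dataset."""
    spectra, metas = small_dataset
    averaged = [
        preprocess_sample(reps, PreprocessConfig())
        for reps in _group_replicates(spectra).values()
    ]
    return {
        "part": build_feature_table(averaged, metas, label_mode="part"),
        "taxon_part": build_feature_table(averaged, metas, label_mode="taxon_part"),
        "averaged": averaged,
        "metas": metas,
    }


def gaussian_spectrum(centers, sigmas, heights, sample_id="s", grid=None,
                      replicate_id="r1"):
    """Build a Spectrum as an explicit sum of Gaussians on the default
    descending grid (independent of the generator's own evaluation code)."""
    if grid is None:
        grid = 4000.0 - 2.0 * np.arange(1801)
    a = np.zeros_like(grid)
    for c, s, h in zip(centers, sigmas, heights):
        a = a + h * np.exp(-0.5 * ((grid - c) / s) ** 2)
    return Spectrum(grid, a, sample_id, replicate_id)
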