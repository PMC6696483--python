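import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thzopenset as tzo

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset() -> tzo.SpectraDataset:
    """4 compound classes x 12 replicate spectra on a 300-subband grid."""
    return tzo.generate_dataset(n_classes=4, n_per_class=12, n_subbands=300, seed=7)


@pytest.fixture(scope="session")
def small_test_pool() -> tzo.SpectraDataset:
    """Later-measured batch of the same 4 classes (independent noise)."""
    return tzo.generate_dataset(n_classes=4, n_per_class=12, n_subbands=300,
                                seed=7, noise=tzo.NoiseConfig(seed=99),
                                measured_later=True)


@pytest.fixture(scope="session")
def binary_scores(small_dataset):
    """PC scores and +/-1 labels for the class-1-vs-rest subproblem."""
    pca = tzo.fit_pca(small_dataset, 8)
    scores = tzo.project(pca, small_dataset.absorbance)
    y = np.where(small_dataset.labels == 1, 1.0, -1.0)
    return scores, y, small_dataset.labels
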