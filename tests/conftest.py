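import numpy as np
import pytest

from memconn import AtlasLabels, Connectome, SimulationConfig, make_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_atlas() -> AtlasLabels:
    """10-ROI atlas: 3 DMN-C, 3 DMN-A, 2 other, 2 hippocampal."""
    return make_atlas({"DefaultC": 3, "DefaultA": 3, "VisCent": 2}, hippocampus_size=2)


@pytest.fixture
def small_config(small_atlas) -> SimulationConfig:
    return SimulationConfig(
        n_subjects=20,
        network_sizes={"DefaultC": 3, "DefaultA": 3, "VisCent": 2},
        hippocampus_size=2,
        n_runs=2,
        run_length=60,
        sampling_interval=1.0,
        seed=7,
    )


def random_connectome(rng: np.random.Generator, n_rois: int, roi_ids=None) -> Connectome:
    """A valid random correlation matrix (Gram matrix of random vectors)."""
    g = rng.standard_normal((n_rois + 5, n_rois))
    m = np.corrcoef(g, rowvar=False)
    m = np.clip((m + m.T) / 2, -1, 1)
    np.fill_diagonal(m, 1.0)
    ids = roi_ids if roi_ids is not None else [f"r{i}" for i in range(n_rois)]
    return Connectome(m, ids, "pearson_r")
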