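import numpy as np
import pytest

from octseg.synthetic import SimulationParams, make_benchmark_dataset


def tiny_params() -> SimulationParams:
    """16x16 scans for fast training tests."""
    return SimulationParams(
        height=16,
        width=16,
        layer_thickness=(1,) * 10,
        top_margin=3.0,
        fovea_depth=1.0,
        fovea_width=3.0,
        boundary_smoothness=0.3,
        speckle=0.12,
        cyst_count_range=(1, 1),
        cyst_semiaxis_rows=(1.0, 1.5),
        cyst_semiaxis_cols=(1.5, 2.5),
        collapse_extent=(3, 6),
    )


@pytest.fixture
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture
def small_params() -> SimulationParams:
    return tiny_params()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small on-disk dataset: 4 labeled + 12 unlabeled train scans, 2 val, 4 test."""
    out = tmp_path_factory.mktemp("tinydata")
    manifest = make_benchmark_dataset(
        tiny_params(),
        seed=7,
        out_dir=out,
        n_labeled_patients=2,
        n_unlabeled_patients=6,
        n_val_patients=1,
        n_test_patients=2,
        scans_per_patient=2,
    )
    return manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
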