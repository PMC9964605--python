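import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sgcsrm.features import BandFeatureTensor
from sgcsrm.graph import ElectrodeLayout
from sgcsrm.synthetic import SyntheticSpec, generate_de_dataset, resolve_layout


@pytest.fixture(scope="session")
def tiny_layout():
    """Four electrodes on a small tetrahedron-like arrangement."""
    coords = np.array(
        [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0], [2.0, 2.0, 2.0]]
    )
    return ElectrodeLayout(("A", "B", "C", "D"), coords)


@pytest.fixture(scope="session")
def small_spec():
    """A fast synthetic world: 3 subjects, 12 channels, 2 bands, 8 windows."""
    return SyntheticSpec(
        n_subjects=3,
        trials_per_class_per_subject=4,
        n_channels=12,
        bands=("alpha", "beta"),
        n_windows=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    tensor, truth = generate_de_dataset(small_spec)
    return tensor, truth, resolve_layout(small_spec)


@pytest.fixture
def random_tensor():
    """An unstructured 2-subject feature tensor for bookkeeping tests."""
    rng = np.random.default_rng(0)
    n, c, b, d = 10, 5, 3, 6
    return BandFeatureTensor(
        values=rng.normal(size=(n, c, b, d)),
        channel_names=("c1", "c2", "c3", "c4", "c5"),
        band_names=("theta", "alpha", "beta"),
        subject_ids=np.array(["s0"] * 5 + ["s1"] * 5),
        labels=np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0]),
        feature_kind="DE",
    )
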