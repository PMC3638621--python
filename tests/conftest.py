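import numpy as np
import pytest

from zhengkit.dataset_io import SymptomDataset
from zhengkit.synthetic import (
    SimulationConfig,
    simulate_annotation_fixture,
    simulate_dataset,
    write_annotation_fixture,
)


@pytest.fixture(scope="session")
def reference_shaped_dataset():
    """166 patients, 120/46 imbalance, 102 symptoms, strong planted signal."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def weak_signal_dataset():
    """Same shape with a weak class signal (0.65 vs 0.35) so the classifier
    does not saturate and undersampling has room to help."""
    return simulate_dataset(
        SimulationConfig(p_informative_pos=0.65, p_informative_neg=0.35, seed=11)
    )


@pytest.fixture(scope="session")
def annotation_fixture():
    return simulate_annotation_fixture(seed=2)


@pytest.fixture(scope="session")
def annotation_paths(annotation_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("annotations")
    return write_annotation_fixture(annotation_fixture, outdir)


@pytest.fixture
def tiny_dataset():
    """4 patients x 2 symptoms, labels (1,1,0,0)."""
    return SymptomDataset(
        sample_ids=("a", "b", "c", "d"),
        symptom_names=("cough", "fever"),
        matrix=np.array([[1, 0], [1, 1], [0, 1], [0, 0]], dtype=float),
        labels=np.array([1, 1, 0, 0]),
    )


def make_dataset(matrix, labels, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or tuple(f"s{j}" for j in range(matrix.shape[1]))
    return SymptomDataset(
        sample_ids=tuple(f"p{i}" for i in range(matrix.shape[0])),
        symptom_names=tuple(names),
        matrix=matrix,
        labels=np.asarray(labels, dtype=int),
    )
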