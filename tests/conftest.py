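import numpy as np
import pytest

from dynhar.dims import ArchDims
from dynhar.synthetic import (
    GeneratorConfig,
    LabeledDataset,
    SensorWindow,
    default_class_specs,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Three stock classes, 10 windows each, 300x6 windows."""
    return GeneratorConfig(class_specs=default_class_specs(), n_per_class=10, seed=7)


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def tiny_dims():
    return ArchDims(ni=2, nd=3, nh=2, nc=3)


def make_windows(values_list, labels, prefix="w"):
    """Build a LabeledDataset from explicit (NT, 6) arrays."""
    windows = [
        SensorWindow(np.asarray(v, float), int(lab), f"{prefix}{i:03d}")
        for i, (v, lab) in enumerate(zip(values_list, labels))
    ]
    class_names = {c: f"class_{c}" for c in sorted({int(l) for l in labels})}
    return LabeledDataset(windows, class_names)


@pytest.fixture
def make_dataset():
    return make_windows
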