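import numpy as np
import pandas as pd
import pytest

from coronalign.atlas import SlicePose, slice_volume
from coronalign.quantify import Ontology
from coronalign.register import OptimizerConfig
from coronalign.preprocess import PreprocessConfig
from coronalign.synthetic import PhantomSpec, make_phantom_volume


@pytest.fixture(scope="session")
def phantom():
    """Session-wide brain-like phantom volume."""
    return make_phantom_volume(PhantomSpec(shape=(96, 96, 112), n_regions=5, seed=3))


@pytest.fixture(scope="session")
def mid_pose():
    return SlicePose(x_angle_deg=0.0, y_angle_deg=0.0, ap_index=48.0)


@pytest.fixture(scope="session")
def mid_section(phantom, mid_pose):
    return slice_volume(phantom, mid_pose)


@pytest.fixture
def fast_cfgs():
    """Reduced-size configs for unit tests of the fitting machinery."""
    return (
        PreprocessConfig(working_size=192, pad_px=20),
        OptimizerConfig(),
    )


@pytest.fixture
def toy_ontology():
    """3-level toy tree: root -> {cortex, midbrain}; cortex -> {L1, L2}; midbrain -> {MB1}."""
    return Ontology(pd.DataFrame({
        "id": [1, 2, 3, 4, 5, 6],
        "acronym": ["root", "CTX", "MB", "L1", "L2", "MB1"],
        "name": ["root", "cortex", "midbrain", "layer 1", "layer 2", "nucleus 1"],
        "parent_id": [np.nan, 1, 1, 2, 2, 3],
    }))
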