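import numpy as np
import pytest

from bndecode import (
    GenerativeModel,
    generate_response_dataset,
    generate_voxel_geometry,
    make_generative_model,
)


@pytest.fixture(scope="session")
def geometry20():
    return generate_voxel_geometry(20, {"BA18": 10, "BA19": 10}, seed=0)


@pytest.fixture(scope="session")
def planted_dataset(geometry20):
    """10-class dataset with 3 planted local couplings (weight 1.5, sd 1)."""
    model = make_generative_model(geometry20, n_classes=10, n_edges=3, seed=0)
    tm = generate_response_dataset(model, 60, geometry20, seed=1)
    return tm, model


@pytest.fixture(scope="session")
def independent_dataset(geometry20):
    """10-class dataset with no attribute couplings."""
    model = make_generative_model(geometry20, n_classes=10, n_edges=0, seed=0)
    tm = generate_response_dataset(model, 60, geometry20, seed=2)
    return tm, model


@pytest.fixture()
def tiny_model():
    """3 voxels, 2 classes, one planted edge 0 -> 1 of weight 2."""
    return GenerativeModel(
        n_classes=2,
        class_means=np.array([[0.0, 0.0, 1.0], [1.0, 0.0, -1.0]]),
        edges=((0, 1),),
        edge_weights={(0, 1): 2.0},
        noise_sd=1.0,
    )
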