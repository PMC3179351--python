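import numpy as np
import pytest

import vertload as v


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom with ground truth."""
    return v.generate_phantom(v.PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def peeled_phantom(default_phantom):
    vol, gt = default_phantom
    return v.peel_shell_endplates(vol), gt


@pytest.fixture(scope="session")
def classified_phantom(peeled_phantom):
    labels, gt = peeled_phantom
    trab = v.LabeledVolume((labels.data == 1).astype(np.uint8), labels.voxel_size_um)
    return labels, v.classify_trabeculae(trab), gt


@pytest.fixture(scope="session")
def solid_block_result():
    """Solved 20^3 homogeneous block at 60 µm, frictionless, no PMMA."""
    labels = v.LabeledVolume(np.ones((20, 20, 20), np.uint8), 60.0)
    model = v.build_fe_model(
        labels, v.MaterialSpec(), v.LoadCase(pmma_layer_thickness_vox=0), include_shell=True
    )
    return model, v.solve(model, rel_tol=1e-8)
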