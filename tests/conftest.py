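import numpy as np
import pytest

from resectnet.synthetic import PhantomSpec, default_target_connectome, make_parcellation, make_streamlines


@pytest.fixture(scope="session")
def phantom():
    """One deterministic phantom subject shared across tests."""
    spec = PhantomSpec(seed=11)
    spec.target_connectome = default_target_connectome(spec.n_regions, seed=11)
    parc = make_parcellation(spec)
    sls = make_streamlines(spec, parc)
    return spec, parc, sls


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_parcellation():
    """Three regions (1, 2, 3) as single-voxel-thick slabs on a 9x3x3 grid
    with an identity affine; labels: x=1 -> 1, x=4 -> 2, x=7 -> 3."""
    from resectnet.io import Parcellation

    labels = np.zeros((9, 3, 3), dtype=np.int32)
    labels[1] = 1
    labels[4] = 2
    labels[7] = 3
    return Parcellation(labels=labels, voxel_to_world=np.eye(4))
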