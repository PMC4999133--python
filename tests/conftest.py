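import numpy as np
import pytest

from scdmri import phantom as ph
from scdmri.schemes import builtin_protocol


@pytest.fixture(scope="session")
def protocol_a():
    return builtin_protocol("A")


@pytest.fixture(scope="session")
def protocol_b():
    return builtin_protocol("B")


@pytest.fixture(scope="session")
def protocol_c():
    return builtin_protocol("C")


@pytest.fixture
def small_spec():
    """Small noiseless phantom spec for exactness tests."""
    return ph.PhantomSpec(grid=(32, 32, 2), noise_sigma=0.0, subject_cv=0.0)


@pytest.fixture
def wt_subject(small_spec):
    return ph.make_subject(small_spec, "WT01", group="WT",
                           timepoint="week10", seed=7)


def make_flat_study(protocol, tensor6, s0, n_voxels, sigma, seed,
                    n_averages=None):
    """A study of identical voxels with a given ground-truth tensor.

    Shapes the voxels as (n, 1, 1) so estimator code paths see a real
    volume; noise follows the protocol averaging unless ``n_averages``
    overrides it with a bare single-acquisition draw.
    """
    from scdmri.estimators import tensor_to_matrix
    from scdmri.schemes import AcquisitionProtocol

    D = tensor_to_matrix(np.asarray(tensor6, dtype=float))
    scheme = protocol.scheme
    b = scheme.full_bvalues()
    g = scheme.full_directions()
    att = np.exp(-b * np.einsum("vi,ij,vj->v", g, D, g))
    clean = np.tile(s0 * att, (n_voxels, 1, 1, 1))
    if n_averages is not None:
        protocol = AcquisitionProtocol(name=protocol.name, scheme=scheme,
                                       n_averages=n_averages, n_repetitions=1)
    return ph.add_noise_and_average(clean, protocol, sigma, seed)
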