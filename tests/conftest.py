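"""Shared small-geometry fixtures.

Most tests use subdivision-3 heads (642 vertices per layer): the geometry is
identical in kind to the default subdivision-4 surfaces but ~4x cheaper.
Mesh-resolution assertions build their own subdivision-4 head.
"""

import numpy as np
import pytest

from megsim import make_head, make_source_space
from megsim.sensor_arrays import build_opm_array, build_squid_arrays, place_opm_sites


@pytest.fixture(scope="session")
def head():
    """Perturbed mid-size head (subdivision 3)."""
    return make_head(scalp_radius=0.092, subdivision=3, perturbation=0.02, seed=5)


@pytest.fixture(scope="session")
def smooth_head():
    """Exactly spherical head: analytic expectations hold exactly."""
    return make_head(scalp_radius=0.092, subdivision=3, perturbation=0.0, seed=0)


@pytest.fixture(scope="session")
def source_space(head):
    return make_source_space(head, n_candidates=600, seed=7)


@pytest.fixture(scope="session")
def opm_sites(head):
    return place_opm_sites(head, seed=5)


@pytest.fixture(scope="session")
def opm_nor(head, opm_sites):
    sites, triads = opm_sites
    return build_opm_array(sites, triads, components=("NOR",), subject_id=head.subject_id)


@pytest.fixture(scope="session")
def opm_all(head, opm_sites):
    sites, triads = opm_sites
    return build_opm_array(sites, triads, subject_id=head.subject_id)


@pytest.fixture(scope="session")
def squid_arrays(head):
    return build_squid_arrays(head, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
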