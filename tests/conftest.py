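"""Shared fixtures: coarse synthetic anatomy and its BEM operator.

The coarse anatomy (subdivision 2 everywhere) keeps the BEM system small
enough for fast unit tests; resolution-sensitive acceptance checks use the
default resolution instead.
"""

import numpy as np
import pytest

from edlsim.activation import default_foci, ventricular_activation
from edlsim.anatomy import (
    PATCH_LOCATIONS,
    Compartment,
    SyntheticAnatomyParams,
    make_synthetic_anatomy,
    _ellipsoid_inside,
)
from edlsim.bem import VolumeConductor
from edlsim.mesh import icosphere
from edlsim.patch import PatchSpec, embed_patch


def coarse_params() -> SyntheticAnatomyParams:
    return SyntheticAnatomyParams(torso_subdiv=2, epi_subdiv=2)


@pytest.fixture(scope="session")
def anatomy():
    return make_synthetic_anatomy(coarse_params(), seed=1)


@pytest.fixture(scope="session")
def conductor(anatomy):
    return VolumeConductor(anatomy)


@pytest.fixture(scope="session")
def foci(anatomy):
    return default_foci(anatomy)


@pytest.fixture(scope="session")
def vmap(anatomy, foci):
    return ventricular_activation(anatomy.ventricles, foci)


def free_wall_patch_spec(anatomy, **kwargs) -> PatchSpec:
    center = anatomy.source_surface.vertices.mean(axis=0) + 60.0 * PATCH_LOCATIONS[
        "rv_free_wall"
    ] / np.linalg.norm(PATCH_LOCATIONS["rv_free_wall"])
    defaults = dict(center=center, radius=15.0, depth=3.0)
    defaults.update(kwargs)
    return PatchSpec(**defaults)


@pytest.fixture(scope="session")
def patched(anatomy):
    return embed_patch(anatomy.ventricles, free_wall_patch_spec(anatomy))


class SphereAnatomy:
    """Homogeneous conducting sphere: the analytic-oracle conductor."""

    def __init__(self, radius=100.0, sigma=0.2, subdiv=3):
        surface = icosphere(subdiv, radius, "sphere")
        self.compartments = [
            Compartment(
                surface, sigma, 0.0, _ellipsoid_inside((0, 0, 0), (radius,) * 3)
            )
        ]
        self.sigma_myocardium = sigma
        self.torso_index = 0
        self.radius = radius
        self._electrodes = np.arange(surface.n_vertices)

    @property
    def surface(self):
        return self.compartments[0].surface

    def electrode_node_indices(self):
        return self._electrodes

    def conductivity_at(self, points):
        inside = self.compartments[0].contains(points)
        return inside * self.compartments[0].sigma_in


@pytest.fixture(scope="session")
def sphere_anatomy():
    return SphereAnatomy()
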