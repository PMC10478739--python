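"""Shared fixtures: coarse study domains and synthetic uniform-tissue domains.

Everything is generated programmatically; module/session scoping keeps the
expensive pieces (numba compilation, Monte Carlo runs) shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pttsim.domain import TissueDomain, TissueLayer, TUMOR, _attach_optics_tables, build_domain
from pttsim.optics.mixing import MediumOpticalProperties
from pttsim.transport import BeamSpec, run_transport


def make_uniform_domain(
    shape: tuple[int, int, int],
    voxel_size: float,
    optics: MediumOpticalProperties,
    k_m: float = 0.49,
    c_v: float = 3421.0,
    rho: float = 1070.0,
    w_b: float = 0.0063,
) -> TissueDomain:
    """Homogeneous single-tissue block (no exterior, no layering).

    Used for analytic verification cases: slabs, pure absorbers, uniform
    perfused media.  Default thermal properties are the tumor's.
    """
    layer = TissueLayer("uniform", 1.0, k_m, c_v, rho, w_b, optics)
    tissue = np.full(shape, TUMOR, dtype=np.uint8)
    dom = TissueDomain(
        voxel_size=voxel_size,
        tissue_id=tissue,
        layers={TUMOR: layer},
        f_v=0.0,
        origin=(-shape[0] * voxel_size / 2, -shape[1] * voxel_size / 2, 0.0),
    )
    _attach_optics_tables(dom)
    return dom


@pytest.fixture(scope="session")
def coarse_domain():
    """Full treatment scenario at 0.4 mm, f_v = 1e-6."""
    return build_domain(voxel_size=0.4, f_v=1e-6)


@pytest.fixture(scope="session")
def coarse_transport(coarse_domain):
    """Vertical-incidence Monte Carlo on the coarse domain (unit power)."""
    return run_transport(coarse_domain, BeamSpec(power=1.0, angle_deg=0.0), 150_000, seed=11)
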