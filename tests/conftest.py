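"""Shared fixtures: the default scenario at reduced stream count.

The session-scoped fixtures hold the expensive objects (domain, solved
field, advected scenario) so the suite builds them once.  The scenario uses
the default study conditions (spray distribution, hot-spot layout, mucus
calibration, 4 h absorption horizon) with a reduced number of droplet
streams per bin, which only widens sampling noise on the regional split.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mucoclear.clearance import advect_particles
from mucoclear.deposition import generate_deposition
from mucoclear.domain import (
    DEFAULT_REGIONS,
    REGION_IDS,
    SurfaceDomain,
    build_synthetic_domain,
)
from mucoclear.mucus_flow import MucusField, default_swirl, solve_mucus_field
from mucoclear.spray import SprayConfig, build_droplet_population

SCENARIO_SEED = 1
SCENARIO_STREAMS_PER_BIN = 40


@pytest.fixture(scope="session")
def domain() -> SurfaceDomain:
    return build_synthetic_domain()


@pytest.fixture(scope="session")
def potential_field(domain) -> MucusField:
    """Calibrated field without the recirculation perturbation."""
    return solve_mucus_field(domain)


@pytest.fixture(scope="session")
def field(domain) -> MucusField:
    """Calibrated field with the default recirculation vortices."""
    return solve_mucus_field(domain, swirl=default_swirl(domain))


@pytest.fixture(scope="session")
def population():
    return build_droplet_population(SprayConfig(streams_per_bin=SCENARIO_STREAMS_PER_BIN))


@pytest.fixture(scope="session")
def deposited(population, domain):
    return generate_deposition(population, domain, seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario(deposited, field):
    """Advected default scenario: 4 h horizon, 2 s steps."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return advect_particles(
            deposited.x_mm,
            deposited.y_mm,
            field,
            dt_s=2.0,
            horizon_s=14400.0,
            snapshot_times_s=(0.0, 60.0, 600.0, 1800.0),
        )


def make_strip_domain(
    n_cols: int = 30,
    n_rows: int = 3,
    cell_mm: float = 1.0,
    boundary_col: int | None = None,
) -> SurfaceDomain:
    """Minimal straight-channel domain: main passage ending in a nasopharynx
    outlet column; optionally a septum band before ``boundary_col``."""
    region = np.full((n_rows, n_cols), REGION_IDS["main_passage"], dtype=np.int64)
    if boundary_col is not None:
        region[:, :boundary_col] = REGION_IDS["septum"]
    region[:, -1] = REGION_IDS["nasopharynx"]
    is_outlet = np.zeros_like(region, dtype=bool)
    is_outlet[:, -1] = True
    dom = SurfaceDomain(
        cell_size_mm=cell_mm,
        x_mm=(np.arange(n_cols) + 0.5) * cell_mm,
        y_mm=(np.arange(n_rows) + 0.5) * cell_mm,
        region_id=region,
        area_cm2=np.full(region.shape, 0.01 * cell_mm * cell_mm),
        width_factor=np.ones(region.shape),
        is_outlet=is_outlet,
        is_ostium=np.zeros_like(region, dtype=bool),
        chamber=np.full(region.shape, 2, dtype=np.int8),
        regions=dict(DEFAULT_REGIONS),
    )
    dom.validate()
    return dom


def uniform_field(dom: SurfaceDomain, vx_mm_min: float, vy_mm_min: float = 0.0) -> MucusField:
    shape = dom.region_id.shape
    return MucusField(
        domain=dom,
        vx_mm_min=np.full(shape, vx_mm_min),
        vy_mm_min=np.full(shape, vy_mm_min),
        source=np.zeros(shape),
        potential=np.zeros(shape),
        source_flux=0.0,
        outlet_flux=0.0,
    )
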