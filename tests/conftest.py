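import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_run():
    """Full assay simulation (thermal + all 13 size bins) on a coarse grid."""
    from evglyco.synthdata import gen_size_distribution
    from evglyco.thermosim import ChamberGeometry, LaserSource, simulate_enrichment

    geom = ChamberGeometry(grid_nr=32, grid_nz_fluid=16)
    return simulate_enrichment(geom, LaserSource(), gen_size_distribution(seed=1))


@pytest.fixture(scope="session")
def default_run():
    """Full assay simulation on the production grid (64 x 32 fluid cells)."""
    from evglyco.synthdata import gen_size_distribution
    from evglyco.thermosim import ChamberGeometry, LaserSource, simulate_enrichment

    return simulate_enrichment(ChamberGeometry(), LaserSource(),
                               gen_size_distribution(seed=1))


@pytest.fixture(scope="session")
def coarse_solution(coarse_run):
    return coarse_run.solution
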