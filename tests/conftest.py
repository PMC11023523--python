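import numpy as np
import pytest

import polarweave as pw


@pytest.fixture(scope="session")
def small_lattice():
    """~300-cell disordered network at reference density (session-cached)."""
    n = 300
    spec = pw.LatticeSpec(domain_radius=pw.scaled_domain_radius(n),
                          target_cell_count=n, mean_spacing=22.5, rng_seed=7)
    return pw.build_lattice(spec)


@pytest.fixture(scope="session")
def medium_lattice():
    """~5,000-cell network for statistical checks (session-cached)."""
    n = 5000
    spec = pw.LatticeSpec(domain_radius=pw.scaled_domain_radius(n),
                          target_cell_count=n, mean_spacing=22.5, rng_seed=1)
    return pw.build_lattice(spec)


@pytest.fixture
def vortex_grid():
    """21x21 grid at PIV spacing with a counterclockwise vortex at center."""
    x, y = pw.make_grid(20 * 66.0, 21)
    frame = pw.compose_defect_field(
        [pw.DefectSpec((x[10], y[10]), +1, np.pi / 2)], x, y)
    return frame


@pytest.fixture
def saddle_grid():
    x, y = pw.make_grid(20 * 66.0, 21)
    return pw.compose_defect_field(
        [pw.DefectSpec((x[10], y[10]), -1, 0.0)], x, y)
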