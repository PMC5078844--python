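"""Shared fixtures: small analytic configurations and cached heavy results."""

from __future__ import annotations

import pytest

from chorioflow.geometry import (
    Opening,
    OpeningConfiguration,
    generate_lattice_openings,
    generate_random_openings,
)


@pytest.fixture(scope="session")
def dipole():
    """Source +1 at (-1,0), sink -1 at (+1,0): the minimal balanced flow."""
    return OpeningConfiguration((
        Opening(0, "arteriolar", -1.0, 0.0, 1.0),
        Opening(1, "venular", 1.0, 0.0, -1.0),
    ))


@pytest.fixture(scope="session")
def two_sources():
    """Two equal sources; the sink is the point at infinity."""
    return OpeningConfiguration(
        (
            Opening(0, "arteriolar", -1.0, 0.0, 1.0),
            Opening(1, "arteriolar", 1.0, 0.0, 1.0),
        ),
        domain="plane_with_infinity",
    )


@pytest.fixture(scope="session")
def quadrupole():
    """Fully symmetric quadrupole: sources at +-1, sinks at +-i."""
    return OpeningConfiguration((
        Opening(0, "arteriolar", -1.0, 0.0, 1.0),
        Opening(1, "arteriolar", 1.0, 0.0, 1.0),
        Opening(2, "venular", 0.0, 1.0, -1.0),
        Opening(3, "venular", 0.0, -1.0, -1.0),
    ))


@pytest.fixture(scope="session")
def dye_benchmark_config():
    """Two sources at (+-1, 0), two drains at (0, +-2): by mirror symmetry
    the separatrix between the two arteriolar territories is the y-axis."""
    a = 0.1
    return OpeningConfiguration((
        Opening(0, "arteriolar", -1.0, 0.0, 1.0, a),
        Opening(1, "arteriolar", 1.0, 0.0, 1.0, a),
        Opening(2, "venular", 0.0, 2.0, -1.0, a),
        Opening(3, "venular", 0.0, -2.0, -1.0, a),
    ))


@pytest.fixture(scope="session")
def random_config():
    """Generic balanced scatter: 4 arterioles, 6 venules."""
    return generate_random_openings(4, 6, seed=7)


@pytest.fixture(scope="session")
def square_lattice():
    return generate_lattice_openings("square", 3)


@pytest.fixture(scope="session")
def square_lattice_segments(square_lattice):
    from chorioflow.segmentation import build_segments

    return build_segments(square_lattice)


@pytest.fixture(scope="session")
def central_square_segment(square_lattice_segments):
    """The interior cell of the 3x3 square lattice: a near-perfect square."""
    seg = [s for s in square_lattice_segments if s.arteriole_id == 4][0]
    assert seg.polygon is not None
    return seg


@pytest.fixture(scope="session")
def dye_sim_small(dye_benchmark_config):
    """Medium-resolution dye run on the two-source benchmark, reused by
    several field-level checks."""
    from chorioflow.dye import simulate_dye

    return simulate_dye(
        dye_benchmark_config,
        grid_n=160,
        D=2e-3,
        schedule=(0.0, 6.0),
        t_end=9.0,
        output_stride=25,
        bound_radius=3.0,
    )
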