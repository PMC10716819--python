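import pytest

from photopath import (
    FixtureSpec,
    SourceParams,
    gen_grid_monolayer,
    gen_multilayer_square,
    gen_spherical_cap_infill,
)


@pytest.fixture(scope="session")
def grid_path():
    """Single-layer 20 x 20 mm crosshatch grid at 1 mm pitch, 5 mm/s."""
    return gen_grid_monolayer(FixtureSpec(n_layers=1, infill=40.0))


@pytest.fixture(scope="session")
def multilayer_path():
    """6-layer 20 x 20 mm square, 0.2 mm layers, 50% infill."""
    return gen_multilayer_square(FixtureSpec(n_layers=6))


@pytest.fixture(scope="session")
def cap_path():
    """Two-layer conformal infill over a spherical cap."""
    return gen_spherical_cap_infill(FixtureSpec(n_layers=2))


@pytest.fixture(scope="session")
def all_fixture_paths(grid_path, multilayer_path, cap_path):
    return {
        "grid_monolayer": grid_path,
        "multilayer_square": multilayer_path,
        "spherical_cap": cap_path,
    }


@pytest.fixture(scope="session")
def src_max_distance():
    """Source at maximum LED-substrate distance (spot 20 mm), 5 mm/s."""
    return SourceParams(v_s=5.0, distance=15.0)
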