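import matplotlib
import pytest

matplotlib.use("Agg")

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci",
        derandomize=True,
        deadline=None,
        max_examples=25,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_lattice():
    from islandfate.lattice import build_disc_hex_lattice

    return build_disc_hex_lattice(2)


@pytest.fixture(scope="session")
def two_cell_lattice():
    """Minimal two-cell chain for scalar oracles."""
    import numpy as np

    from islandfate.lattice import HexLattice

    return HexLattice(
        positions=np.array([[0.0, 0.0], [1.0, 0.0]]),
        adjacency=((1,), (0,)),
    )
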