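import pytest

from leapdeg import (
    EdgePartition,
    build_gamma_nanoribbon,
    build_zigzag_nanoribbon,
    fixture_graph,
)


@pytest.fixture(scope="session")
def c6():
    return fixture_graph("cycle", 6)


@pytest.fixture(scope="session")
def c6_partition():
    return EdgePartition(2, {(2, 2): 6})


@pytest.fixture(scope="session")
def gnr11():
    return build_gamma_nanoribbon(1, 1)


@pytest.fixture(scope="session")
def zgnr3():
    return build_zigzag_nanoribbon(3)


@pytest.fixture(scope="session")
def small_fixtures():
    """Assorted small graphs exercising paths, cycles, stars, cliques,
    disconnected and random topologies."""
    return {
        "p4": fixture_graph("path", 4),
        "c6": fixture_graph("cycle", 6),
        "star4": fixture_graph("star", 4),
        "k4": fixture_graph("complete", 4),
        "rand30": fixture_graph("random", 30, seed=7),
        "rand12": fixture_graph("random", 12, seed=3),
    }
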