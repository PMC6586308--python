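import pytest

import mousestr as M


@pytest.fixture(scope="session")
def panel():
    return M.load_panel()


@pytest.fixture(scope="session")
def core_panel():
    return M.load_panel(version="core18")


@pytest.fixture(scope="session")
def table6():
    """The 21 concordant cell-line profiles, keyed by sample id."""
    return {p.sample_id: p for p in M.load_fixture("table6")}


@pytest.fixture(scope="session")
def table5():
    """The 12-laboratory NIH/3T3 call table."""
    return M.load_fixture("table5")


@pytest.fixture(scope="session")
def calibrant1():
    return M.load_fixture("table10")


@pytest.fixture(scope="session")
def offsets(panel):
    return M.synthetic_anchor_sizes(panel)


@pytest.fixture(scope="session")
def calibrant_binset(panel, calibrant1, offsets):
    """Bin set anchored on Calibrant 1 under the synthetic size model."""
    anchors = M.anchors_from_profile(
        {m: list(a) for m, a in calibrant1.calls.items()}, offsets
    )
    return M.build_binset(panel, anchors)
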