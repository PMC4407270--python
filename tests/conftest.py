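import pytest

from rfbsim.locus import LocusMap, Origin, Side, TimingParams, packaged_origin_map


@pytest.fixture(scope="session")
def timing():
    return TimingParams()


@pytest.fixture(scope="session")
def barrier_map():
    """The packaged eight-origin map, active orientation."""
    return packaged_origin_map("AO")


@pytest.fixture(scope="session")
def barrier_map_io():
    return packaged_origin_map("IO")


@pytest.fixture
def toy_map():
    """One blocking origin at 3 kb (1.0 min), one converging at 30 kb
    (10.0 min), both 50% efficient: window 9.0 min when both fire."""
    return LocusMap(
        "AO",
        (
            Origin("b1", Side.BLOCKING, 3000, 0.5),
            Origin("c1", Side.CONVERGING, 30000, 0.5),
        ),
    )
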