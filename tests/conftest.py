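import numpy as np
import pytest

from mucoperm.plate_io import ExperimentGeometry, WellSeries


@pytest.fixture
def geometry() -> ExperimentGeometry:
    """The 24-well ThinCert protocol geometry (300/900 µL, 0.336 cm², hourly x4)."""
    return ExperimentGeometry.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_series(
    baso,
    stock=1000.0,
    well_id="w1",
    role="cells",
    compound="ibuprofen",
    channel="mAU_min",
    **kw,
):
    return WellSeries(
        well_id=well_id,
        role=role,
        compound=compound,
        channel=channel,
        baso_signal=np.asarray(baso, dtype=float),
        stock_signal=stock,
        **kw,
    )
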