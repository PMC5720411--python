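import numpy as np
import pytest

from transitdose import (
    BeamGeometry,
    load_default_tables,
    make_breast_slice,
    make_cylinder_slice,
)


@pytest.fixture(scope="session")
def beam():
    return BeamGeometry()


@pytest.fixture(scope="session")
def calib():
    return load_default_tables()


@pytest.fixture(scope="session")
def cylinder_825():
    """Calibration cylinder r = 8.25 cm, centred on the isocenter."""
    return make_cylinder_slice(8.25, spacing=0.25)


@pytest.fixture(scope="session")
def breast_slice():
    """Default breast phantom: 7 cm apex radius, lung at density 0.3."""
    return make_breast_slice()


@pytest.fixture(autouse=True)
def _quiet_range_warnings():
    """Silence expected out-of-range warnings from near-apex fan lines."""
    import warnings

    from transitdose.calibration import CalibrationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
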