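import warnings

import pytest

from supercoil import fit_calibration
from supercoil.tables import calibration_pairs, survey_tables


@pytest.fixture(scope="session")
def curve():
    """Default response curve: anchors plus the survey table pairs.

    The Ter-proximal sensor row is a known monotonicity outlier, so the fit
    emits its residual warning; that is expected here.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return fit_calibration(calibration_pairs())


@pytest.fixture(scope="session")
def anchor_curve():
    """Curve defined by the three stated response anchors alone."""
    from supercoil import DEFAULT_ANCHORS
    return fit_calibration([], DEFAULT_ANCHORS)


@pytest.fixture(scope="session")
def tables():
    return survey_tables()
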