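import numpy as np
import pytest

from valveform import synthetic as syn


@pytest.fixture()
def disk_frame():
    """Noiseless bright disk (radius 15) on a flat background."""
    yy, xx = np.mgrid[0:96, 0:96]
    img = np.where((xx - 48) ** 2 + (yy - 48) ** 2 <= 15**2, 150.0, 50.0)
    return img, (48.0, 48.0), 15.0


@pytest.fixture()
def default_times():
    """5-min sampling over 150 min, the study's acquisition grid."""
    return np.arange(0, 155, 5.0)


@pytest.fixture()
def two_phase_params():
    """Kinetics at the population means: t_Exp = 90 min, t_Dec = 47 min."""
    return syn.KineticParams(k=0.013, F0=200.0, t_peak=90.0, t_dec=47.0)
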