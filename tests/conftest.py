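import numpy as np
import pytest

from amaresfit import FidSeries
from amaresfit.prior_knowledge import PeakPrior, compile_prior


def make_meta(n=512, dwell=5e-4, f0=120.3, **kw):
    return FidSeries(samples=None, n_points=n, dwell_time=dwell,
                     transmitter_freq=f0, **kw)


def two_peak_priors(amp_pcr=1.0, amp_atp=0.7):
    """Two well-separated Lorentzian singlets sharing one phase."""
    return [
        PeakPrior(name="PCR", shift_start=0.0, linewidth_start=10.0,
                  linewidth_lower=2.0, linewidth_upper=40.0,
                  amplitude_start=amp_pcr, amplitude_upper=20.0,
                  group_phase="g"),
        PeakPrior(name="ATP", shift_start=-2.5, linewidth_start=14.0,
                  linewidth_lower=2.0, linewidth_upper=60.0,
                  amplitude_start=amp_atp, amplitude_upper=20.0,
                  group_phase="g"),
    ]


@pytest.fixture
def meta512():
    return make_meta()


@pytest.fixture
def two_peak_cmap():
    return compile_prior(two_peak_priors())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
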