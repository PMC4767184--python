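import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dcekinetics import ScanSchedule, TIC

settings.register_profile(
    "det", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def schedule():
    return ScanSchedule()


def make_tic(post_signals, s0=6000.0, subject_id="t", dose=0.2):
    """TIC on the default time grid truncated to len(post_signals) scans."""
    post_signals = np.asarray(post_signals, dtype=float)
    sched = ScanSchedule(n_post=len(post_signals))
    return TIC(s0=s0, s=post_signals,
               times=np.array(sched.completion_times),
               subject_id=subject_id, dose=dose)


@pytest.fixture
def washout_curve():
    """39-scan curve peaking at scan 2 (108 s) with linear washout."""
    s = np.empty(39)
    s[0] = 14000.0
    s[1] = 15000.0
    s[1:] = 15000.0 - 162.162162 * np.arange(38)
    s[-1] = 9000.0
    return make_tic(s, s0=6000.0)
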