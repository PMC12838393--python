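import numpy as np
import pytest

from vancohd.pk import (
    DEFAULT_HD_POP,
    DoseEvent,
    HDSession,
    HDSettings,
)


@pytest.fixture
def pop():
    return DEFAULT_HD_POP


@pytest.fixture
def settings():
    return HDSettings(
        q_blood=174.6, q_dialysate=500.0, q_uf=10.0,
        cl_b12_baseline=130.0, cl_cr_baseline=170.0,
        q_blood_ref=200.0, q_dialysate_ref=500.0,
    )


@pytest.fixture
def hd_scenario(settings):
    """Loading dose, first HD at 39.3 h, post-dialytic maintenance, second
    HD 48 h later — the canonical thrice-weekly first-interval history."""
    sessions = [HDSession(start=39.3, duration=3.5),
                HDSession(start=87.3, duration=3.5)]
    doses = [DoseEvent(time=0.0, amount=1800.0, t_inf=1.0),
             DoseEvent(time=42.8, amount=600.0, t_inf=1.0)]
    return doses, sessions, settings


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
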