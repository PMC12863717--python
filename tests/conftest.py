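import numpy as np
import pytest

from ratelearn.events import PokeStream, ProtocolSpec, TrialSummary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_protocol():
    """A fast protocol for pipeline-level tests: 6 sessions of 10 trials."""
    return ProtocolSpec(group_id="t", T_mean=10.0, C=90.0,
                        trials_per_session=10, n_sessions=6)


def make_trial(i, n_cs, cs_dur=20.0, latency=2.0, in_mag=0.0,
               n_pre=0, pre_exp=10.0, pre_mag=0.0, onset=None, session=1):
    """Hand-built trial summary with sane defaults."""
    return TrialSummary(
        trial_index=i,
        cs_onset=onset if onset is not None else 100.0 * i,
        cs_duration=cs_dur,
        n_cs_pokes=n_cs,
        cs_first_poke_latency=latency if n_cs > 0 else None,
        cs_in_magazine_time=in_mag,
        n_pre_pokes=n_pre,
        pre_exposure=pre_exp,
        pre_in_magazine_time=pre_mag,
        session=session,
    )


@pytest.fixture
def make_trials():
    return make_trial
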