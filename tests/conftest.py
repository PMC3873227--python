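"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from rtcnet import circuit_sim as cs
from rtcnet import cortical_noise as cn
from rtcnet import hybrid_replay as hr
from rtcnet import stimuli as st

DURATION = 100_000.0  # ms, reference protocol length


@pytest.fixture(scope="session")
def lc_run():
    """100 s simulation of the 30-cell circuit at the LC optimum,
    uncorrelated bombardment, single 30 Hz gamma-3 afferent."""
    rng = np.random.default_rng(42)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=DURATION), rng)
    circ = cs.build_circuit("single", 30)
    res = cs.simulate(circ, [ret], noise=cn.lc_optimal(),
                      corr=cn.CorrelationSpec(), duration=DURATION, seed=1)
    return ret, res


@pytest.fixture(scope="session")
def hybrid_library():
    """Reduced pseudo-recording library: 3 cells x 20 trials x 20 s."""
    dur = 20_000.0
    rng = np.random.default_rng(7)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=dur), rng)
    sets = hr.generate_pseudo_recordings(
        ret, cn.lc_optimal(), n_cells=3, duration=dur, rng=rng)
    return ret, sets
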