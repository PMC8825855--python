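"""Shared fixtures: small deterministic synthetic sessions.

Sessions are generated once per test run (session scope) at sizes small
enough to keep the unit suite fast while still exercising every pathway.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from seqmem import GeneratorConfig, simulate_session
from seqmem.session import Session, SpikeTrain

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_session():
    """30 neurons, 12 sequences, no LFP: enough for the rate-based stages."""
    cfg = GeneratorConfig(n_neurons=30, n_sequences=12)
    session, gt = simulate_session(cfg, seed=101, include_lfp=False)
    return session, gt


@pytest.fixture(scope="session")
def theta_session():
    """With LFP, for phase / cycle / SWR pathways."""
    cfg = GeneratorConfig(n_neurons=30, n_sequences=12)
    cfg.swr.rate_hz = 0.05
    session, gt = simulate_session(cfg, seed=202, include_lfp=True)
    return session, gt


@pytest.fixture()
def toy_session():
    """Hand-built two-trial session with known spikes."""
    trials = pd.DataFrame(
        [
            dict(trial_id="t0", sequence_id="s0", position=1, odor="A", in_seq=True,
                 poke_in=10.0, poke_out=11.25, correct=True),
            dict(trial_id="t1", sequence_id="s0", position=2, odor="B", in_seq=True,
                 poke_in=15.0, poke_out=16.25, correct=True),
        ]
    )
    neurons = [
        SpikeTrain("n0", np.array([10.10, 10.30, 15.40])),
        SpikeTrain("n1", np.array([10.50, 15.50, 15.75])),
    ]
    return Session("toy", neurons, {"n0": "T00", "n1": "T00"}, [], trials)
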