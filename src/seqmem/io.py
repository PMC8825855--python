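"""Session directory I/O.

A session lives in a plain-text directory:

    spikes.csv        neuron_id, spike_time_s
    trials.csv        trial table columns
    lfp_<tetrode>.csv t_s, uv          (one file per tetrode)
    session.json      session_id, sample_rate_lfp, neuron -> tetrode map,
                      optional generator config + seed for synthetic sessions

Round trips are lossless at the declared precision (times to 1 us, LFP to
1e-3 uV).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    TRIAL_COLUMNS,
    LfpChannel,
    Session,
    SessionValidationError,
    SpikeTrain,
)

log = logging.getLogger(__name__)


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = [
        (n.neuron_id, t) for n in session.neurons for t in np.round(n.spike_times, 6)
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"]).to_csv(
        path / "spikes.csv", index=False
    )

    session.trials[TRIAL_COLUMNS].to_csv(path / "trials.csv", index=False)

    for ch in session.lfp:
        pd.DataFrame(
            {"t_s": np.round(ch.times, 6), "uv": np.round(ch.samples, 3)}
        ).to_csv(path / f"lfp_{ch.tetrode_id}.csv", index=False)

    meta = {
        "session_id": session.session_id,
        "sample_rate_lfp": session.sample_rate_lfp,
        "neuron_ids": session.neuron_ids,
        "tetrode_of_neuron": session.tetrode_of_neuron,
        **session.meta,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    return path


def load_session(path: str | Path) -> Session:
    """Load and validate a session directory; raises on missing files or
    invariant violations."""
    path = Path(path)
    meta_file = path / "session.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"missing session.json in {path}")
    meta = json.loads(meta_file.read_text())

    spikes_file = path / "spikes.csv"
    trials_file = path / "trials.csv"
    for f in (spikes_file, trials_file):
        if not f.exists():
            raise FileNotFoundError(f"missing {f.name} in {path}")

    spikes = pd.read_csv(spikes_file)
    neuron_ids = meta.get("neuron_ids") or sorted(spikes.neuron_id.unique())
    by_neuron = {nid: grp.spike_time_s.to_numpy() for nid, grp in spikes.groupby("neuron_id")}
    neurons = [SpikeTrain(nid, np.sort(by_neuron.get(nid, np.empty(0)))) for nid in neuron_ids]

    trials = pd.read_csv(trials_file)
    trials["in_seq"] = trials.in_seq.astype(bool)
    trials["correct"] = trials.correct.astype(bool)

    fs = float(meta.get("sample_rate_lfp", 1000.0))
    lfp = []
    for f in sorted(path.glob("lfp_*.csv")):
        tet = f.stem[len("lfp_"):]
        df = pd.read_csv(f)
        lfp.append(LfpChannel(tet, df.uv.to_numpy(), t0=float(df.t_s.iloc[0]), fs=fs))

    session = Session(
        session_id=meta.get("session_id", path.name),
        neurons=neurons,
        tetrode_of_neuron=dict(meta.get("tetrode_of_neuron", {})),
        lfp=lfp,
        trials=trials,
        sample_rate_lfp=fs,
        meta={k: v for k, v in meta.items()
              if k not in ("session_id", "sample_rate_lfp", "neuron_ids", "tetrode_of_neuron")},
    )
    session.validate()
    log.info("loaded session %s: %d neurons, %d trials, %d LFP channels",
             session.session_id, session.n_neurons, len(trials), len(lfp))
    return session


def validate_dir(path: str | Path) -> bool:
    """CLI helper: load and validate, returning True on success."""
    try:
        load_session(path)
    except (FileNotFoundError, SessionValidationError) as exc:
        log.error("validation failed: %s", exc)
        return False
    return True
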