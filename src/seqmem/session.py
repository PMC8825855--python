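"""Core data model for an ensemble recording session.

A session bundles per-neuron spike trains, per-tetrode LFP traces sampled on a
fixed grid, and a trial table describing the self-paced odor-sequence task:
each trial is one odor presentation (odor A-E at sequence position 1-5),
flagged in-sequence (InSeq) or out-of-sequence (OutSeq), with port-entry /
port-withdrawal times and the correctness of the animal's hold/withdraw
judgment.

All times are in seconds from session start; trial-relative times are computed
on demand by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ODORS = ("A", "B", "C", "D", "E")

#: canonical sequence position of each odor in the learned sequence ABCDE
ODOR_POSITION = {o: i + 1 for i, o in enumerate(ODORS)}

TRIAL_COLUMNS = [
    "trial_id",
    "sequence_id",
    "position",
    "odor",
    "in_seq",
    "poke_in",
    "poke_out",
    "correct",
]


class SessionValidationError(ValueError):
    """Raised when a session (or one of its components) violates an invariant."""


@dataclass
class SpikeTrain:
    neuron_id: str
    spike_times: np.ndarray  # seconds, nondecreasing

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self) -> None:
        t = self.spike_times
        if t.ndim != 1:
            raise SessionValidationError(f"neuron {self.neuron_id}: spike_times must be 1-D")
        if t.size and not np.all(np.isfinite(t)):
            raise SessionValidationError(f"neuron {self.neuron_id}: non-finite spike time")
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise SessionValidationError(
                f"neuron {self.neuron_id}: spike times must be nondecreasing and >= 0"
            )

    def __eq__(self, other: object) -> bool:
        # equality at the declared on-disk precision (times stored to 1 us)
        return (
            isinstance(other, SpikeTrain)
            and self.neuron_id == other.neuron_id
            and self.spike_times.shape == other.spike_times.shape
            and np.allclose(self.spike_times, other.spike_times, atol=2e-6)
        )


@dataclass
class LfpChannel:
    tetrode_id: str
    samples: np.ndarray  # microvolts, fixed sampling interval
    t0: float = 0.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.samples.size - 1) / self.fs

    def validate(self) -> None:
        if self.samples.ndim != 1:
            raise SessionValidationError(f"tetrode {self.tetrode_id}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise SessionValidationError(f"tetrode {self.tetrode_id}: non-finite LFP sample")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LfpChannel)
            and self.tetrode_id == other.tetrode_id
            and self.samples.shape == other.samples.shape
            and np.allclose(self.samples, other.samples, atol=1e-6)
            and abs(self.t0 - other.t0) < 1e-9
            and abs(self.fs - other.fs) < 1e-9
        )


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the trial-table invariants, naming the offending record."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise SessionValidationError(f"trial table missing columns: {sorted(missing)}")
    for _, row in trials.iterrows():
        if row.poke_out <= row.poke_in:
            raise SessionValidationError(
                f"trial {row.trial_id}: poke_out ({row.poke_out}) <= poke_in ({row.poke_in})"
            )
        if row.odor not in ODORS:
            raise SessionValidationError(f"trial {row.trial_id}: unknown odor {row.odor!r}")
        if not 1 <= int(row.position) <= 5:
            raise SessionValidationError(f"trial {row.trial_id}: position {row.position} out of range")
        if int(row.position) == 1 and (row.odor != "A" or not row.in_seq):
            raise SessionValidationError(
                f"trial {row.trial_id}: position 1 must be odor A presented InSeq"
            )
    for seq_id, grp in trials.groupby("sequence_id"):
        pk = grp.sort_values("position").poke_in.to_numpy()
        if np.any(np.diff(pk) <= 0):
            raise SessionValidationError(f"sequence {seq_id}: poke_in times not ascending")


@dataclass
class Session:
    session_id: str
    neurons: list[SpikeTrain]
    tetrode_of_neuron: dict[str, str]
    lfp: list[LfpChannel]
    trials: pd.DataFrame
    sample_rate_lfp: float = 1000.0
    meta: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> list[str]:
        return [n.neuron_id for n in self.neurons]

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def spikes_of(self, neuron_id: str) -> np.ndarray:
        for n in self.neurons:
            if n.neuron_id == neuron_id:
                return n.spike_times
        raise KeyError(neuron_id)

    def lfp_channel(self, tetrode_id: str) -> LfpChannel:
        for ch in self.lfp:
            if ch.tetrode_id == tetrode_id:
                return ch
        raise KeyError(tetrode_id)

    def validate(self) -> None:
        for n in self.neurons:
            n.validate()
            if n.neuron_id not in self.tetrode_of_neuron:
                raise SessionValidationError(f"neuron {n.neuron_id} has no tetrode assignment")
        for ch in self.lfp:
            ch.validate()
        validate_trials(self.trials)
        if self.lfp:
            t_lo = min(ch.t0 for ch in self.lfp)
            t_hi = max(ch.t_end for ch in self.lfp)
            for _, row in self.trials.iterrows():
                if row.poke_in < t_lo or row.poke_out > t_hi:
                    raise SessionValidationError(
                        f"trial {row.trial_id}: event times outside LFP span [{t_lo}, {t_hi}]"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        same_trials = self.trials.reset_index(drop=True)[TRIAL_COLUMNS].round(9).equals(
            other.trials.reset_index(drop=True)[TRIAL_COLUMNS].round(9)
        )
        return (
            self.session_id == other.session_id
            and self.neurons == other.neurons
            and self.tetrode_of_neuron == other.tetrode_of_neuron
            and sorted(c.tetrode_id for c in self.lfp) == sorted(c.tetrode_id for c in other.lfp)
            and all(self.lfp_channel(c.tetrode_id) == c for c in other.lfp)
            and same_trials
            and abs(self.sample_rate_lfp - other.sample_rate_lfp) < 1e-9
        )
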