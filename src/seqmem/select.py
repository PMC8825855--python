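"""Trial selection and filtering rules.

The analyses repeatedly need specific trial subsets: correct InSeq trials,
trials from intact sequences (every position InSeq, consecutively presented
and correctly identified), specific odors or positions, or trials with a
minimum hold. Selection never reorders trials; an empty result warns rather
than raises so exploratory runs keep going (decoders raise on empty input
themselves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class TrialSelection:
    """Declarative trial-filter criteria; ``None`` means "no constraint"."""

    in_seq: bool | None = None
    correct: bool | None = None
    odors: tuple[str, ...] | None = None
    positions: tuple[int, ...] | None = None
    min_hold: float | None = None
    consecutive_inseq: bool = False  # keep only intact all-InSeq-correct sequences
    exclude_positions: tuple[int, ...] | None = None


def intact_sequence_ids(trials: pd.DataFrame) -> set:
    """Sequences with all five positions presented InSeq and judged correctly."""
    ids = set()
    for seq_id, grp in trials.groupby("sequence_id"):
        if len(grp) == 5 and grp.in_seq.all() and grp.correct.all():
            ids.add(seq_id)
    return ids


def select_trials(trials: pd.DataFrame, criteria: TrialSelection | None = None) -> pd.DataFrame:
    if criteria is None:
        return trials.copy()
    mask = pd.Series(True, index=trials.index)
    if criteria.in_seq is not None:
        mask &= trials.in_seq == criteria.in_seq
    if criteria.correct is not None:
        mask &= trials.correct == criteria.correct
    if criteria.odors is not None:
        mask &= trials.odor.isin(criteria.odors)
    if criteria.positions is not None:
        mask &= trials.position.isin(criteria.positions)
    if criteria.exclude_positions is not None:
        mask &= ~trials.position.isin(criteria.exclude_positions)
    if criteria.min_hold is not None:
        mask &= (trials.poke_out - trials.poke_in) >= criteria.min_hold
    if criteria.consecutive_inseq:
        mask &= trials.sequence_id.isin(intact_sequence_ids(trials))
    out = trials[mask]
    log.info("select_trials: %d -> %d trials", len(trials), len(out))
    if out.empty:
        log.warning("select_trials: empty selection (criteria %s)", criteria)
    return out.copy()
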