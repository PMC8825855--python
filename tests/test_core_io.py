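"""Session model, I/O round trips, trial selection, spike counting, and the
permutation engine."""

import numpy as np
import pandas as pd
import pytest

from seqmem import (
    GeneratorConfig,
    SessionValidationError,
    TrialSelection,
    load_session,
    permutation_stream,
    select_trials,
    simulate_session,
    window_spike_counts,
    write_session,
)
from seqmem.windows import sliding_spike_counts


class TestSessionIO:
    def test_round_trip_identity(self, tmp_path, small_session):
        session, _ = small_session
        write_session(session, tmp_path / "sess")
        loaded = load_session(tmp_path / "sess")
        assert loaded == session

    def test_lfp_round_trip(self, tmp_path, theta_session):
        session, _ = theta_session
        write_session(session, tmp_path / "sess")
        loaded = load_session(tmp_path / "sess")
        assert len(loaded.lfp) == len(session.lfp)
        ch0, ch1 = session.lfp[0], loaded.lfp_channel(session.lfp[0].tetrode_id)
        assert np.allclose(ch0.samples, ch1.samples, atol=1e-2)

    def test_invalid_poke_order_rejected(self, tmp_path, toy_session):
        bad = toy_session
        bad.trials.loc[0, "poke_out"] = bad.trials.loc[0, "poke_in"] - 0.1
        write_session(bad, tmp_path / "bad")
        with pytest.raises(SessionValidationError, match="poke_out"):
            load_session(tmp_path / "bad")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_session(tmp_path / "nothing")

    def test_loaded_spike_count_matches_generator(self, tmp_path):
        cfg = GeneratorConfig(n_neurons=5, n_sequences=2)
        session, _ = simulate_session(cfg, seed=3, include_lfp=False)
        emitted = sum(len(n.spike_times) for n in session.neurons)
        write_session(session, tmp_path / "s")
        loaded = load_session(tmp_path / "s")
        assert sum(len(n.spike_times) for n in loaded.neurons) == emitted


class TestSelectTrials:
    def test_no_criteria_is_identity(self, small_session):
        session, _ = small_session
        out = select_trials(session.trials, None)
        pd.testing.assert_frame_equal(out, session.trials)

    def test_in_seq_filter_count(self, small_session):
        session, _ = small_session
        out = select_trials(session.trials, TrialSelection(in_seq=True))
        assert len(out) == int(session.trials.in_seq.sum())
        assert out.in_seq.all()

    def test_consecutive_inseq_keeps_only_intact_sequences(self, small_session):
        session, _ = small_session
        out = select_trials(session.trials, TrialSelection(consecutive_inseq=True))
        for _, grp in out.groupby("sequence_id"):
            assert len(grp) == 5
            assert grp.in_seq.all() and grp.correct.all()
        # every excluded sequence is genuinely broken
        kept = set(out.sequence_id)
        for sid, grp in session.trials.groupby("sequence_id"):
            intact = len(grp) == 5 and grp.in_seq.all() and grp.correct.all()
            assert (sid in kept) == intact

    def test_empty_selection_warns_not_raises(self, small_session, caplog):
        session, _ = small_session
        out = select_trials(session.trials, TrialSelection(odors=("E",), positions=(1,)))
        assert out.empty


class TestWindowSpikeCounts:
    def test_known_counts(self, toy_session):
        counts = window_spike_counts(toy_session, toy_session.trials,
                                     "poke_in", (0.0, 0.5), 0.25)
        # n0 spikes at +0.10, +0.30 on t0 -> [1, 1]
        assert counts[0, 0].tolist() == [1, 1]

    def test_total_conservation(self, small_session):
        session, _ = small_session
        counts = window_spike_counts(session, session.trials, "poke_in", (0.0, 1.2), 0.05)
        whole = window_spike_counts(session, session.trials, "poke_in", (0.0, 1.2), 1.2)
        assert np.array_equal(counts.sum(axis=2), whole[:, :, 0])

    def test_edge_spike_goes_to_later_bin(self):
        from seqmem.session import Session, SpikeTrain

        trials = pd.DataFrame([dict(trial_id="t", sequence_id="s", position=1,
                                    odor="A", in_seq=True, poke_in=0.0,
                                    poke_out=1.2, correct=True)])
        sess = Session("e", [SpikeTrain("n", np.array([0.25]))], {"n": "T"}, [], trials)
        counts = window_spike_counts(sess, trials, "poke_in", (0.0, 0.5), 0.25)
        assert counts[0, 0].tolist() == [0, 1]

    def test_bad_bin_raises(self, toy_session):
        with pytest.raises(ValueError, match="divide"):
            window_spike_counts(toy_session, toy_session.trials, "poke_in", (0.0, 0.5), 0.3)

    def test_sliding_counts_match_dense_at_equal_step(self, toy_session):
        dense = window_spike_counts(toy_session, toy_session.trials, "poke_in", (0, 1.0), 0.25)
        sliding, starts = sliding_spike_counts(toy_session, toy_session.trials,
                                               "poke_in", (0, 1.0), 0.25, 0.25)
        assert np.array_equal(dense, sliding)
        assert np.allclose(starts, [0, 0.25, 0.5, 0.75])


class TestPermutationEngine:
    def test_same_seed_identical_streams(self):
        a = [x.tolist() for x in permutation_stream(10, 5, seed=9)]
        b = [x.tolist() for x in permutation_stream(10, 5, seed=9)]
        assert a == b

    def test_label_shuffle_match_fraction(self):
        # balanced 4-class labels: a shuffle matches the original label in
        # 1/4 of positions in expectation
        labels = np.repeat(np.arange(4), 25)
        fracs = [
            (labels[perm] == labels).mean()
            for perm in permutation_stream(100, 1000, seed=1)
        ]
        assert abs(np.mean(fracs) - 0.25) < 0.01  # MC error ~ 0.0014

    def test_downsample_full_size_is_identity_set(self):
        (idx,) = list(permutation_stream(7, 1, seed=0, scheme="downsample", size=7))
        assert sorted(idx.tolist()) == list(range(7))

    def test_downsample_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            list(permutation_stream(5, 1, seed=0, scheme="downsample", size=6))
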