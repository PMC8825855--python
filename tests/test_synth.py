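"""Generator contracts: trial statistics, Poisson emission, phase coding,
LFP structure, and ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import circmean

from seqmem import GeneratorConfig, simulate_lfp, simulate_session, simulate_spikes, simulate_trials
from seqmem.synth import theta_phase_deg


class TestTrials:
    def test_no_outseq_when_probability_zero(self):
        cfg = GeneratorConfig(n_sequences=30, p_outseq=(0, 0, 0, 0))
        trials = simulate_trials(cfg, seed=1)
        assert trials.in_seq.all()

    def test_no_incorrect_gives_full_sequences(self):
        cfg = GeneratorConfig(n_sequences=30, p_incorrect=0.0, p_incorrect_outseq=0.0)
        trials = simulate_trials(cfg, seed=2)
        assert (trials.groupby("sequence_id").size() == 5).all()

    def test_outseq_fraction_matches_binomial(self):
        cfg = GeneratorConfig(n_sequences=500, p_outseq=(0.5, 0, 0, 0),
                              p_incorrect=0.0, p_incorrect_outseq=0.0)
        trials = simulate_trials(cfg, seed=3)
        pos2 = trials[trials.position == 2]
        frac = 1 - pos2.in_seq.mean()
        se = np.sqrt(0.25 / len(pos2))
        assert abs(frac - 0.5) < 4 * se

    def test_position1_always_odor_A_inseq(self):
        trials = simulate_trials(GeneratorConfig(n_sequences=40), seed=4)
        p1 = trials[trials.position == 1]
        assert (p1.odor == "A").all() and p1.in_seq.all()

    def test_incorrect_truncates_sequence(self):
        cfg = GeneratorConfig(n_sequences=200, p_incorrect=0.3)  # plus OutSeq errors
        trials = simulate_trials(cfg, seed=5)
        for _, grp in trials.groupby("sequence_id"):
            grp = grp.sort_values("position")
            wrong = grp[~grp.correct]
            if not wrong.empty:
                assert grp.position.max() == wrong.position.iloc[0]

    def test_inter_odor_interval_floor_and_median(self):
        cfg = GeneratorConfig(n_sequences=300, p_incorrect=0.0, p_incorrect_outseq=0.0)
        trials = simulate_trials(cfg, seed=6)
        gaps = []
        for _, grp in trials.groupby("sequence_id"):
            grp = grp.sort_values("position")
            gaps.extend(np.diff(grp.poke_in.to_numpy()))
        gaps = np.asarray(gaps)
        holds = 1.2
        assert (gaps >= holds + cfg.timing.ioi_floor - 1e-9).all()
        assert 4.0 < np.median(gaps) < 6.5  # ~5 s median odor-to-odor


class TestSpikes:
    def test_zero_peak_gives_baseline_poisson_rate(self):
        cfg = GeneratorConfig(n_neurons=8, n_sequences=10)
        cfg.time_cells.peak_range = (0.0, 1e-9)
        cfg.time_cells.baseline_range = (3.0, 3.0)
        cfg.theta.role_probs = {"none": 1.0}
        cfg.predictive.enabled = False
        cfg.outcome.frac = 0.0
        trials = simulate_trials(cfg, seed=7)
        spikes, gt = simulate_spikes(cfg, trials, seed=7)
        T = trials.poke_out.max() + 10.0
        rates = [len(s.spike_times) / T for s in spikes]
        # each neuron's count is Poisson(3*T): check the pooled rate
        total = sum(len(s.spike_times) for s in spikes)
        expect = 3.0 * T * len(spikes)
        assert abs(total - expect) < 4 * np.sqrt(expect)
        assert all(abs(r - 3.0) < 1.0 for r in rates)

    def test_lag_gain_one_equalizes_infield_rates(self):
        cfg = GeneratorConfig(n_neurons=12, n_sequences=25)
        cfg.time_cells.lag_gain = 1.0
        cfg.theta.role_probs = {"none": 1.0}
        cfg.predictive.enabled = False
        session, gt = simulate_session(cfg, seed=8, include_lfp=False)
        from seqmem.windows import window_spike_counts

        sel = session.trials[session.trials.in_seq & session.trials.correct]
        counts = window_spike_counts(session, sel, "poke_in", (0.0, 1.2), 1.2)[:, :, 0]
        groups = [counts[(sel.odor == od).to_numpy()].sum(axis=1) for od in "ABCD"]
        _, p = stats.f_oneway(*groups)
        assert p > 0.001  # no systematic odor dependence at rho = 1

    def test_present_neuron_phase_locking(self):
        cfg = GeneratorConfig(n_neurons=6, n_sequences=20)
        cfg.theta.role_probs = {"present": 1.0}
        cfg.theta.kappa = 8.0
        cfg.time_cells.baseline_range = (0.01, 0.02)
        session, gt = simulate_session(cfg, seed=9, include_lfp=False)
        trials = session.trials
        phases = []
        for neuron, pref in zip(session.neurons, gt.neurons.pref_odor):
            sel = trials[(trials.odor == pref) & trials.in_seq & trials.correct]
            for _, tr in sel.iterrows():
                st = neuron.spike_times
                m = (st >= tr.poke_in) & (st < tr.poke_out)
                phases.append(theta_phase_deg(st[m], cfg.theta.freq))
        phases = np.concatenate(phases)
        mu = circmean(phases, high=360)
        assert phases.size > 100
        assert abs((mu - 180 + 180) % 360 - 180) < 15

    def test_ground_truth_never_empty(self, small_session):
        _, gt = small_session
        assert len(gt.neurons) == 30
        assert {"pref_odor", "t0", "sigma", "peak", "baseline", "role"} <= set(gt.neurons.columns)


class TestLfp:
    def test_phase_track_closed_form(self):
        # cos(2*pi*6t): peak at t=0 -> phase 0; trough at t=1/12 -> 180
        assert theta_phase_deg(np.array([0.0]), 6.0)[0] == pytest.approx(0.0)
        assert theta_phase_deg(np.array([1 / 12]), 6.0)[0] == pytest.approx(180.0, abs=1e-6)

    def test_zero_swr_rate_gives_empty_events(self):
        cfg = GeneratorConfig(n_tetrodes=2)
        _, events = simulate_lfp(cfg, duration=50.0, seed=10)
        assert events == []

    def test_injected_ripple_raises_band_power(self):
        from seqmem.swr import band_envelope_z

        cfg = GeneratorConfig(n_tetrodes=2)
        cfg.swr.rate_hz = 0.1
        chans, events = simulate_lfp(cfg, duration=120.0, seed=11)
        assert events
        z = band_envelope_z(chans[0], (150.0, 250.0))
        for s, e in events:
            i0, i1 = int(s * 1000), int(e * 1000)
            assert z[i0:i1].max() > 3.0

    def test_ground_truth_swr_recorded_in_session(self):
        cfg = GeneratorConfig(n_neurons=5, n_sequences=2, n_tetrodes=2)
        cfg.swr.rate_hz = 0.2
        session, gt = simulate_session(cfg, seed=12, include_lfp=True)
        assert len(gt.swr_events) >= 1

    def test_round_trip_ground_truth_json(self, tmp_path, small_session):
        from seqmem import GroundTruth

        _, gt = small_session
        gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.theta_freq == gt.theta_freq
        assert list(back.neurons.neuron_id) == list(gt.neurons.neuron_id)
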