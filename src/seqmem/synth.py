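"""Synthetic session generator.

Emulates the statistical structure of a CA1 ensemble recording during the
odor-sequence task so that every downstream analysis can be verified by
parameter recovery, without any real recording:

* self-paced trials: sequences of five odor presentations (ABCDE), position 1
  always odor A InSeq, OutSeq substitutions at positions 2-5, 1.2 s InSeq
  holds, shorter OutSeq withdrawals, log-normal inter-odor intervals with a
  ~5 s median and a 0.8 s floor, and early sequence termination after an
  incorrect judgment;
* inhomogeneous-Poisson "time cells" with odor-specific Gaussian firing
  fields whose gain decays as rho**|lag| with the sequence lag between the
  presented and preferred odor;
* theta-band LFP (sinusoidal carrier + Gaussian noise) and theta-coding
  neurons whose firing is gated by a von Mises phase factor: each such neuron
  represents one odor and fires for that odor in its role as the past,
  present, or future stimulus at phase 60, 180, or 300 degrees respectively
  (the configured role sets which lobe dominates), with an optional linear
  phase-precession shift per theta cycle;
* an optional within-trial reactivation schedule (upcoming odors replayed in
  order), pre-entry predictive coding of the expected odor (degraded on
  incorrect trials), outcome-modulated units, and injectable sharp-wave
  ripple transients.

All ground-truth parameters are recorded alongside the session; analysis
modules never read them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0

from .permute import derive_seed
from .session import ODOR_POSITION, ODORS, LfpChannel, Session, SpikeTrain

DT = 1e-3  # spike-rate evaluation grid, s


@dataclass
class TimingConfig:
    inseq_hold: float = 1.2        # s, hold until the tone on InSeq judgments
    hold_jitter: tuple[float, float] = (0.02, 0.08)
    outseq_hold_mean: float = 0.751
    outseq_hold_sd: float = 0.229
    outseq_hold_range: tuple[float, float] = (0.35, 1.15)
    ioi_median: float = 5.0        # poke_in-to-poke_in, s
    ioi_sigma: float = 0.35        # log-normal shape
    ioi_floor: float = 0.8         # s, software-enforced minimum gap
    interseq_gap: float = 12.0
    session_start: float = 5.0


@dataclass
class TimeCellConfig:
    t0_range: tuple[float, float] = (0.0, 1.2)
    sigma_range: tuple[float, float] = (0.08, 0.25)
    peak_range: tuple[float, float] = (8.0, 20.0)
    baseline_range: tuple[float, float] = (0.5, 2.0)
    lag_gain: float = 0.6  # rho: in-field rate multiplier rho**|lag|


@dataclass
class ThetaConfig:
    freq: float = 6.0
    amplitude_uv: float = 100.0
    noise_sd_uv: float = 30.0
    kappa: float = 4.0
    lobe_phases: tuple[float, float, float] = (60.0, 180.0, 300.0)  # past, present, future
    dominant_lobe_gain: float = 1.0
    other_lobe_gain: float = 0.6
    role_probs: dict = field(
        default_factory=lambda: {"past": 0.2, "present": 0.2, "future": 0.2, "none": 0.4}
    )
    precession_slope: float = 0.0  # deg per theta cycle (negative = precession)
    present_decay: float = 0.35    # within-trial decay of the present lobe
    future_base: float = 0.4       # future lobe ramps future_base -> 1 over the hold
    past_decay: float = 0.4
    pre_entry_span: float = 0.45   # s of pre-entry phase coding
    pre_present_gain: float = 0.8  # pre-entry lobe envelopes
    pre_future_gain: float = 0.8


@dataclass
class PredictiveConfig:
    enabled: bool = True
    pretrial_gain: float = 0.8     # rate-code pulse for the expected odor
    pretrial_window: float = 0.4   # s before port entry
    incorrect_degradation: float = 0.2  # gain multiplier on incorrect trials


@dataclass
class ReactivationConfig:
    """Injectable within-trial replay of the upcoming odors: the current,
    next, and next-next odors' coding neurons receive Gaussian gain pulses at
    successively later in-trial times. Off by default."""

    enabled: bool = False
    gain: float = 1.2
    width: float = 0.2
    t_first: float = 0.3   # peak time of the current odor's reactivation pulse
    spacing: float = 0.4   # s between successive odors' pulses


@dataclass
class OutcomeConfig:
    frac: float = 0.15
    rate_hz: float = 8.0   # extra rate after withdrawal on incorrect trials
    duration: float = 0.5


@dataclass
class SwrConfig:
    rate_hz: float = 0.0          # injection rate over the whole session
    ripple_freq: float = 200.0
    amplitude_sd: float = 6.0     # in SD units of the background noise
    duration: float = 0.08
    sharpwave_duration: float = 0.1


@dataclass
class GeneratorConfig:
    n_neurons: int = 60
    n_tetrodes: int = 4
    n_sequences: int = 40
    p_outseq: tuple[float, float, float, float] = (0.125, 0.125, 0.125, 0.125)
    p_incorrect: float = 0.05          # InSeq error rate (rare anticipation errors)
    p_incorrect_outseq: float = 0.25   # OutSeq judgments are the hard ones
    timing: TimingConfig = field(default_factory=TimingConfig)
    time_cells: TimeCellConfig = field(default_factory=TimeCellConfig)
    theta: ThetaConfig = field(default_factory=ThetaConfig)
    predictive: PredictiveConfig = field(default_factory=PredictiveConfig)
    reactivation: ReactivationConfig = field(default_factory=ReactivationConfig)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    swr: SwrConfig = field(default_factory=SwrConfig)

    def validate(self) -> None:
        if not 0 < self.time_cells.lag_gain <= 1:
            raise ValueError("lag_gain must be in (0, 1]")
        probs = (*self.p_outseq, self.p_incorrect, self.p_incorrect_outseq)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.timing.inseq_hold <= 0:
            raise ValueError("holds must be positive")
        if min(self.time_cells.peak_range + self.time_cells.baseline_range) < 0:
            raise ValueError("rates must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in [
            ("timing", TimingConfig), ("time_cells", TimeCellConfig),
            ("theta", ThetaConfig), ("predictive", PredictiveConfig),
            ("reactivation", ReactivationConfig), ("outcome", OutcomeConfig),
            ("swr", SwrConfig),
        ]:
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for k, v in sub_d.items():
                    if isinstance(v, list):
                        sub_d[k] = tuple(v)
                d[key] = sub(**sub_d)
        if "p_outseq" in d and isinstance(d["p_outseq"], list):
            d["p_outseq"] = tuple(d["p_outseq"])
        return cls(**d)


@dataclass
class GroundTruth:
    neurons: pd.DataFrame        # per-neuron tuning parameters
    trial_latents: pd.DataFrame  # per-trial relational odors
    swr_events: list             # (start, end) of injected transients
    theta_freq: float
    config: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "neurons": self.neurons.to_dict(orient="list"),
            "trial_latents": self.trial_latents.to_dict(orient="list"),
            "swr_events": [[float(a), float(b)] for a, b in self.swr_events],
            "theta_freq": self.theta_freq,
            "config": self.config,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            neurons=pd.DataFrame(d["neurons"]),
            trial_latents=pd.DataFrame(d["trial_latents"]),
            swr_events=[tuple(ev) for ev in d["swr_events"]],
            theta_freq=d["theta_freq"],
            config=d["config"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# trials


def simulate_trials(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Draw the self-paced trial table."""
    config.validate()
    rng = np.random.default_rng(derive_seed(seed, 1))
    tm = config.timing
    rows = []
    t = tm.session_start
    trial_idx = 0
    for s in range(config.n_sequences):
        for pos in range(1, 6):
            expected = ODORS[pos - 1]
            if pos == 1:
                odor = "A"
            elif rng.random() < config.p_outseq[pos - 2]:
                others = [o for o in ODORS if o != expected]
                odor = others[rng.integers(len(others))]
            else:
                odor = expected
            in_seq = odor == expected
            p_err = config.p_incorrect if in_seq else config.p_incorrect_outseq
            correct = bool(rng.random() >= p_err)
            judged_inseq = (in_seq and correct) or (not in_seq and not correct)
            if judged_inseq:
                hold = tm.inseq_hold + rng.uniform(*tm.hold_jitter)
            elif in_seq:  # anticipation error: withdrew just before the tone
                hold = rng.uniform(1.05, 1.19)
            else:
                lo, hi = tm.outseq_hold_range
                hold = float(np.clip(rng.normal(tm.outseq_hold_mean, tm.outseq_hold_sd), lo, hi))
            rows.append(
                dict(trial_id=f"t{trial_idx:04d}", sequence_id=f"s{s:03d}", position=pos,
                     odor=odor, in_seq=in_seq, poke_in=round(t, 6),
                     poke_out=round(t + hold, 6), correct=correct)
            )
            trial_idx += 1
            if not correct:
                t = t + hold
                break
            gap = max(tm.ioi_floor, rng.lognormal(np.log(tm.ioi_median), tm.ioi_sigma) - hold)
            t = t + hold + gap
        t += tm.interseq_gap
    return pd.DataFrame(rows)


def _trial_latents(trials: pd.DataFrame) -> pd.DataFrame:
    """Relational odors per trial.

    Post-entry frame: past = previously presented odor in the sequence,
    present = presented odor, future = expected odor at the next position.
    Pre-entry frame (before the nosepoke): everything shifts back one step and
    the upcoming (expected) odor takes the future slot.
    """
    recs = []
    for _, grp in trials.groupby("sequence_id", sort=False):
        grp = grp.sort_values("position")
        odors = list(grp.odor)
        for i, (_, row) in enumerate(grp.iterrows()):
            pos = int(row.position)
            expected = ODORS[pos - 1]
            recs.append(
                dict(
                    trial_id=row.trial_id,
                    expected=expected,
                    past=odors[i - 1] if i > 0 else None,
                    present=row.odor,
                    future=ODORS[pos] if pos < 5 else None,
                    pre_past=odors[i - 2] if i > 1 else None,
                    pre_present=odors[i - 1] if i > 0 else None,
                    pre_future=expected,
                )
            )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# neurons


def _draw_neurons(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(derive_seed(seed, 2))
    tc = config.time_cells
    roles, probs = zip(*config.theta.role_probs.items())
    n = config.n_neurons
    df = pd.DataFrame(
        {
            "neuron_id": [f"n{i:03d}" for i in range(n)],
            "tetrode": [f"T{i % config.n_tetrodes:02d}" for i in range(n)],
            "pref_odor": rng.choice(list(ODORS), size=n),
            "t0": rng.uniform(*tc.t0_range, size=n),
            "sigma": rng.uniform(*tc.sigma_range, size=n),
            "peak": rng.uniform(*tc.peak_range, size=n),
            "baseline": rng.uniform(*tc.baseline_range, size=n),
            "role": rng.choice(list(roles), size=n, p=np.asarray(probs) / np.sum(probs)),
            "phase_pref": np.zeros(n),
            "outcome_modulated": rng.random(n) < config.outcome.frac,
        }
    )
    lobe = dict(zip(("past", "present", "future"), config.theta.lobe_phases))
    df["phase_pref"] = [lobe.get(r, np.nan) for r in df.role]
    return df


def _von_mises(phase_deg: np.ndarray, mu_deg: np.ndarray | float, kappa: float) -> np.ndarray:
    """Multiplicative phase factor normalized to unit mean over uniform phase."""
    return np.exp(kappa * np.cos(np.radians(phase_deg - mu_deg))) / i0(kappa)


def theta_phase_deg(t: np.ndarray, freq: float) -> np.ndarray:
    """Ground-truth phase of the sinusoidal theta carrier (0 deg = peak)."""
    return np.mod(360.0 * freq * np.asarray(t), 360.0)


def _cycle_index(t_abs: np.ndarray, poke_in: float, freq: float) -> np.ndarray:
    """Theta cycle index relative to port entry: cycle 1 is the first full
    cycle starting at or after poke_in + 100 ms; earlier cycles count down
    through 0, -1, ..."""
    t_c1 = np.ceil((poke_in + 0.1) * freq) / freq
    return np.floor((t_abs - t_c1) * freq).astype(int) + 1


def simulate_spikes(
    config: GeneratorConfig, trials: pd.DataFrame, seed: int
) -> tuple[list[SpikeTrain], GroundTruth]:
    """Inhomogeneous-Poisson spike trains for all neurons plus ground truth."""
    config.validate()
    rng = np.random.default_rng(derive_seed(seed, 3))
    neurons = _draw_neurons(config, seed)
    latents = _trial_latents(trials).set_index("trial_id")
    th, pred, react = config.theta, config.predictive, config.reactivation

    t_session_end = float(trials.poke_out.max()) + 10.0
    pre_span, post_span = 0.8, 0.7
    poke_in = trials.poke_in.to_numpy()
    poke_out = trials.poke_out.to_numpy()
    hold = poke_out - poke_in
    n_trials = len(trials)
    L = int(np.ceil((pre_span + hold.max() + post_span) / DT))
    rel_t = -pre_span + DT * (np.arange(L) + 0.5)            # (L,)
    grid = poke_in[:, None] + rel_t[None, :]  # absolute times, (n_trials, L)
    in_trial = (rel_t[None, :] >= 0) & (rel_t[None, :] <= hold[:, None])
    pre_win = (rel_t[None, :] >= -pred.pretrial_window) & (rel_t[None, :] < 0)
    pre_theta = (rel_t[None, :] >= -th.pre_entry_span) & (rel_t[None, :] < 0)
    post_out = (rel_t[None, :] > hold[:, None]) & (
        rel_t[None, :] <= hold[:, None] + config.outcome.duration
    )

    lat = latents.loc[trials.trial_id]
    presented = trials.odor.to_numpy()
    expected = lat.expected.to_numpy()
    incorrect = ~trials.correct.to_numpy()
    degrade = np.where(incorrect, pred.incorrect_degradation, 1.0)

    phase = theta_phase_deg(grid, th.freq)
    cyc = np.stack([_cycle_index(grid[j], poke_in[j], th.freq) for j in range(n_trials)])
    prec_shift = th.precession_slope * (cyc - 1)

    # relational lobe envelopes (post-entry / pre-entry frames)
    frac = np.clip(rel_t[None, :] / config.timing.inseq_hold, 0.0, 1.0)
    env_post = {
        "past": (1.0 - th.past_decay * frac) * in_trial,
        "present": (1.0 - th.present_decay * frac) * in_trial,
        "future": (th.future_base + (1 - th.future_base) * frac) * in_trial,
    }
    env_pre = {
        "past": 0.5 * pre_theta,
        "present": th.pre_present_gain * pre_theta,
        "future": th.pre_future_gain * pre_theta,
    }
    lobe_odor_post = {
        "past": lat.past.to_numpy(), "present": lat.present.to_numpy(),
        "future": lat.future.to_numpy(),
    }
    lobe_odor_pre = {
        "past": lat.pre_past.to_numpy(), "present": lat.pre_present.to_numpy(),
        "future": lat.pre_future.to_numpy(),
    }
    lobe_mu = dict(zip(("past", "present", "future"), th.lobe_phases))
    pos_arr = trials.position.to_numpy()

    spike_trains: list[SpikeTrain] = []
    rho = config.time_cells.lag_gain
    for _, nr in neurons.iterrows():
        rate = np.zeros((n_trials, L))
        pref = nr.pref_odor
        if nr.role == "none":
            lag = np.abs(
                np.vectorize(ODOR_POSITION.get)(presented) - ODOR_POSITION[pref]
            )
            gain = nr.peak * rho**lag
            rate += gain[:, None] * np.exp(
                -((rel_t[None, :] - nr.t0) ** 2) / (2 * nr.sigma**2)
            ) * in_trial
            if react.enabled:
                for k in range(3):
                    sched = np.array(
                        [ODORS[p + k - 1] if p + k <= 5 else "" for p in pos_arr]
                    )
                    match = (sched == pref).astype(float)
                    if match.any():
                        t_k = react.t_first + k * react.spacing
                        rate += (
                            nr.peak * react.gain * match[:, None]
                            * np.exp(-((rel_t[None, :] - t_k) ** 2) / (2 * react.width**2))
                            * in_trial
                        )
            if pred.enabled:
                match = (expected == pref).astype(float) * degrade
                rate += nr.peak * pred.pretrial_gain * match[:, None] * pre_win
        else:
            a_role = {
                r: (th.dominant_lobe_gain if r == nr.role else th.other_lobe_gain)
                for r in ("past", "present", "future")
            }
            for lobe in ("past", "present", "future"):
                vm = _von_mises(phase, lobe_mu[lobe] + prec_shift, th.kappa)
                # only the predictive (future) component degrades on
                # incorrect trials; the representation of experienced odors
                # is intact
                deg_lobe = degrade if lobe == "future" else np.ones(n_trials)
                match_post = (lobe_odor_post[lobe] == pref).astype(float) * deg_lobe
                contrib = a_role[lobe] * match_post[:, None] * env_post[lobe]
                if pred.enabled:
                    match_pre = (lobe_odor_pre[lobe] == pref).astype(float) * deg_lobe
                    contrib = contrib + a_role[lobe] * match_pre[:, None] * env_pre[lobe]
                rate += nr.peak * contrib * vm
        if nr.outcome_modulated:
            rate += config.outcome.rate_hz * incorrect[:, None] * post_out

        # draw extra (above-baseline) spikes on the trial grids
        counts = rng.poisson(rate * DT)
        jidx, kidx = np.nonzero(counts)
        reps = counts[jidx, kidx]
        times = np.repeat(grid[jidx, kidx], reps) + (rng.random(reps.sum()) - 0.5) * DT
        # homogeneous baseline over the whole session
        n_base = rng.poisson(nr.baseline * t_session_end)
        base_times = rng.uniform(0, t_session_end, n_base)
        all_times = np.sort(np.concatenate([times, base_times]))
        all_times = all_times[all_times >= 0]
        spike_trains.append(SpikeTrain(nr.neuron_id, all_times))

    gt = GroundTruth(
        neurons=neurons,
        trial_latents=latents.reset_index(),
        swr_events=[],
        theta_freq=th.freq,
        config=config.to_dict(),
        seed=seed,
    )
    return spike_trains, gt


# ---------------------------------------------------------------------------
# LFP


def simulate_lfp(
    config: GeneratorConfig, duration: float, seed: int
) -> tuple[list[LfpChannel], list[tuple[float, float]]]:
    """Theta-band LFP per tetrode plus injected SWR transients.

    Returns (channels, injected event intervals). The sinusoidal theta
    carrier is shared across tetrodes (its true phase is
    ``theta_phase_deg``); noise is independent per tetrode. Ripples go on
    tetrode 0, co-timed sharp waves on tetrode 1.
    """
    rng = np.random.default_rng(derive_seed(seed, 4))
    th, swr = config.theta, config.swr
    fs = 1000.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    carrier = th.amplitude_uv * np.cos(2 * np.pi * th.freq * t)
    channels = []
    for k in range(config.n_tetrodes):
        noise = rng.normal(0.0, th.noise_sd_uv, n) if th.noise_sd_uv > 0 else 0.0
        channels.append(LfpChannel(f"T{k:02d}", carrier + noise, t0=0.0, fs=fs))

    events: list[tuple[float, float]] = []
    if swr.rate_hz > 0 and config.n_tetrodes >= 2:
        from scipy.signal import butter, hilbert, sosfiltfilt

        def env_stats(x: np.ndarray, band) -> tuple[float, float]:
            if np.isscalar(band):
                sos = butter(3, band, btype="highpass", fs=fs, output="sos")
            else:
                sos = butter(3, band, btype="bandpass", fs=fs, output="sos")
            env = np.abs(hilbert(sosfiltfilt(sos, x)))
            return float(env.mean()), float(env.std())

        # amplitudes expressed in SD units of each channel's background
        # envelope, the scale the detector thresholds against
        rip_mu, rip_sd = env_stats(channels[0].samples, (150.0, 250.0))
        sw_mu, sw_sd = env_stats(channels[1].samples, 4.0)
        rip_amp = rip_mu + swr.amplitude_sd * rip_sd
        # the theta carrier can interfere destructively with the deflection,
        # so its amplitude is added on top of the nominal SD level
        sw_amp = sw_mu + swr.amplitude_sd * sw_sd + th.amplitude_uv
        n_ev = rng.poisson(swr.rate_hz * duration)
        starts = np.sort(rng.uniform(1.0, duration - 1.0, n_ev))
        last_end = -np.inf
        for s in starts:
            if s < last_end + 0.2:  # keep injected events separable
                continue
            i0_, i1 = int(s * fs), int((s + swr.duration) * fs)
            win = np.hanning(i1 - i0_)
            channels[0].samples[i0_:i1] += rip_amp * win * np.sin(
                2 * np.pi * swr.ripple_freq * t[i0_:i1]
            )
            j1 = int((s + swr.sharpwave_duration) * fs)
            channels[1].samples[i0_:j1] += -sw_amp * np.hanning(j1 - i0_)
            events.append((s, max(s + swr.duration, s + swr.sharpwave_duration)))
            last_end = events[-1][1]
    return channels, events


# ---------------------------------------------------------------------------
# full session


def simulate_session(
    config: GeneratorConfig, seed: int, include_lfp: bool = True
) -> tuple[Session, GroundTruth]:
    trials = simulate_trials(config, seed)
    spikes, gt = simulate_spikes(config, trials, seed)
    duration = float(trials.poke_out.max()) + 10.0
    if include_lfp:
        lfp, events = simulate_lfp(config, duration, seed)
        gt.swr_events = events
    else:
        lfp = []
    tet_map = dict(zip(gt.neurons.neuron_id, gt.neurons.tetrode))
    session = Session(
        session_id=f"synthetic-{seed}",
        neurons=spikes,
        tetrode_of_neuron=tet_map,
        lfp=lfp,
        trials=trials,
        sample_rate_lfp=1000.0,
        meta={
            "synthetic": True,
            "generator_seed": seed,
            "theta_tetrode": "T00",
            "ripple_tetrode": "T00",
            "sharpwave_tetrode": "T01",
            "generator_config": config.to_dict(),
        },
    )
    return session, gt
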