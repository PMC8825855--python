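"""Theta-cycle decoding of past, present, and future stimuli, and phase
precession.

Phase convention: the LFP is band-passed 4-7 Hz (Butterworth, zero-phase)
and Hilbert-transformed; phase 0 deg is the filtered-trace peak, 180 deg the
trough. Phase partition within a cycle: descending [0, 120), trough
[120, 240), ascending [240, 360). Cycles run peak-to-peak (ascending
crossings of 0 deg), so the trough sits mid-cycle; cycle 1 is the first full
cycle starting at or after port entry + 100 ms, the cycle immediately before
it has index -1 (pre-1), and so on.

The decoding protocol follows the trough-training rule: a LASSO multinomial
logistic regression is fit on each neuron's firing rate during the trough of
cycle 1 (correct InSeq trials), then applied across phases, cycles, and
trial types through a 120-deg window sliding in 10-deg steps. Decoded odor
probabilities are mapped to past / present / future according to each
trial's position in the learned sequence ABCDE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from .permute import derive_seed
from .session import ODORS, LfpChannel, Session
from .stats import circ_lin_corr, linear_trend_test, quadratic_trend_test

log = logging.getLogger(__name__)

N_BINS = 36           # 10-degree bins
WINDOW_DEG = 120.0
PHASE_WINDOWS = {"descending": (0.0, 120.0), "trough": (120.0, 240.0),
                 "ascending": (240.0, 360.0)}
ODOR_SET = ("A", "B", "C", "D")
BIN_CENTERS = 5.0 + 10.0 * np.arange(N_BINS)


@dataclass
class PhaseSeries:
    phase_deg: np.ndarray   # [0, 360), 0 = peak of the filtered trace
    amplitude: np.ndarray   # analytic-signal envelope
    fs: float
    t0: float
    band: tuple[float, float]

    def at(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round((np.asarray(t) - self.t0) * self.fs).astype(int),
                      0, self.phase_deg.size - 1)
        return self.phase_deg[idx]


def extract_phase(
    channel: LfpChannel,
    band: tuple[float, float] = (4.0, 7.0),
    order: int = 2,
    expected_fs: float = 1000.0,
) -> PhaseSeries:
    """Instantaneous theta phase and amplitude of one LFP channel."""
    if abs(channel.fs - expected_fs) > 1e-6:
        raise ValueError(f"sampling rate {channel.fs} != declared {expected_fs}")
    if channel.samples.size < 2 * channel.fs:
        raise ValueError("need at least 2 s of signal for stable filtering")
    sos = signal.butter(order, band, btype="bandpass", fs=channel.fs, output="sos")
    filt = signal.sosfiltfilt(sos, channel.samples)
    analytic = signal.hilbert(filt)
    phase = np.mod(np.degrees(np.angle(analytic)), 360.0)
    return PhaseSeries(phase, np.abs(analytic), channel.fs, channel.t0, band)


def select_theta_channel(session: Session, band: tuple[float, float] = (4.0, 7.0)) -> LfpChannel:
    """The channel with maximal theta-band power (synthetic sessions also
    mark one in their metadata)."""
    tet = session.meta.get("theta_tetrode")
    if tet is not None:
        return session.lfp_channel(tet)
    best, best_p = None, -np.inf
    for ch in session.lfp:
        fr, pxx = signal.welch(ch.samples, fs=ch.fs, nperseg=4096)
        p = pxx[(fr >= band[0]) & (fr <= band[1])].sum()
        if p > best_p:
            best, best_p = ch, p
    if best is None:
        raise ValueError("session has no LFP channels")
    return best


# ---------------------------------------------------------------------------
# cycle segmentation


@dataclass
class ThetaCycleSet:
    cycles: pd.DataFrame          # trial_id, cycle, t_start, t_end, amplitude
    phase: PhaseSeries
    excluded_trials: list[str]    # weak-amplitude cycle-1 exclusions

    def rows(self, cycles: tuple[int, ...] | None = None) -> pd.DataFrame:
        df = self.cycles
        return df if cycles is None else df[df.cycle.isin(cycles)]


def segment_cycles(
    phase: PhaseSeries,
    trials: pd.DataFrame,
    amplitude_exclude_pct: float = 20.0,
    max_pre: int = 3,
    max_post: int = 6,
) -> ThetaCycleSet:
    """Segment theta cycles around each trial and index them relative to
    port entry.

    Trials whose cycle-1 amplitude falls in the weakest
    ``amplitude_exclude_pct`` percentile are excluded; trials with no
    complete cycle between port entry + 100 ms and port withdrawal are
    dropped and logged.
    """
    ph = phase.phase_deg
    wraps = np.flatnonzero(np.diff(ph) < -180.0)  # ascending 0-deg crossings
    starts = (wraps + 1) / phase.fs + phase.t0
    rows = []
    dropped = []
    for _, tr in trials.iterrows():
        k1 = np.searchsorted(starts, tr.poke_in + 0.1)
        if k1 + 1 >= starts.size or starts[k1 + 1] > tr.poke_out + 0.05:
            dropped.append(tr.trial_id)
            continue
        for k in range(max(0, k1 - max_pre), min(starts.size - 1, k1 + max_post)):
            idx = k - k1 + 1 if k >= k1 else k - k1
            t0_, t1 = starts[k], starts[k + 1]
            if idx > 1 and t1 > tr.poke_out + 0.05:
                continue
            i0, i1 = int((t0_ - phase.t0) * phase.fs), int((t1 - phase.t0) * phase.fs)
            rows.append(dict(trial_id=tr.trial_id, cycle=int(idx), t_start=t0_,
                             t_end=t1, amplitude=float(phase.amplitude[i0:i1].mean())))
    if dropped:
        log.info("segment_cycles: dropped %d trials with no complete cycle", len(dropped))
    df = pd.DataFrame(rows)
    excluded: list[str] = []
    if amplitude_exclude_pct > 0 and not df.empty:
        c1 = df[df.cycle == 1]
        thr = np.percentile(c1.amplitude, amplitude_exclude_pct)
        excluded = list(c1[c1.amplitude < thr].trial_id)
        df = df[~df.trial_id.isin(excluded)]
        log.info("segment_cycles: excluded %d weak-theta trials", len(excluded))
    return ThetaCycleSet(df.reset_index(drop=True), phase, excluded)


# ---------------------------------------------------------------------------
# phase-windowed firing rates


def _cycle_histograms(
    session: Session, cycleset: ThetaCycleSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per cycle row: 10-deg histograms of sample time (occupancy) and of
    each neuron's spikes. Returns (occupancy (n_rows, 36) seconds,
    spike counts (n_rows, n_neurons, 36))."""
    ph = cycleset.phase
    df = cycleset.cycles
    n_rows = len(df)
    occ = np.zeros((n_rows, N_BINS))
    spk = np.zeros((n_rows, session.n_neurons, N_BINS))
    spike_arrays = [n.spike_times for n in session.neurons]
    for r, row in enumerate(df.itertuples()):
        i0 = int((row.t_start - ph.t0) * ph.fs)
        i1 = int((row.t_end - ph.t0) * ph.fs)
        bins = np.minimum((ph.phase_deg[i0:i1] / 10.0).astype(int), N_BINS - 1)
        occ[r] = np.bincount(bins, minlength=N_BINS) / ph.fs
        for j, st in enumerate(spike_arrays):
            a = np.searchsorted(st, row.t_start, side="left")
            b = np.searchsorted(st, row.t_end, side="left")
            if b > a:
                sb = np.minimum((ph.at(st[a:b]) / 10.0).astype(int), N_BINS - 1)
                spk[r, j] = np.bincount(sb, minlength=N_BINS)
    return occ, spk


def _window_sum(x: np.ndarray, half_bins: int = 6) -> np.ndarray:
    """Circular sum over a window of 2*half_bins bins centered on each bin
    label (the 120-deg sliding window)."""
    idx = (np.arange(N_BINS)[:, None] + np.arange(-half_bins, half_bins)[None, :]) % N_BINS
    return x[..., idx].sum(axis=-1)


def sliding_phase_rates(
    session: Session, cycleset: ThetaCycleSet
) -> np.ndarray:
    """Firing rate of each neuron in the 120-deg window centered on each
    10-deg bin, per cycle row: (n_rows, n_neurons, 36). NaN where the window
    holds no samples."""
    occ, spk = _cycle_histograms(session, cycleset)
    dur = _window_sum(occ)                      # (n_rows, 36)
    cnt = _window_sum(spk)                      # (n_rows, n_neurons, 36)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = cnt / dur[:, None, :]
    return rates


def trough_rates(session: Session, cycleset: ThetaCycleSet, cycle: int = 1) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-trial firing rates in the trough (120-240 deg) of one cycle."""
    occ, spk = _cycle_histograms(session, cycleset)
    mask = cycleset.cycles.cycle == cycle
    bins = slice(12, 24)  # [120, 240) in 10-deg bins
    dur = occ[mask.values][:, bins].sum(axis=1)
    cnt = spk[mask.values][:, :, bins].sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = cnt / dur[:, None]
    return rates, cycleset.cycles[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# relational odors


def relational_odors(trials: pd.DataFrame) -> pd.DataFrame:
    """Past / present / future odors of each trial from the trial table:
    past = previously presented odor in the sequence, present = presented
    odor, future = expected odor at the next position of ABCDE."""
    recs = []
    for _, grp in trials.groupby("sequence_id", sort=False):
        grp = grp.sort_values("position")
        odors = list(grp.odor)
        for i, (_, row) in enumerate(grp.iterrows()):
            pos = int(row.position)
            recs.append(dict(trial_id=row.trial_id,
                             past=odors[i - 1] if i > 0 else None,
                             present=row.odor,
                             future=ODORS[pos] if pos < 5 else None,
                             expected=ODORS[pos - 1]))
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# trough-trained LASSO classifier


@dataclass
class ThetaClassifier:
    clf: LogisticRegression | LogisticRegressionCV
    scaler: StandardScaler
    odors: tuple[str, ...]
    training_trial_ids: list[str]

    def predict_proba(self, rates: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(self.scaler.transform(rates))

    @property
    def zero_weight_neurons(self) -> np.ndarray:
        return np.flatnonzero(np.all(self.clf.coef_ == 0, axis=0))


def train_trough_lasso(
    session: Session,
    cycleset: ThetaCycleSet,
    seed: int = 0,
    odors: tuple[str, ...] = ODOR_SET,
    n_folds: int = 10,
    Cs: int = 5,
) -> ThetaClassifier:
    """L1-penalized multinomial logistic regression on cycle-1 trough rates
    of correct InSeq trials; the penalty is set by stratified cross-
    validation (folds reduced with a warning when a class is small)."""
    rates, rows = trough_rates(session, cycleset, cycle=1)
    trials = session.trials.set_index("trial_id")
    meta = trials.loc[rows.trial_id]
    keep = (meta.in_seq & meta.correct & meta.odor.isin(odors)).to_numpy()
    X = np.nan_to_num(rates[keep])
    y = meta.odor.to_numpy()[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 odor classes in the training cycles")
    class_min = pd.Series(y).value_counts().min()
    folds = min(n_folds, int(class_min))
    if folds < n_folds:
        log.warning("train_trough_lasso: reducing folds to %d (small class)", folds)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if folds >= 2:
        clf = LogisticRegressionCV(
            Cs=Cs, cv=folds, l1_ratios=(1.0,), solver="saga", max_iter=5000,
            random_state=derive_seed(seed, 61), scoring="accuracy",
        ).fit(Xs, y)
    else:  # degenerate: fixed penalty
        clf = LogisticRegression(penalty="l1", solver="saga", C=1.0,
                                 max_iter=5000).fit(Xs, y)
    order = [list(clf.classes_).index(od) for od in odors if od in clf.classes_]
    present = tuple(od for od in odors if od in clf.classes_)
    tc = ThetaClassifier(clf, scaler, present, list(rows.trial_id[keep]))
    tc._class_order = order  # noqa: SLF001 - cached column order
    return tc


def decode_phase_sliding(
    classifier: ThetaClassifier,
    session: Session,
    cycleset: ThetaCycleSet,
    cycles: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Odor probabilities per 10-deg bin (120-deg window) per cycle row.

    Returns a tidy frame (trial_id, cycle, bin_center, p_<odor>..., plus the
    phase-window label of the bin). Bins with an empty window give NaN.
    """
    rates = sliding_phase_rates(session, cycleset)
    df = cycleset.cycles
    sel = np.ones(len(df), bool) if cycles is None else df.cycle.isin(cycles).to_numpy()
    rates = rates[sel]
    rows_meta = df[sel].reset_index(drop=True)
    n_rows = rates.shape[0]
    flat = rates.transpose(0, 2, 1).reshape(n_rows * N_BINS, -1)
    ok = ~np.isnan(flat).any(axis=1)
    probs = np.full((flat.shape[0], len(classifier.odors)), np.nan)
    if ok.any():
        p = classifier.predict_proba(np.nan_to_num(flat[ok]))
        probs[ok] = p[:, classifier._class_order] if hasattr(classifier, "_class_order") else p
    out = pd.DataFrame({
        "trial_id": np.repeat(rows_meta.trial_id.to_numpy(), N_BINS),
        "cycle": np.repeat(rows_meta.cycle.to_numpy(), N_BINS),
        "bin_center": np.tile(BIN_CENTERS, n_rows),
    })
    for j, od in enumerate(classifier.odors):
        out[f"p_{od}"] = probs[:, j]
    out["phase"] = pd.cut(out.bin_center, [0, 120, 240, 360], right=False,
                          labels=["descending", "trough", "ascending"])
    return out


def attach_roles(decoded: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Add p_past / p_present / p_future columns from each trial's
    relational odors (NaN where the role odor is undefined or outside the
    decoded odor set)."""
    rel = relational_odors(trials).set_index("trial_id")
    out = decoded.copy()
    for role in ("past", "present", "future"):
        role_od = rel[role].reindex(out.trial_id).to_numpy()
        vals = np.full(len(out), np.nan)
        for od in ODOR_SET:
            m = role_od == od
            col = f"p_{od}"
            if col in out:
                vals[m] = out.loc[m, col]
        out[f"p_{role}"] = vals
    return out


# ---------------------------------------------------------------------------
# cycle-1 hypothesis tests and cross-cycle analysis


def cycle1_phase_tests(decoded_roles: pd.DataFrame) -> dict:
    """Paired comparisons of past/present/future decoding across the three
    phases of cycle 1 (pooled over odor B and C trials by the caller)."""
    d = decoded_roles[decoded_roles.cycle == 1]
    per = d.groupby(["trial_id", "phase"], observed=True)[
        ["p_past", "p_present", "p_future"]].mean().reset_index()
    piv = {ph: per[per.phase == ph].set_index("trial_id")
           for ph in ("descending", "trough", "ascending")}
    common = piv["descending"].index.intersection(piv["trough"].index).intersection(
        piv["ascending"].index)
    res: dict = {"n_trials": int(len(common))}

    def paired(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        ok = ~(np.isnan(a) | np.isnan(b))
        t, p = stats.ttest_rel(a[ok], b[ok])
        return float(t), float(p)

    res["descending_past_gt_future"] = paired(
        piv["descending"].loc[common, "p_past"].to_numpy(),
        piv["descending"].loc[common, "p_future"].to_numpy())
    res["ascending_future_gt_past"] = paired(
        piv["ascending"].loc[common, "p_future"].to_numpy(),
        piv["ascending"].loc[common, "p_past"].to_numpy())
    res["trough_present_gt_descending"] = paired(
        piv["trough"].loc[common, "p_present"].to_numpy(),
        piv["descending"].loc[common, "p_present"].to_numpy())
    res["trough_present_gt_ascending"] = paired(
        piv["trough"].loc[common, "p_present"].to_numpy(),
        piv["ascending"].loc[common, "p_present"].to_numpy())
    # ascending/descending x past/future interaction
    a = piv["descending"].loc[common, "p_past"].to_numpy() - piv["descending"].loc[common, "p_future"].to_numpy()
    b = piv["ascending"].loc[common, "p_past"].to_numpy() - piv["ascending"].loc[common, "p_future"].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    t, p = stats.ttest_rel(a[ok], b[ok])
    res["interaction_t"], res["interaction_p"] = float(t), float(p)
    return res


def cross_cycle_analysis(
    decoded_roles: pd.DataFrame,
    cycles: tuple[int, ...] = (-2, 1, 3, 5),
) -> tuple[pd.DataFrame, dict]:
    """Role decoding across equidistant cycles, collapsed over phase.

    Each role's probabilities are z-normalized over its whole normalization
    set (all bins, cycles, trials); the same trends are reported for raw
    values. Returns (per-trial-per-cycle table, summary with linear /
    quadratic trend tests)."""
    d = decoded_roles[decoded_roles.cycle.isin(cycles)].copy()
    for role in ("past", "present", "future"):
        col = f"p_{role}"
        mu, sd = d[col].mean(), d[col].std()
        d[f"z_{role}"] = (d[col] - mu) / (sd if sd else 1.0)
    per = d.groupby(["trial_id", "cycle"], observed=True)[
        [c for c in d.columns if c.startswith(("p_", "z_"))]].mean().reset_index()
    order = {c: i for i, c in enumerate(sorted(cycles))}
    per["cycle_rank"] = per.cycle.map(order)
    summary: dict = {}
    for role in ("past", "present", "future"):
        sub = per.dropna(subset=[f"z_{role}"])
        summary[f"{role}_linear"] = linear_trend_test(sub[f"z_{role}"], sub.cycle_rank)
        summary[f"{role}_quadratic"] = quadratic_trend_test(sub[f"z_{role}"], sub.cycle_rank)
        summary[f"{role}_linear_raw"] = linear_trend_test(sub[f"p_{role}"], sub.cycle_rank)
    # stimulus x cycle interaction on the long table
    long = per.melt(id_vars=["trial_id", "cycle_rank"],
                    value_vars=["z_past", "z_present", "z_future"],
                    var_name="role", value_name="z").dropna()
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    fit = ols("z ~ C(role) * cycle_rank", data=long).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    summary["interaction_F"] = float(an.loc["C(role):cycle_rank", "F"])
    summary["interaction_p"] = float(an.loc["C(role):cycle_rank", "PR(>F)"])
    return per, summary


# ---------------------------------------------------------------------------
# trial-type comparisons


def outcome_comparison(
    classifier: ThetaClassifier,
    session: Session,
    cycleset: ThetaCycleSet,
    positions: tuple[int, ...] = (2, 3),
    n_downsample: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Pre-entry decoding of the expected (InSeq) stimulus on OutSeq trials:
    correct vs incorrect, per phase, averaged over the two pre-entry cycles.
    Two-way ANOVA (outcome x phase) + Bonferroni per-phase t-tests."""
    trials = session.trials
    out = trials[(~trials.in_seq) & trials.position.isin(positions)]
    if out[out.correct].empty or out[~out.correct].empty:
        raise ValueError("need correct and incorrect OutSeq trials")
    dec = decode_phase_sliding(classifier, session, cycleset, cycles=(-1, -2))
    dec = dec[dec.trial_id.isin(out.trial_id)]
    rel = relational_odors(trials).set_index("trial_id")
    exp_od = rel.expected.reindex(dec.trial_id).to_numpy()
    vals = np.full(len(dec), np.nan)
    for od in classifier.odors:
        m = exp_od == od
        vals[m] = dec.loc[m, f"p_{od}"]
    dec = dec.assign(p_expected=vals)
    per = dec.groupby(["trial_id", "phase"], observed=True).p_expected.mean().reset_index()
    per = per.merge(trials[["trial_id", "correct"]], on="trial_id")
    res: dict = {}
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    fit = ols("p_expected ~ C(correct) * C(phase)", data=per.dropna()).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    res["interaction_F"] = float(an.loc["C(correct):C(phase)", "F"])
    res["interaction_p"] = float(an.loc["C(correct):C(phase)", "PR(>F)"])
    for ph in ("descending", "trough", "ascending"):
        a = per[(per.phase == ph) & per.correct].p_expected.dropna()
        b = per[(per.phase == ph) & ~per.correct].p_expected.dropna()
        if a.size < 2 or b.size < 2:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(a, b)
        res[f"{ph}_t"], res[f"{ph}_p_bonf"] = float(t), float(min(1.0, 3 * p))
        res[f"{ph}_mean_correct"] = float(a.mean()) if a.size else np.nan
        res[f"{ph}_mean_incorrect"] = float(b.mean()) if b.size else np.nan
    if n_downsample is not None:
        from .permute import permutation_stream
        corr_ids = per[per.correct].trial_id.unique()
        if n_downsample < corr_ids.size:
            ts = []
            for idx in permutation_stream(corr_ids.size, n_perm, derive_seed(seed, 62),
                                          "downsample", size=n_downsample):
                sub = per[per.trial_id.isin(corr_ids[idx]) | ~per.correct]
                a = sub[(sub.phase == "ascending") & sub.correct].p_expected.dropna()
                b = sub[(sub.phase == "ascending") & ~sub.correct].p_expected.dropna()
                ts.append(stats.ttest_ind(a, b)[0])
            res["ascending_t_downsampled_mean"] = float(np.nanmean(ts))
    return res


def inseq_outseq_comparison(
    classifier: ThetaClassifier,
    session: Session,
    cycleset: ThetaCycleSet,
    positions: tuple[int, ...] = (2, 3),
) -> dict:
    """Cycle-1 decoding of the reference InSeq stimuli (past at descending,
    expected-present at trough, future at ascending) compared between InSeq
    and OutSeq trials."""
    trials = session.trials
    rel = relational_odors(trials).set_index("trial_id")
    dec = decode_phase_sliding(classifier, session, cycleset, cycles=(1,))
    keep = trials[trials.position.isin(positions)]
    dec = dec[dec.trial_id.isin(keep.trial_id)]
    ref_role = {"descending": "past", "trough": "expected", "ascending": "future"}
    vals = np.full(len(dec), np.nan)
    for ph, role in ref_role.items():
        m = (dec.phase == ph).to_numpy()
        role_od = rel[role].reindex(dec.trial_id).to_numpy()
        for od in classifier.odors:
            mm = m & (role_od == od)
            vals[mm] = dec.loc[mm, f"p_{od}"]
    dec = dec.assign(p_ref=vals)
    per = dec.groupby(["trial_id", "phase"], observed=True).p_ref.mean().reset_index()
    per = per.merge(trials[["trial_id", "in_seq"]], on="trial_id")
    res: dict = {}
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    fit = ols("p_ref ~ C(in_seq) * C(phase)", data=per.dropna()).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    res["interaction_F"] = float(an.loc["C(in_seq):C(phase)", "F"])
    res["interaction_p"] = float(an.loc["C(in_seq):C(phase)", "PR(>F)"])
    for ph in ("descending", "trough", "ascending"):
        a = per[(per.phase == ph) & per.in_seq].p_ref.dropna()
        b = per[(per.phase == ph) & ~per.in_seq].p_ref.dropna()
        t, p = stats.ttest_ind(a, b)
        res[f"{ph}_t"], res[f"{ph}_p_bonf"] = float(t), float(min(1.0, 3 * p))
        res[f"{ph}_mean_inseq"], res[f"{ph}_mean_outseq"] = float(a.mean()), float(b.mean())
    return res


# ---------------------------------------------------------------------------
# single-cell decoding


def _univariate_models(
    session: Session,
    cycleset: ThetaCycleSet,
    odors: tuple[str, ...] = ODOR_SET,
) -> tuple[list, np.ndarray, list]:
    """One logistic model per neuron, trained on its cycle-1 trough rate
    (correct InSeq trials). Returns (models, training mask of usable neurons,
    class orders)."""
    rates, rows = trough_rates(session, cycleset, cycle=1)
    trials = session.trials.set_index("trial_id")
    meta = trials.loc[rows.trial_id]
    keep = (meta.in_seq & meta.correct & meta.odor.isin(odors)).to_numpy()
    X = np.nan_to_num(rates[keep])
    y = meta.odor.to_numpy()[keep]
    models, orders = [], []
    for j in range(session.n_neurons):
        xj = X[:, [j]]
        if xj.std() == 0:
            models.append(None)
            orders.append(None)
            continue
        clf = LogisticRegression(max_iter=1000).fit(xj, y)
        models.append(clf)
        orders.append([list(clf.classes_).index(od) if od in clf.classes_ else -1
                       for od in odors])
    return models, keep, orders


def single_cell_role_probs(
    session: Session,
    cycleset: ThetaCycleSet,
    trials: pd.DataFrame,
    cycles: tuple[int, ...],
    odors: tuple[str, ...] = ODOR_SET,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-neuron decoded role probabilities.

    Returns (array (n_neurons, n_rows, 36, 3) of past/present/future
    probabilities, row metadata). NaN where a role odor is undefined or a
    neuron unusable."""
    models, _, orders = _univariate_models(session, cycleset, odors)
    rates = sliding_phase_rates(session, cycleset)
    df = cycleset.cycles
    sel = df.cycle.isin(cycles).to_numpy() & df.trial_id.isin(trials.trial_id).to_numpy()
    rates = rates[sel]
    meta = df[sel].reset_index(drop=True)
    rel = relational_odors(session.trials).set_index("trial_id")
    n_rows = rates.shape[0]
    out = np.full((session.n_neurons, n_rows, N_BINS, 3), np.nan)
    role_ods = {role: rel[role].reindex(meta.trial_id).to_numpy()
                for role in ("past", "present", "future")}
    for j, (clf, order) in enumerate(zip(models, orders)):
        if clf is None:
            continue
        x = np.nan_to_num(rates[:, j, :]).reshape(-1, 1)
        p = clf.predict_proba(x)  # (n_rows*36, n_classes)
        full = np.zeros((x.shape[0], len(odors)))
        for c, od in enumerate(odors):
            if order[c] >= 0:
                full[:, c] = p[:, order[c]]
        full = full.reshape(n_rows, N_BINS, len(odors))
        for k, role in enumerate(("past", "present", "future")):
            ods = role_ods[role]
            for c, od in enumerate(odors):
                m = ods == od
                out[j, m, :, k] = full[m, :, c]
    return out, meta


def single_cell_phase_map(
    session: Session,
    cycleset: ThetaCycleSet,
    trials: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha_screen: float = 0.05,
) -> dict:
    """Proportion of phase-modulated neurons decoding past / present /
    future per 10-deg bin of cycle 1, and the diagonal (phase x stimulus)
    correlation with a permutation p-value.

    Role probabilities are z-scored per role over all bins and trials; each
    neuron's decoded role per bin is the arg-max z. Neurons pass the screen
    when a one-way test of decoded probability across the three phase
    windows is significant for at least one odor.
    """
    probs, meta = single_cell_role_probs(session, cycleset, trials, cycles=(1,))
    n_neurons = probs.shape[0]
    # z per role across bins/trials, per neuron population convention:
    z = np.full_like(probs, np.nan)
    for k in range(3):
        v = probs[..., k]
        mu, sd = np.nanmean(v), np.nanstd(v)
        z[..., k] = (v - mu) / (sd if sd else 1.0)
    mean_z = np.nanmean(z, axis=1)  # (n_neurons, 36, 3)

    # phase-modulation screen on raw per-odor decoding across phase windows
    keep = np.zeros(n_neurons, bool)
    win_of_bin = np.repeat([0, 1, 2], 12)
    for j in range(n_neurons):
        if np.isnan(mean_z[j]).all():
            continue
        for k in range(3):
            groups = [mean_z[j, win_of_bin == w, k] for w in range(3)]
            groups = [g[~np.isnan(g)] for g in groups]
            if any(g.size < 2 for g in groups):
                continue
            if stats.f_oneway(*groups)[1] < alpha_screen:
                keep[j] = True
                break
    if not keep.any():
        raise ValueError("no phase-modulated neurons")
    decoded_role = np.nanargmax(np.where(np.isnan(mean_z), -np.inf, mean_z), axis=2)

    def diagonal_corr(roles_by_bin: np.ndarray) -> float:
        # 3x3 joint table: phase window x decoded role
        tab = np.zeros((3, 3))
        for j in np.flatnonzero(keep):
            for b in range(N_BINS):
                tab[win_of_bin[b], roles_by_bin[j, b]] += 1
        tab = tab / tab.sum()
        rows, cols = np.indices((3, 3))
        w = tab.ravel()
        x, y = rows.ravel().astype(float), cols.ravel().astype(float)
        mx, my = (w * x).sum(), (w * y).sum()
        cov = (w * (x - mx) * (y - my)).sum()
        sx = np.sqrt((w * (x - mx) ** 2).sum())
        sy = np.sqrt((w * (y - my) ** 2).sum())
        return float(cov / (sx * sy)) if sx and sy else 0.0

    obs = diagonal_corr(decoded_role)
    rng = np.random.default_rng(derive_seed(seed, 63))
    null = np.empty(n_perm)
    shuffled = decoded_role.copy()
    for i in range(n_perm):
        for j in np.flatnonzero(keep):
            shuffled[j] = decoded_role[j, rng.permutation(N_BINS)]
        null[i] = diagonal_corr(shuffled)
    p = (1 + np.sum(null >= obs)) / (n_perm + 1)
    prop = np.zeros((3, N_BINS))
    for j in np.flatnonzero(keep):
        for b in range(N_BINS):
            prop[decoded_role[j, b], b] += 1
    prop /= keep.sum()
    return {"diagonal_corr": obs, "p": float(p),
            "fraction_phase_modulated": float(keep.mean()),
            "proportions": prop}


# ---------------------------------------------------------------------------
# phase precession


def spike_phase_precession(
    session: Session,
    phase: PhaseSeries,
    trials: pd.DataFrame,
    odors: tuple[str, ...] = ("B", "C", "D"),
    min_spikes: int = 10,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Circular-linear correlation between in-trial spike time and theta
    phase, per neuron (odor A excluded to avoid running-associated theta).
    Neurons with fewer than ``min_spikes`` in-trial spikes are skipped."""
    sub = trials[trials.odor.isin(odors)]
    rows = []
    for neuron in session.neurons:
        st = neuron.spike_times
        xs, phs = [], []
        for _, tr in sub.iterrows():
            a = np.searchsorted(st, tr.poke_in, "left")
            b = np.searchsorted(st, tr.poke_out, "left")
            if b > a:
                xs.append(st[a:b] - tr.poke_in)
                phs.append(phase.at(st[a:b]))
        if not xs:
            continue
        x = np.concatenate(xs)
        if x.size < min_spikes:
            log.info("spike_phase_precession: %s skipped (<%d spikes)",
                     neuron.neuron_id, min_spikes)
            continue
        ph = np.concatenate(phs)
        rho, p, slope = circ_lin_corr(x, ph)
        rows.append(dict(neuron_id=neuron.neuron_id, n_spikes=int(x.size),
                         rho=rho, p=p, slope_deg_per_s=slope,
                         significant=bool(p < alpha)))
    return pd.DataFrame(rows)


def ensemble_precession(
    session: Session,
    cycleset: ThetaCycleSet,
    trials: pd.DataFrame,
    cycles: tuple[int, ...] = (-3, -2, -1, 1, 2, 3, 4, 5, 6),
    corr_cycles: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Phase of peak present-stimulus decoding per cycle, its correlation
    with cycle index, and a cycle-order permutation null.

    Per 10-deg bin and cycle, each neuron's mean present-stimulus decoding
    (odor B and C trials) is brought to a common scale by z-scoring within
    the cycle (per neuron, across bins) and summed across neurons; per-cycle
    curves are normalized to [-1, 1]; the peak phase per cycle is correlated
    with the cycle index. (Z-scoring across neurons within each bin, read
    literally, sums to zero identically, so the per-neuron normalization is
    used.) The correlation runs over ``corr_cycles`` — post-entry cycles by
    default, because before port entry the "present" stimulus is represented
    through predictive ascending-phase coding, whose phase is not produced
    by within-field precession and would confound the estimate. The null
    permutes the order of each trial's cycles."""
    sub = trials[trials.odor.isin(("B", "C"))]
    probs, meta = single_cell_role_probs(session, cycleset, sub, cycles=cycles)
    pres = probs[..., 1]  # (n_neurons, n_rows, 36) present-stimulus prob
    cyc = meta.cycle.to_numpy()
    tid = meta.trial_id.to_numpy()
    cycles_sorted = sorted(set(cyc))
    c_index = {c: i for i, c in enumerate(cycles_sorted)}
    n_c = len(cycles_sorted)
    trial_list = list(dict.fromkeys(tid))
    t_index = {t: i for i, t in enumerate(trial_list)}
    # dense (n_neurons, n_trials, n_cycles, 36); NaN where absent
    n_neurons = pres.shape[0]
    dense = np.full((n_neurons, len(trial_list), n_c, N_BINS), np.nan)
    for r in range(pres.shape[1]):
        dense[:, t_index[tid[r]], c_index[cyc[r]], :] = pres[:, r, :]

    corr_mask = np.array([c in corr_cycles for c in cycles_sorted])
    corr_x = np.asarray([c_index[c] for c in cycles_sorted if c in corr_cycles], float)

    def peaks_and_corr(d: np.ndarray) -> tuple[np.ndarray, float]:
        from scipy.ndimage import gaussian_filter1d

        with np.errstate(invalid="ignore"):
            m = np.nanmean(d, axis=1)               # (n_neurons, n_cycles, 36)
            mu = np.nanmean(m, axis=2, keepdims=True)
            sd = np.nanstd(m, axis=2, keepdims=True)
            z = (m - mu) / np.where(sd == 0, 1, sd)
            s = np.nansum(z, axis=0)                # (n_cycles, 36)
            s = gaussian_filter1d(s, 1.0, axis=1, mode="wrap")  # 10-deg smoothing
            lo, hi = s.min(axis=1, keepdims=True), s.max(axis=1, keepdims=True)
            rngv = np.where(hi - lo == 0, 1, hi - lo)
            norm = 2 * (s - lo) / rngv - 1
        pk = BIN_CENTERS[np.argmax(norm, axis=1)]
        r = float(np.corrcoef(corr_x, pk[corr_mask])[0, 1])
        return pk, r

    peaks, r_obs = peaks_and_corr(dense)
    rng = np.random.default_rng(derive_seed(seed, 64))
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuf = np.empty_like(dense)
        for t in range(len(trial_list)):
            shuf[:, t] = dense[:, t, rng.permutation(n_c), :]
        null[i] = peaks_and_corr(shuf)[1]
    p = (1 + np.sum(null <= r_obs)) / (n_perm + 1)  # one-sided: precession is negative
    return {"peak_phase_by_cycle": dict(zip(cycles_sorted, peaks.tolist())),
            "r": r_obs, "p": float(p), "null_mean": float(null.mean())}
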