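"""Supervised odor decoding with a tetrode-wise convolutional network.

The decoder consumes, per tetrode, a multivariate time series on a common
10 ms grid over a trial window: the tetrode's LFP (z-scored session-wide,
down-averaged to the grid) plus each of its units' spike counts. Convolution
filters are applied per tetrode, time-averaged features are concatenated and
passed through dropout-regularized dense layers to a softmax over odors A-D.
Training uses correct InSeq trials in the 150-400 ms window after port
entry; the trained model is then applied to successive 250 ms windows from
-400 ms to 1350 ms to trace the within-trial decoding dynamics, with the
penultimate hidden layer serving as a supervised latent space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .nn import TetrodeCNN
from .permute import derive_seed, permutation_stream
from .session import Session
from .stats import cmh_general, goodman_multinomial_ci
from .windows import window_spike_counts

log = logging.getLogger(__name__)

GRID = 0.01  # s, common LFP/spike grid
TRAIN_WINDOW = (0.15, 0.40)
DECODE_STARTS_MS = tuple(range(-400, 1101, 250))  # seven 250 ms windows
ODOR_SET = ("A", "B", "C", "D")


@dataclass
class OdorDecoder:
    net: TetrodeCNN
    odors: tuple[str, ...]
    tetrodes: list[str]
    units_of_tetrode: dict[str, list[str]]
    lfp_norm: dict[str, tuple[float, float]]  # tetrode -> (mean, sd)
    window_s: float = 0.25
    meta: dict = field(default_factory=dict)

    def predict_proba(self, inputs: list[np.ndarray]) -> np.ndarray:
        return self.net.predict_proba(inputs)

    def latent(self, inputs: list[np.ndarray]) -> np.ndarray:
        return self.net.latent(inputs)


def _tetrode_layout(session: Session) -> tuple[list[str], dict[str, list[str]]]:
    tets = sorted({session.tetrode_of_neuron[n] for n in session.neuron_ids})
    units = {t: [n for n in session.neuron_ids if session.tetrode_of_neuron[n] == t]
             for t in tets}
    return tets, units


def build_inputs(
    session: Session,
    trials: pd.DataFrame,
    window: tuple[float, float],
    tetrodes: list[str],
    units_of_tetrode: dict[str, list[str]],
    lfp_norm: dict[str, tuple[float, float]] | None = None,
) -> list[np.ndarray]:
    """Per-tetrode input arrays (n_trials, n_channels, n_steps)."""
    counts = window_spike_counts(session, trials, "poke_in", window, GRID)
    t_steps = counts.shape[2]
    nid_idx = {n: i for i, n in enumerate(session.neuron_ids)}
    have_lfp = bool(session.lfp) and lfp_norm is not None
    inputs = []
    anchors = trials.poke_in.to_numpy()
    for tet in tetrodes:
        chans = [counts[:, [nid_idx[n] for n in units_of_tetrode[tet]], :]]
        if have_lfp:
            ch = session.lfp_channel(tet)
            mu, sd = lfp_norm[tet]
            blocks = np.empty((len(trials), 1, t_steps))
            per_block = int(round(GRID * ch.fs))
            for i, a in enumerate(anchors):
                i0 = int(round((a + window[0] - ch.t0) * ch.fs))
                seg = ch.samples[i0:i0 + t_steps * per_block]
                blocks[i, 0] = ((seg - mu) / sd).reshape(t_steps, per_block).mean(axis=1)
            chans.append(blocks)
        inputs.append(np.concatenate(chans, axis=1).astype(float))
    return inputs


def _lfp_norms(session: Session, tetrodes: list[str]) -> dict[str, tuple[float, float]]:
    norms = {}
    for tet in tetrodes:
        try:
            ch = session.lfp_channel(tet)
        except KeyError:
            continue
        norms[tet] = (float(ch.samples.mean()), float(ch.samples.std() or 1.0))
    return norms


def train_cnn(
    session: Session,
    trials: pd.DataFrame,
    seed: int,
    odors: tuple[str, ...] = ODOR_SET,
    train_window: tuple[float, float] = TRAIN_WINDOW,
    **net_kw,
) -> OdorDecoder:
    """Train the tetrode-wise CNN on correct InSeq trials (caller-filtered)."""
    sub = trials[trials.odor.isin(odors)]
    y = np.searchsorted(np.asarray(odors), sub.odor.to_numpy())
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 odor classes")
    tets, units = _tetrode_layout(session)
    lfp_norm = _lfp_norms(session, tets) if session.lfp else {}
    inputs = build_inputs(session, sub, train_window, tets, units,
                          lfp_norm if lfp_norm else None)
    net = TetrodeCNN(
        channel_counts=[x.shape[1] for x in inputs],
        n_timesteps=inputs[0].shape[2],
        n_classes=len(odors),
        seed=derive_seed(seed, 51),
        **net_kw,
    ).fit(inputs, y)
    return OdorDecoder(net, tuple(odors), tets, units, lfp_norm,
                       window_s=train_window[1] - train_window[0])


def cv_accuracy(
    session: Session,
    trials: pd.DataFrame,
    seed: int,
    n_folds: int = 10,
    model: str = "cnn",
    odors: tuple[str, ...] = ODOR_SET,
    train_window: tuple[float, float] = TRAIN_WINDOW,
    shuffle_labels: bool = False,
    balance: bool = False,
    **net_kw,
) -> float:
    """Stratified k-fold held-out accuracy of the CNN or of the benchmark
    multinomial logistic regression on the same inputs.

    ``balance`` downsamples every odor class to the smallest class count (a
    balanced subset), so chance is exactly 1/len(odors)."""
    sub = trials[trials.odor.isin(odors)].reset_index(drop=True)
    if balance:
        rng = np.random.default_rng(derive_seed(seed, 56))
        n_min = sub.odor.value_counts().min()
        keep = np.concatenate([
            rng.choice(np.flatnonzero(sub.odor == od), n_min, replace=False)
            for od in odors if (sub.odor == od).any()
        ])
        sub = sub.iloc[np.sort(keep)].reset_index(drop=True)
    y = np.searchsorted(np.asarray(odors), sub.odor.to_numpy())
    if shuffle_labels:
        y = y[next(permutation_stream(y.size, 1, derive_seed(seed, 52)))]
    counts = np.bincount(y)
    n_folds = min(n_folds, counts[counts > 0].min())
    if n_folds < 2:
        raise ValueError("a class has too few trials for stratified folds")
    tets, units = _tetrode_layout(session)
    lfp_norm = _lfp_norms(session, tets) if session.lfp else None
    inputs = build_inputs(session, sub, train_window, tets, units, lfp_norm)
    flat = np.concatenate([x.reshape(x.shape[0], -1) for x in inputs], axis=1)
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=derive_seed(seed, 53))
    correct = 0
    for tr, te in skf.split(flat, y):
        if model == "cnn":
            net = TetrodeCNN(
                channel_counts=[x.shape[1] for x in inputs],
                n_timesteps=inputs[0].shape[2],
                n_classes=len(odors),
                seed=derive_seed(seed, 54),
                **net_kw,
            ).fit([x[tr] for x in inputs], y[tr])
            pred = net.predict_proba([x[te] for x in inputs]).argmax(axis=1)
        elif model == "logistic":
            clf = LogisticRegression(max_iter=2000).fit(flat[tr], y[tr])
            pred = clf.predict(flat[te])
        else:
            raise ValueError(model)
        correct += int((pred == y[te]).sum())
    return correct / y.size


def decode_windows(
    decoder: OdorDecoder,
    session: Session,
    trials: pd.DataFrame,
    starts_ms: tuple[int, ...] = DECODE_STARTS_MS,
    flag_training_trials: set | None = None,
) -> pd.DataFrame:
    """Apply the trained decoder to each 250 ms window of each trial.

    Returns a tidy frame (trial_id, odor, window_start_ms, p_<odor>...,
    argmax, in_sample)."""
    rows = []
    for start in starts_ms:
        win = (start / 1000.0, start / 1000.0 + decoder.window_s)
        inputs = build_inputs(session, trials, win, decoder.tetrodes,
                              decoder.units_of_tetrode,
                              decoder.lfp_norm if decoder.lfp_norm else None)
        probs = decoder.predict_proba(inputs)
        for i, (_, tr) in enumerate(trials.iterrows()):
            rec = dict(trial_id=tr.trial_id, odor=tr.odor, window_start_ms=start,
                       in_sample=bool(flag_training_trials and tr.trial_id in flag_training_trials))
            rec.update({f"p_{od}": float(probs[i, j]) for j, od in enumerate(decoder.odors)})
            rec["argmax"] = decoder.odors[int(probs[i].argmax())]
            rows.append(rec)
    return pd.DataFrame(rows)


def latent_projection(
    decoder: OdorDecoder,
    session: Session,
    trials: pd.DataFrame,
    window: tuple[float, float] = TRAIN_WINDOW,
) -> tuple[pd.DataFrame, LogisticRegression, float]:
    """2-D PCA of the supervised latent space with linearized class regions.

    Returns (coordinates frame, boundary model, consistency = fraction of
    points whose linear region agrees with the decoder argmax).
    """
    inputs = build_inputs(session, trials, window, decoder.tetrodes,
                          decoder.units_of_tetrode,
                          decoder.lfp_norm if decoder.lfp_norm else None)
    lat = decoder.latent(inputs)
    if np.allclose(lat.var(axis=0).sum(), 0):
        raise ValueError("degenerate latent covariance")
    xy = PCA(n_components=2).fit_transform(lat)
    pred = decoder.predict_proba(inputs).argmax(axis=1)
    boundary = LogisticRegression(max_iter=2000).fit(xy, pred)
    consistency = float((boundary.predict(xy) == pred).mean())
    df = pd.DataFrame(dict(trial_id=trials.trial_id, x=xy[:, 0], y=xy[:, 1],
                           decoded=[decoder.odors[k] for k in pred]))
    return df, boundary, consistency


def window_stats(
    probs: pd.DataFrame,
    odors: tuple[str, ...] = ODOR_SET,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window pooled multinomial statistics.

    Trials are pooled by their argmax class (as when aggregating ensembles),
    giving per-window counts; Goodman simultaneous CIs and a chi-square test
    against uniformity are reported. Non-overlapping CIs between two classes
    indicate a significant difference.
    """
    rows = []
    for start, grp in probs.groupby("window_start_ms"):
        counts = np.array([(grp["argmax"] == od).sum() for od in odors])
        if counts.sum() == 0:
            continue
        ci = goodman_multinomial_ci(counts, alpha)
        chi2, p = stats.chisquare(counts)
        rec = dict(window_start_ms=start, n=int(counts.sum()),
                   chi2=float(chi2), chi2_p=float(p))
        for j, od in enumerate(odors):
            rec[f"count_{od}"] = int(counts[j])
            rec[f"ci_lo_{od}"], rec[f"ci_hi_{od}"] = float(ci[j, 0]), float(ci[j, 1])
        rows.append(rec)
    return pd.DataFrame(rows)


def probability_slope_test(
    probs: pd.DataFrame, odor_x: str, odor_y: str
) -> tuple[pd.Series, float, float]:
    """Per-trial least-squares slope of (P_x - P_y) across the window grid,
    with a one-sample two-tailed t-test of the slopes against zero."""
    slopes = {}
    for tid, grp in probs.groupby("trial_id"):
        grp = grp.sort_values("window_start_ms")
        d = grp[f"p_{odor_x}"].to_numpy() - grp[f"p_{odor_y}"].to_numpy()
        if len(d) < 2 or np.isnan(d).any():
            continue
        slopes[tid] = np.polyfit(np.arange(len(d)), d, 1)[0]
    s = pd.Series(slopes)
    t, p = stats.ttest_1samp(s.to_numpy(), 0.0)
    return s, float(t), float(p)


def outcome_pretrial_comparison(
    decoder: OdorDecoder,
    session: Session,
    positions: tuple[int, ...] = (2, 3, 4),
    window: tuple[float, float] = (-0.25, 0.0),
    n_downsample: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Pre-entry decoding of the expected (InSeq) odor on OutSeq trials,
    compared between correct and incorrect responses (KS test)."""
    from .session import ODORS as ALL_ODORS

    trials = session.trials
    out = trials[(~trials.in_seq) & trials.position.isin(positions)]
    if out[out.correct].empty or out[~out.correct].empty:
        raise ValueError("need correct and incorrect OutSeq trials")
    inputs = build_inputs(session, out, window, decoder.tetrodes,
                          decoder.units_of_tetrode,
                          decoder.lfp_norm if decoder.lfp_norm else None)
    probs = decoder.predict_proba(inputs)
    expected = [ALL_ODORS[int(p) - 1] for p in out.position]
    p_exp = np.array([
        probs[i, decoder.odors.index(od)] if od in decoder.odors else np.nan
        for i, od in enumerate(expected)
    ])
    ok = ~np.isnan(p_exp)
    corr = p_exp[ok & out.correct.to_numpy()]
    inc = p_exp[ok & ~out.correct.to_numpy()]
    d, p = stats.ks_2samp(corr, inc)
    res = {"ks_D": float(d), "ks_p": float(p),
           "mean_correct": float(corr.mean()), "mean_incorrect": float(inc.mean())}
    if n_downsample is not None and n_downsample < corr.size:
        ds = [stats.ks_2samp(corr[idx], inc)[0]
              for idx in permutation_stream(corr.size, n_perm, derive_seed(seed, 55),
                                            "downsample", size=n_downsample)]
        res["ks_D_downsampled_mean"] = float(np.mean(ds))
    return res


def cmh_subject_control(confusions: list[np.ndarray]) -> dict:
    """Cochran-Mantel-Haenszel control for subject effects.

    ``confusions``: per-session confusion matrices (true odor x predicted
    odor). Builds one leave-one-session-out group matrix per session,
    re-stratifies by true odor, and tests whether predicted odors vary
    across the leave-one-out groups. Invariant to session ordering.
    """
    if len(confusions) < 2:
        raise ValueError("need >= 2 sessions")
    conf = np.stack([np.asarray(c, dtype=float) for c in confusions])
    loo = conf.sum(axis=0)[None] - conf  # (n_sessions, n_true, n_pred)
    # strata = true odors: tables (n_loo_groups x n_predicted)
    tables = np.stack([loo[:, k, :] for k in range(conf.shape[1])])
    q, df, p = cmh_general(tables)
    return {"chi2": q, "df": df, "p": p}
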