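"""Memoryless Bayesian reconstruction of time from ensemble spiking.

Under independent-Poisson spiking, the posterior over reconstructed time t
given the spike-count vector n observed in an actual-time bin is

    P(t | n, odor)  ∝  P(t | odor) · Π_i [tau f_i(t, odor)]^{n_i} / n_i!
                       · exp(-tau Σ_i f_i(t, odor))

with tau the bin length, f_i the mean training firing rate of neuron i, and
a uniform prior over time within the analysis window (all InSeq holds share
the same duration). Likelihoods are evaluated in log space; a rate floor
eps = 1e-3 Hz keeps the log finite when a spike lands in a zero-rate bin.
Neurons whose training rate is all-zero for the decoded odor are dropped
from that decode.

The decoder is memoryless: each actual-time bin (overlapping bins of width
tau advancing by ``step``) is decoded independently. Reconstruction accuracy
of a trial's posterior matrix is the mean Pearson correlation between
matching rows and columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .permute import derive_seed, permutation_stream
from .select import TrialSelection, intact_sequence_ids, select_trials
from .session import ODOR_POSITION, ODORS, Session
from .stats import kl_divergence, linear_trend_test
from .windows import sliding_spike_counts

log = logging.getLogger(__name__)

EPS_RATE = 1e-3  # Hz floor applied to rates before taking logs


@dataclass
class RateMap:
    f: dict[str, np.ndarray]  # odor -> (n_neurons, n_bins) mean rate, Hz
    tau: float
    step: float
    window: tuple[float, float]
    neuron_ids: list[str]
    training_trial_ids: dict[str, list[str]]
    flagged: dict[str, list[str]] = field(default_factory=dict)  # all-zero neurons per odor

    @property
    def n_bins(self) -> int:
        return next(iter(self.f.values())).shape[1]


def fit_rate_map(
    session: Session,
    trials: pd.DataFrame,
    tau: float = 0.05,
    step: float = 0.005,
    window: tuple[float, float] = (0.0, 1.2),
    odors: tuple[str, ...] = ("A", "B", "C", "D"),
    anchor: str = "poke_in",
) -> RateMap:
    """Mean firing rate per neuron in overlapping time bins, per odor."""
    f: dict[str, np.ndarray] = {}
    train_ids: dict[str, list[str]] = {}
    flagged: dict[str, list[str]] = {}
    for od in odors:
        sub = trials[trials.odor == od]
        if sub.empty:
            raise ValueError(f"no training trials for odor {od}")
        counts, _ = sliding_spike_counts(session, sub, anchor, window, tau, step)
        f[od] = counts.mean(axis=0) / tau
        train_ids[od] = list(sub.trial_id)
        zero = [nid for nid, row in zip(session.neuron_ids, f[od]) if row.max() == 0]
        if zero:
            flagged[od] = zero
            log.info("fit_rate_map: odor %s has %d all-zero neurons", od, len(zero))
    return RateMap(f, tau, step, window, list(session.neuron_ids), train_ids, flagged)


def decode_posterior(
    f: np.ndarray, counts: np.ndarray, tau: float, eps: float = EPS_RATE
) -> np.ndarray:
    """Posterior matrix (n_actual_bins, n_candidate_bins).

    ``f``: (n_neurons, n_candidate_bins) rates; ``counts``:
    (n_actual_bins, n_neurons). Neurons with all-zero rate rows are dropped.
    Rows sum to 1.
    """
    active = f.max(axis=1) > 0
    if not active.any():
        raise ValueError("cannot decode: all neurons have zero training rate")
    fa = np.maximum(f[active], eps)
    n = counts[:, active].astype(float)
    loglik = n @ np.log(tau * fa) - (tau * fa).sum(axis=0)[None, :]
    post = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    return post


def decode_time(
    rate_map: RateMap,
    counts: np.ndarray,
    odor: str | None = None,
    mode: str = "within-odor",
) -> np.ndarray:
    """Decode a trial's sliding-bin counts against the rate map.

    ``within-odor`` returns (n_actual, n_bins) over reconstructed time for
    the given odor; ``joint`` returns (n_actual, n_bins * n_odors) over
    (time, odor) pairs, ordered odor-major in rate-map odor order.
    """
    if mode == "within-odor":
        if odor is None:
            raise ValueError("within-odor decoding requires odor")
        return decode_posterior(rate_map.f[odor], counts, rate_map.tau)
    if mode == "joint":
        f = np.concatenate([rate_map.f[od] for od in rate_map.f], axis=1)
        return decode_posterior(f, counts, rate_map.tau)
    raise ValueError(f"unknown mode {mode!r}")


def reconstruction_accuracy(posterior: np.ndarray) -> float:
    """Mean Pearson correlation between matching rows and columns.

    Pairs with zero variance are skipped; if every pair is undefined the
    result is NaN (logged).
    """
    P = np.asarray(posterior, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"posterior must be square, got {P.shape}")
    rows = P - P.mean(axis=1, keepdims=True)
    cols = P.T - P.T.mean(axis=1, keepdims=True)
    num = (rows * cols).sum(axis=1)
    den = np.sqrt((rows**2).sum(axis=1) * (cols**2).sum(axis=1))
    valid = den > 0
    if not valid.any():
        log.info("reconstruction_accuracy: all row/column pairs undefined")
        return float("nan")
    return float(np.mean(num[valid] / den[valid]))


# ---------------------------------------------------------------------------
# leave-one-out protocol


def _per_trial_counts(session, trials, tau, step, window, anchor="poke_in"):
    counts, starts = sliding_spike_counts(session, trials, anchor, window, tau, step)
    return counts, starts


def loo_accuracies(
    session: Session,
    trials: pd.DataFrame,
    tau: float = 0.05,
    step: float = 0.005,
    window: tuple[float, float] = (0.0, 1.2),
) -> np.ndarray:
    """Leave-one-out reconstructed-time accuracy for each trial of one odor
    class: the rate map is refit from all remaining trials for every decode."""
    counts, _ = _per_trial_counts(session, trials, tau, step, window)
    n_trials = counts.shape[0]
    if n_trials < 2:
        raise ValueError("leave-one-out needs >= 2 trials")
    total = counts.sum(axis=0).astype(float)
    accs = np.empty(n_trials)
    for i in range(n_trials):
        f = (total - counts[i]) / (n_trials - 1) / tau
        post = decode_posterior(f, counts[i].T, tau)
        accs[i] = reconstruction_accuracy(post)
    return accs


def chance_accuracies(
    session: Session,
    trials: pd.DataFrame,
    tau: float = 0.05,
    step: float = 0.005,
    window: tuple[float, float] = (0.0, 1.2),
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Mean leave-one-out accuracy under ``n_perm`` random permutations of
    the time factor of the rate map (one joint permutation of the time bins,
    applied to every neuron)."""
    counts, _ = _per_trial_counts(session, trials, tau, step, window)
    n_trials, _, n_bins = counts.shape
    total = counts.sum(axis=0).astype(float)
    out = np.empty(n_perm)
    for k, perm in enumerate(permutation_stream(n_bins, n_perm, seed, "time-shuffle")):
        accs = []
        for i in range(n_trials):
            f = ((total - counts[i]) / (n_trials - 1) / tau)[:, perm]
            accs.append(reconstruction_accuracy(decode_posterior(f, counts[i].T, tau)))
        out[k] = np.nanmean(accs)
    return out


# ---------------------------------------------------------------------------
# lag analysis


def lag_analysis(
    session: Session,
    tau: float = 0.05,
    step: float = 0.025,
    window: tuple[float, float] = (0.0, 1.2),
    train_odors: tuple[str, ...] = ("A", "B", "C", "D"),
    max_lag: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Reconstructed-time accuracy as a function of sequence lag.

    The model is trained per odor at its proper position on trials from
    intact sequences (all InSeq, consecutively presented, correct). For
    |lag| >= 1 it is tested on correct InSeq trials of other odors; for lag 0
    on same-odor InSeq-correct trials outside the training set (trials from
    broken sequences, topped up by holding out training trials when needed).
    Train and test sets are disjoint in every cell.
    """
    trials = session.trials
    intact = intact_sequence_ids(trials)
    base = select_trials(trials, TrialSelection(in_seq=True, correct=True))
    rows = []
    for od in train_odors:
        pos = ODOR_POSITION[od]
        pool = base[(base.odor == od) & (base.sequence_id.isin(intact))]
        nonconsec = base[(base.odor == od) & (~base.sequence_id.isin(intact))]
        if len(pool) < 4:
            log.warning("lag_analysis: odor %s has too few intact-sequence trials", od)
            continue
        if len(nonconsec) >= 3:
            train, test0 = pool, nonconsec
        else:  # hold out every third training trial for the lag-0 test
            hold = pool.iloc[::3]
            train, test0 = pool.drop(hold.index), hold
        assert set(train.trial_id).isdisjoint(test0.trial_id)
        counts_tr, _ = _per_trial_counts(session, train, tau, step, window)
        f = counts_tr.mean(axis=0) / tau

        for test_od in ODORS:
            lag = ODOR_POSITION[test_od] - pos
            if abs(lag) > max_lag:
                continue
            test = test0 if lag == 0 else base[base.odor == test_od]
            if test.empty:
                log.info("lag_analysis: no test trials for %s->%s", od, test_od)
                continue
            counts_te, _ = _per_trial_counts(session, test, tau, step, window)
            for i, tid in enumerate(test.trial_id):
                acc = reconstruction_accuracy(decode_posterior(f, counts_te[i].T, tau))
                rows.append(dict(trial_id=tid, train_odor=od, test_odor=test_od,
                                 lag=lag, accuracy=acc))
    table = pd.DataFrame(rows).dropna(subset=["accuracy"])

    summary: dict = {}
    by_abs = table.assign(abs_lag=table.lag.abs()).groupby("abs_lag").accuracy.mean()
    summary["mean_by_abs_lag"] = by_abs.to_dict()
    groups = [g.accuracy.to_numpy() for _, g in table.groupby("lag")]
    if len(groups) > 1:
        f_stat, p = stats.f_oneway(*groups)
        summary["anova_F"], summary["anova_p"] = float(f_stat), float(p)
        lag0 = table[table.lag == 0].accuracy.to_numpy()
        others = {int(l): g.accuracy.to_numpy() for l, g in table.groupby("lag") if l != 0}
        if others and lag0.size > 1:
            res = stats.dunnett(*others.values(), control=lag0)
            summary["dunnett_p"] = dict(zip(others.keys(), (float(x) for x in res.pvalue)))
        pos_t = table[table.lag >= 0]
        neg_t = table[table.lag <= 0]
        summary["linear_trend_pos"] = linear_trend_test(pos_t.accuracy, pos_t.lag)
        summary["linear_trend_neg"] = linear_trend_test(neg_t.accuracy, -neg_t.lag)
    return table, summary


# ---------------------------------------------------------------------------
# full-sequence decoding and outcome comparison


def fit_sequence_rate_map(
    session: Session,
    tau: float = 0.5,
    step: float = 0.1,
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Rate map over full-sequence time, anchored at each sequence's first
    port entry, built from intact sequences. Returns (f, anchor table,
    window length = median intact-sequence duration)."""
    trials = session.trials
    intact = sorted(intact_sequence_ids(trials))
    if not intact:
        raise ValueError("no intact sequences to train on")
    anchors = []
    for sid in intact:
        grp = trials[trials.sequence_id == sid].sort_values("position")
        anchors.append(dict(sequence_id=sid, t_start=float(grp.poke_in.iloc[0]),
                            t_end=float(grp.poke_out.iloc[-1])))
    adf = pd.DataFrame(anchors)
    span = float(np.median(adf.t_end - adf.t_start))
    pseudo = pd.DataFrame({"poke_in": adf.t_start, "poke_out": adf.t_start + span,
                           "trial_id": adf.sequence_id})
    counts, _ = sliding_spike_counts(session, pseudo, "poke_in", (0.0, span), tau, step)
    return counts.mean(axis=0) / tau, adf, span


def outcome_kl_comparison(
    session: Session,
    tau: float = 0.5,
    step: float = 0.1,
    pre_window: float = 0.25,
    positions: tuple[int, ...] = (2, 3, 4),
    n_downsample: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Compare pre-entry time decoding on correct vs incorrect OutSeq trials.

    The model is trained on intact full sequences; each OutSeq trial's spike
    counts in the 250 ms before port entry are decoded into a posterior over
    sequence time, and compared (KL divergence) with the mean posterior of
    InSeq trials at the same sequence position. Correct vs incorrect KL
    distributions are compared with a two-sample Kolmogorov-Smirnov test.
    """
    f, _, span = fit_sequence_rate_map(session, tau, step)
    trials = session.trials

    def pre_entry_post(sub: pd.DataFrame) -> np.ndarray:
        counts, _ = sliding_spike_counts(
            session, sub, "poke_in", (-pre_window, 0.0), pre_window, pre_window
        )
        return decode_posterior(f, counts[:, :, 0], pre_window)

    inseq_mean: dict[int, np.ndarray] = {}
    for pos in positions:
        ref = trials[(trials.position == pos) & trials.in_seq & trials.correct]
        if ref.empty:
            raise ValueError(f"no InSeq reference trials at position {pos}")
        inseq_mean[pos] = pre_entry_post(ref).mean(axis=0)

    out = trials[(~trials.in_seq) & trials.position.isin(positions)]
    if out[out.correct].empty or out[~out.correct].empty:
        raise ValueError("need both correct and incorrect OutSeq trials")
    posts = pre_entry_post(out)
    kl = [
        kl_divergence(posts[i], inseq_mean[int(row.position)])
        for i, (_, row) in enumerate(out.iterrows())
    ]
    table = pd.DataFrame(dict(trial_id=out.trial_id, position=out.position,
                              correct=out.correct, kl=kl))
    corr = table[table.correct].kl.to_numpy()
    inc = table[~table.correct].kl.to_numpy()
    d, p = stats.ks_2samp(corr, inc)
    summary = {"ks_D": float(d), "ks_p": float(p),
               "mean_kl_correct": float(corr.mean()), "mean_kl_incorrect": float(inc.mean())}
    if n_downsample is not None and n_downsample < corr.size:
        ds = []
        for idx in permutation_stream(corr.size, n_perm, derive_seed(seed, 11),
                                      "downsample", size=n_downsample):
            ds.append(stats.ks_2samp(corr[idx], inc)[0])
        summary["ks_D_downsampled_mean"] = float(np.mean(ds))
    return table, summary


# ---------------------------------------------------------------------------
# controls


def split_half_control(
    session: Session,
    odor: str,
    scheme: str = "odd-even",
    tau: float = 0.05,
    step: float = 0.025,
    window: tuple[float, float] = (0.0, 1.2),
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """50:50 train/test validation of time reconstruction for one odor.

    Schemes: ``first-second`` (session halves), ``quarters`` (Q1&Q3 vs
    Q2&Q4), ``odd-even``.
    """
    sel = select_trials(
        session.trials, TrialSelection(in_seq=True, correct=True, odors=(odor,))
    ).reset_index(drop=True)
    n = len(sel)
    if n < 4:
        raise ValueError(f"need >= 4 trials for a 50:50 split, got {n}")
    idx = np.arange(n)
    if scheme == "first-second":
        a = idx < n // 2
    elif scheme == "quarters":
        a = (idx * 4 // max(n, 1)) % 2 == 0
    elif scheme == "odd-even":
        a = idx % 2 == 0
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    half_a, half_b = sel[a], sel[~a]
    if half_a.empty or half_b.empty:
        raise ValueError("degenerate split")
    accs, rngs = [], np.random.default_rng(derive_seed(seed, 21))
    chance = []
    for train, test in ((half_a, half_b), (half_b, half_a)):
        counts_tr, _ = _per_trial_counts(session, train, tau, step, window)
        counts_te, _ = _per_trial_counts(session, test, tau, step, window)
        f = counts_tr.mean(axis=0) / tau
        accs += [
            reconstruction_accuracy(decode_posterior(f, counts_te[i].T, tau))
            for i in range(len(test))
        ]
        for _ in range(n_perm // 2):
            perm = rngs.permutation(f.shape[1])
            chance.append(np.nanmean([
                reconstruction_accuracy(decode_posterior(f[:, perm], counts_te[i].T, tau))
                for i in range(len(test))
            ]))
    return {
        "accuracy": float(np.nanmean(accs)),
        "chance_mean": float(np.mean(chance)),
        "chance_p95": float(np.percentile(chance, 95)),
        "train_test_disjoint": set(half_a.trial_id).isdisjoint(half_b.trial_id),
    }


def informative_neuron_filter(
    session: Session,
    odor: str,
    tau: float = 0.05,
    step: float = 0.025,
    window: tuple[float, float] = (0.0, 1.2),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Neurons whose single-neuron time reconstruction beats its own
    time-shuffled null at level ``alpha``. Silent neurons are excluded a
    priori."""
    sel = select_trials(
        session.trials, TrialSelection(in_seq=True, correct=True, odors=(odor,))
    )
    counts, _ = _per_trial_counts(session, sel, tau, step, window)
    n_trials, n_neurons, n_bins = counts.shape
    total = counts.sum(axis=0).astype(float)
    perms = list(permutation_stream(n_bins, n_perm, derive_seed(seed, 31), "time-shuffle"))
    rows = []
    for j in range(n_neurons):
        if total[j].max() == 0:
            continue
        accs = []
        for i in range(n_trials):
            fj = ((total[j] - counts[i, j]) / (n_trials - 1) / tau)[None, :]
            accs.append(reconstruction_accuracy(decode_posterior(fj, counts[i, j][:, None], tau)))
        obs = np.nanmean(accs)
        null = np.empty(n_perm)
        for k, perm in enumerate(perms):
            accs_p = []
            for i in range(n_trials):
                fj = ((total[j] - counts[i, j]) / (n_trials - 1) / tau)[None, perm]
                accs_p.append(reconstruction_accuracy(decode_posterior(fj, counts[i, j][:, None], tau)))
            null[k] = np.nanmean(accs_p)
        p = (1 + np.sum(null >= obs)) / (n_perm + 1)
        rows.append(dict(neuron_id=session.neuron_ids[j], accuracy=obs, p=p))
    table = pd.DataFrame(rows)
    keep = list(table[table.p < alpha].neuron_id) if alpha < 1 else list(table.neuron_id)
    log.info("informative_neuron_filter: %d/%d neurons retained", len(keep), len(table))
    return keep, table
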