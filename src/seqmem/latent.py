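"""Unsupervised 2-D latent embedding of windowed ensemble activity.

Each 250 ms analysis window of a trial is cut into sixteen 100 ms sub-windows
advancing in 10 ms steps; each sub-window's spike counts (10 ms bins, all
neurons) form one input vector. A separate autoencoder is trained per
analysis window, without any trial labels; labels (stimulus, temporal order,
trial outcome) are attached post hoc for k-NN separability and
Mahalanobis cluster-distance analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .nn import MLPAutoencoder
from .permute import derive_seed, permutation_stream
from .session import ODOR_POSITION, Session
from .stats import linear_trend_test
from .windows import window_spike_counts

log = logging.getLogger(__name__)

SUB_WIN = 0.1     # s
SUB_STEP = 0.01   # s
BIN = 0.01        # s
N_SUB = 16        # sub-windows per 250 ms window

#: the four behavior-matched analysis windows: (anchor, start, stop) seconds
DEFAULT_WINDOWS = {
    "entry_0_250": ("poke_in", 0.0, 0.25),
    "entry_250_500": ("poke_in", 0.25, 0.50),
    "exit_m250_0": ("poke_out", -0.25, 0.0),
    "exit_0_250": ("poke_out", 0.0, 0.25),
}


@dataclass
class LatentEmbedding:
    points: np.ndarray       # (n_trials, n_sub, 2)
    trial_ids: list[str]
    window_id: str

    @property
    def centroids(self) -> np.ndarray:
        return self.points.mean(axis=1)


def make_windows(
    session: Session,
    trials: pd.DataFrame,
    anchor: str = "poke_in",
    start: float = 0.0,
    stop: float = 0.25,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Input matrix for one analysis window.

    Returns (X, index): X has one row per (trial, sub-window) —
    shape (n_trials * 16, n_neurons * 10) — and the index frame carries
    trial_id and sub-window number. Trials whose window falls outside the
    recording are dropped with a log entry upstream (the generator keeps all
    trials in span).
    """
    counts = window_spike_counts(session, trials, anchor, (start, stop), BIN)
    n_trials, n_neurons, n_bins = counts.shape
    sub_bins = int(round(SUB_WIN / BIN))
    # (n_trials, n_neurons, n_sub, sub_bins)
    v = sliding_window_view(counts, sub_bins, axis=2)
    n_sub = v.shape[2]
    X = v.transpose(0, 2, 1, 3).reshape(n_trials * n_sub, n_neurons * sub_bins)
    index = pd.DataFrame(
        {
            "trial_id": np.repeat(trials.trial_id.to_numpy(), n_sub),
            "subwindow": np.tile(np.arange(n_sub), n_trials),
        }
    )
    return X.astype(float), index


def train_autoencoder(
    X: np.ndarray,
    seed: int,
    encoder_widths: tuple[int, ...] = (500, 500),
    epochs: int = 200,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 64,
    n_restarts: int = 2,
) -> tuple[MLPAutoencoder, np.ndarray, np.ndarray]:
    """Standardize per feature, train, return (model, mean, sd).

    SGD from an unlucky initialization can stall at the predict-the-mean
    optimum, so ``n_restarts`` seeded initializations are trained and the
    one with the lowest final reconstruction loss kept (deterministic for a
    given seed)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    best: MLPAutoencoder | None = None
    for r in range(max(1, n_restarts)):
        model = MLPAutoencoder(
            X.shape[1], encoder_widths=encoder_widths, lr=lr, momentum=momentum,
            batch_size=batch_size, epochs=epochs, seed=derive_seed(seed, 40, r),
        ).fit(Xs)
        if best is None or model.loss_history[-1] < best.loss_history[-1]:
            best = model
    return best, mu, sd


def embed_window(
    session: Session,
    trials: pd.DataFrame,
    window_id: str = "entry_0_250",
    seed: int = 0,
    **train_kw,
) -> LatentEmbedding:
    anchor, start, stop = DEFAULT_WINDOWS[window_id]
    X, index = make_windows(session, trials, anchor, start, stop)
    model, mu, sd = train_autoencoder(X, seed=derive_seed(seed, 41), **train_kw)
    Z = model.encode((X - mu) / sd)
    n_sub = index.subwindow.max() + 1
    pts = Z.reshape(len(trials), n_sub, 2)
    return LatentEmbedding(pts, list(trials.trial_id), window_id)


# ---------------------------------------------------------------------------
# k-NN separability


def _knn_trial_accuracy(
    train_pts: np.ndarray, train_lab: np.ndarray, test_pts: np.ndarray, test_lab: np.ndarray
) -> float:
    """Per-trial prediction from point-level 2-NN votes.

    Each test point takes the label of its two nearest training points; a
    split vote resolves to the nearer neighbor (equidistant ties to the lower
    training index). A trial's label is the majority over its 16 point votes,
    distance-sum tie-broken.
    """
    n_tr = train_pts.shape[0] * train_pts.shape[1]
    flat_tr = train_pts.reshape(n_tr, 2)
    flat_lab = np.repeat(train_lab, train_pts.shape[1])
    nn = NearestNeighbors(n_neighbors=2).fit(flat_tr)
    correct = 0
    for i in range(test_pts.shape[0]):
        dist, idx = nn.kneighbors(test_pts[i])
        votes = []
        for d, j in zip(dist, idx):
            l0, l1 = flat_lab[j[0]], flat_lab[j[1]]
            votes.append(l0 if (l0 == l1 or d[0] <= d[1]) else l1)
        votes = np.asarray(votes)
        cand, cnt = np.unique(votes, return_counts=True)
        best = cand[cnt == cnt.max()]
        if best.size == 1:
            pred = best[0]
        else:  # majority tie: class with smaller summed vote distance
            sums = [dist[votes == c, 0].sum() for c in best]
            pred = best[int(np.argmin(sums))]
        correct += pred == test_lab[i]
    return correct / test_pts.shape[0]


def knn_separability(
    embedding: LatentEmbedding,
    labels: pd.Series | np.ndarray,
    k: int = 2,
    train_fraction: float = 0.7,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """k-NN (k=2) label separability with a permutation chance band.

    70 % of trials (stratified) train, 30 % test; chance is the 2.5-97.5
    percentile interval of ``n_perm`` label-shuffled accuracies. The result
    is significant when accuracy exceeds the upper bound.
    """
    if k != 2:
        raise ValueError("the separability analysis is defined for k = 2")
    y = np.asarray(labels)
    pts = embedding.points
    rng = np.random.default_rng(derive_seed(seed, 42))

    def stratified_split(y_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = []
        for c in np.unique(y_arr):
            idx = np.flatnonzero(y_arr == c)
            if idx.size < 2:
                raise ValueError(f"label class {c!r} has fewer than 2 trials")
            n_tr = max(1, int(round(train_fraction * idx.size)))
            n_tr = min(n_tr, idx.size - 1)
            tr.append(rng.permutation(idx)[:n_tr])
        tr = np.concatenate(tr)
        te = np.setdiff1d(np.arange(y_arr.size), tr)
        return tr, te

    tr, te = stratified_split(y)
    acc = _knn_trial_accuracy(pts[tr], y[tr], pts[te], y[te])
    null = np.empty(n_perm)
    for i, perm in enumerate(permutation_stream(y.size, n_perm, derive_seed(seed, 43))):
        yp = y[perm]
        null[i] = _knn_trial_accuracy(pts[tr], yp[tr], pts[te], yp[te])
    lo, hi = np.percentile(null, [2.5, 97.5])
    return {
        "accuracy": float(acc),
        "chance_ci": (float(lo), float(hi)),
        "chance_mean": float(null.mean()),
        "significant": bool(acc > hi),
        "n_train": int(tr.size),
        "n_test": int(te.size),
    }


# ---------------------------------------------------------------------------
# cluster lag distances


def _pair_distances(cent: np.ndarray, vi: np.ndarray) -> np.ndarray:
    d = cent[:, None, :] - cent[None, :, :]
    return np.sqrt(np.einsum("ijk,kl,ijl->ij", d, vi, d))


def cluster_lag_distance(
    embedding: LatentEmbedding,
    trials: pd.DataFrame,
    trial_class: str = "inseq",
) -> tuple[pd.DataFrame, dict]:
    """Mahalanobis distance between trial centroids, grouped by lag.

    ``inseq``: correct InSeq trials of odors B-E; lag = odor distance.
    ``outseq``: OutSeq trials; pairs share the same odor, lag = position
    distance. Falls back to Euclidean distance if the pooled covariance is
    singular.
    """
    tid_to_row = {t: i for i, t in enumerate(embedding.trial_ids)}
    cent_all = embedding.centroids
    sub = trials[trials.trial_id.isin(tid_to_row)]
    if trial_class == "inseq":
        sub = sub[sub.in_seq & sub.correct & sub.odor.isin(list("BCDE"))]
    elif trial_class == "outseq":
        sub = sub[~sub.in_seq]
    else:
        raise ValueError(trial_class)
    cent = cent_all[[tid_to_row[t] for t in sub.trial_id]]
    cov = np.cov(cent_all.T)
    try:
        vi = np.linalg.inv(cov)
        metric = "mahalanobis"
    except np.linalg.LinAlgError:
        log.warning("cluster_lag_distance: singular covariance, using Euclidean")
        vi = np.eye(2)
        metric = "euclidean"
    D = _pair_distances(cent, vi)

    rows = []
    recs = sub.reset_index(drop=True)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs.iloc[i], recs.iloc[j]
            if trial_class == "inseq":
                lag = abs(ODOR_POSITION[a.odor] - ODOR_POSITION[b.odor])
            else:
                if a.odor != b.odor:
                    continue
                lag = abs(int(a.position) - int(b.position))
            rows.append(dict(trial_i=a.trial_id, trial_j=b.trial_id,
                             lag=lag, distance=D[i, j]))
    table = pd.DataFrame(rows)
    summary: dict = {"metric": metric}
    if not table.empty and table.lag.nunique() > 1:
        groups = [g.distance.to_numpy() for _, g in table.groupby("lag")]
        f, p = stats.f_oneway(*groups)
        slope, t, pt = linear_trend_test(table.distance, table.lag)
        summary.update(anova_F=float(f), anova_p=float(p),
                       trend_slope=slope, trend_t=t, trend_p=pt,
                       mean_by_lag=table.groupby("lag").distance.mean().to_dict())
    return table, summary
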