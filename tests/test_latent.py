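"""Autoencoder embedding, k-NN separability, and cluster-lag distances."""

import numpy as np
import pandas as pd
import pytest

from seqmem import TrialSelection, select_trials
from seqmem.latent import (
    LatentEmbedding,
    _knn_trial_accuracy,
    cluster_lag_distance,
    knn_separability,
    make_windows,
    train_autoencoder,
)
from seqmem.nn import MLPAutoencoder


class TestMakeWindows:
    def test_sixteen_subwindows_per_trial(self, small_session):
        session, _ = small_session
        sel = session.trials.head(5)
        X, idx = make_windows(session, sel, "poke_in", 0.0, 0.25)
        assert (idx.groupby("trial_id").size() == 16).all()
        assert X.shape == (5 * 16, session.n_neurons * 10)

    def test_input_dim_scales_with_neurons(self, toy_session):
        X, _ = make_windows(toy_session, toy_session.trials, "poke_in", 0.0, 0.25)
        assert X.shape[1] == 2 * 10

    def test_subwindow_counts_conserve_spikes(self, toy_session):
        from seqmem.windows import window_spike_counts

        X, idx = make_windows(toy_session, toy_session.trials, "poke_in", 0.0, 0.25)
        dense = window_spike_counts(toy_session, toy_session.trials, "poke_in",
                                    (0.0, 0.25), 0.01)
        # first sub-window of each trial equals bins [0, 10)
        first = X[idx.subwindow.to_numpy() == 0].reshape(2, 2, 10)
        assert np.array_equal(first, dense[:, :, :10])


class TestAutoencoder:
    def test_recovers_2d_linear_subspace(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 30))
        Z = rng.normal(size=(400, 2))
        X = Z @ basis
        m = MLPAutoencoder(30, encoder_widths=(32, 32), epochs=150, seed=1).fit(X)
        assert m.mse(X) < 0.05 * X.var()

    def test_loss_decreases(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 20))
        m = MLPAutoencoder(20, encoder_widths=(16, 16), epochs=40, seed=3).fit(X)
        assert m.loss_history[-1] <= m.loss_history[0]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 15))
        z1 = MLPAutoencoder(15, encoder_widths=(16, 16), epochs=20, seed=5).fit(X).encode(X)
        z2 = MLPAutoencoder(15, encoder_widths=(16, 16), epochs=20, seed=5).fit(X).encode(X)
        assert np.array_equal(z1, z2)

    def test_bottleneck_must_be_two(self):
        with pytest.raises(ValueError, match="bottleneck"):
            MLPAutoencoder(10, bottleneck=3)

    def test_holdout_mse_within_overfit_guard(self, small_session):
        session, _ = small_session
        sel = select_trials(session.trials,
                            TrialSelection(in_seq=True, correct=True)).reset_index(drop=True)
        X, _ = make_windows(session, sel, "poke_in", 0.25, 0.5)
        rng = np.random.default_rng(6)
        idx = rng.permutation(len(X))
        hold, train = idx[: len(X) // 10], idx[len(X) // 10:]
        model, mu, sd = train_autoencoder(X[train], seed=7,
                                          encoder_widths=(64, 64), epochs=60)
        mse_tr = model.mse((X[train] - mu) / sd)
        mse_ho = model.mse((X[hold] - mu) / sd)
        assert mse_ho <= 2 * mse_tr


class TestKnnSeparability:
    def _embedding(self, pts, ids):
        return LatentEmbedding(pts, ids, "w")

    def test_separated_clouds_classify_perfectly(self):
        rng = np.random.default_rng(0)
        n = 40
        pts = rng.normal(scale=0.1, size=(n, 16, 2))
        labels = np.array(["x"] * (n // 2) + ["y"] * (n // 2))
        pts[labels == "y"] += 50.0
        res = knn_separability(self._embedding(pts, [f"t{i}" for i in range(n)]),
                               labels, n_perm=30, seed=1)
        assert res["accuracy"] == 1.0
        assert res["significant"]

    def test_random_labels_inside_chance_band(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(60, 16, 2))
        labels = rng.choice(["x", "y"], 60)
        res = knn_separability(self._embedding(pts, [f"t{i}" for i in range(60)]),
                               labels, n_perm=100, seed=2)
        lo, hi = res["chance_ci"]
        assert lo - 0.05 <= res["accuracy"] <= hi + 0.05

    def test_engineered_tie_resolved_by_nearer_neighbor(self):
        # training points: class a at distance 1, class b at distance 2 from a
        # single-point "trial"; the 2-NN vote splits, the nearer wins
        train = np.zeros((2, 1, 2))
        train[0, 0] = [1.0, 0.0]   # class a
        train[1, 0] = [-2.0, 0.0]  # class b
        test = np.zeros((1, 1, 2))
        acc = _knn_trial_accuracy(train, np.array(["a", "b"]), test, np.array(["a"]))
        assert acc == 1.0

    def test_tiny_class_raises(self):
        pts = np.zeros((3, 16, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            knn_separability(self._embedding(pts, ["a", "b", "c"]),
                             np.array(["x", "x", "y"]), n_perm=2, seed=0)


class TestClusterLagDistance:
    def test_collinear_centroids_distance_proportional_to_lag(self, small_session):
        session, _ = small_session
        sel = select_trials(session.trials, TrialSelection(
            in_seq=True, correct=True, odors=("B", "C", "D", "E"))).reset_index(drop=True)
        pos = sel.odor.map({"B": 0.0, "C": 1.0, "D": 2.0, "E": 3.0}).to_numpy()
        pts = np.zeros((len(sel), 16, 2))
        pts[:, :, 0] = pos[:, None]
        # perfectly collinear centroids make the pooled covariance singular,
        # exercising the documented Euclidean fallback, under which the
        # distance is exactly proportional to the lag
        emb = LatentEmbedding(pts, list(sel.trial_id), "w")
        table, summary = cluster_lag_distance(emb, session.trials, "inseq")
        assert summary["metric"] == "euclidean"
        means = table.groupby("lag").distance.mean()
        assert means.loc[0] == pytest.approx(0.0, abs=1e-12)
        assert means.loc[2] == pytest.approx(2 * means.loc[1], rel=1e-9)
        assert means.loc[3] == pytest.approx(3 * means.loc[1], rel=1e-9)
        assert summary["trend_p"] < 1e-6

    def test_lag_graded_generator_gives_positive_trend(self):
        from seqmem import GeneratorConfig, simulate_session
        from seqmem.latent import embed_window

        cfg = GeneratorConfig(n_neurons=50, n_sequences=30)
        session, _ = simulate_session(cfg, seed=77, include_lfp=False)
        sel = select_trials(session.trials, TrialSelection(
            in_seq=True, correct=True, odors=("B", "C", "D", "E"))).reset_index(drop=True)
        emb = embed_window(session, sel, "entry_250_500", seed=5,
                           encoder_widths=(128, 128), epochs=80)
        table, summary = cluster_lag_distance(emb, session.trials, "inseq")
        assert summary["trend_slope"] > 0
        assert summary["trend_p"] < 0.05
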