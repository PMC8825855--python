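"""Windowed spike counting: the shared substrate of every decoder.

Counts use half-open bins [t, t + bin): a spike exactly on a bin's right edge
belongs to the next bin. Overlapping bins (bin width > step) are supported for
the Bayesian decoder's sliding-bin rate maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session import Session


def _anchor_times(trials: pd.DataFrame, anchor: str) -> np.ndarray:
    if anchor not in ("poke_in", "poke_out"):
        raise ValueError(f"anchor must be poke_in or poke_out, got {anchor!r}")
    return trials[anchor].to_numpy(dtype=float)


def bin_edges(window: tuple[float, float], bin_s: float, tol: float = 1e-9) -> np.ndarray:
    a, b = window
    n = (b - a) / bin_s
    if abs(n - round(n)) > tol * max(1.0, abs(n)):
        raise ValueError(f"bin {bin_s} does not divide window ({a}, {b})")
    return a + bin_s * np.arange(round(n) + 1)


def window_spike_counts(
    session: Session,
    trials: pd.DataFrame,
    anchor: str = "poke_in",
    window: tuple[float, float] = (0.0, 1.2),
    bin_s: float = 0.01,
) -> np.ndarray:
    """Integer spike counts, shape (n_trials, n_neurons, n_bins).

    Total spikes in [a, b) are conserved across bins by the half-open
    convention.
    """
    edges = bin_edges(window, bin_s)
    anchors = _anchor_times(trials, anchor)
    n_trials, n_bins = anchors.size, edges.size - 1
    counts = np.zeros((n_trials, session.n_neurons, n_bins), dtype=np.int64)
    # absolute edge times per trial: (n_trials, n_bins+1)
    abs_edges = anchors[:, None] + edges[None, :]
    for j, neuron in enumerate(session.neurons):
        idx = np.searchsorted(neuron.spike_times, abs_edges, side="left")
        counts[:, j, :] = np.diff(idx, axis=1)
    return counts


def sliding_spike_counts(
    session: Session,
    trials: pd.DataFrame,
    anchor: str,
    window: tuple[float, float],
    tau: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts in overlapping bins of width ``tau`` advancing by ``step``.

    Returns (counts with shape (n_trials, n_neurons, n_bins), bin start
    offsets relative to the anchor). The last bin ends at or before the
    window's right edge.
    """
    a, b = window
    starts = []
    s = a
    while s + tau <= b + 1e-9:
        starts.append(s)
        s += step
    starts = np.asarray(starts)
    anchors = _anchor_times(trials, anchor)
    n_trials, n_bins = anchors.size, starts.size
    counts = np.zeros((n_trials, session.n_neurons, n_bins), dtype=np.int64)
    lo = anchors[:, None] + starts[None, :]
    hi = lo + tau
    for j, neuron in enumerate(session.neurons):
        t = neuron.spike_times
        counts[:, j, :] = np.searchsorted(t, hi, side="left") - np.searchsorted(t, lo, side="left")
    return counts, starts
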