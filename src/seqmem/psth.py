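"""Peri-stimulus time histograms, peak-latency sorting, and trial-wise PSTH
correlation.

PSTHs are built from 1 ms bins, Gaussian-smoothed (kernel truncated at
+/- 4 sd, reflected boundaries), averaged across trials, and peak-normalized
per neuron. Neurons silent on every included trial are dropped and logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .session import Session
from .windows import window_spike_counts

log = logging.getLogger(__name__)


@dataclass
class Psth:
    rates: np.ndarray        # (n_neurons, n_bins) normalized mean rate
    neuron_ids: list[str]
    bin_s: float
    smooth_sd_ms: float
    anchor: str
    window: tuple[float, float]
    excluded: list[str]      # neurons silent on all included trials

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + self.bin_s * (np.arange(self.rates.shape[1]) + 0.5)


def _smooth_rows(x: np.ndarray, sd_bins: float) -> np.ndarray:
    if sd_bins <= 0:
        return x
    return gaussian_filter1d(x, sd_bins, axis=-1, mode="reflect", truncate=4.0)


def build_psth(
    session: Session,
    trials: pd.DataFrame,
    anchor: str = "poke_in",
    window: tuple[float, float] = (0.0, 1.2),
    smooth_sd_ms: float = 150.0,
    bin_ms: float = 1.0,
) -> Psth:
    """Trial-averaged, smoothed, peak-normalized firing-rate matrix."""
    if trials.empty:
        raise ValueError("build_psth requires a nonempty trial selection")
    bin_s = bin_ms / 1000.0
    counts = window_spike_counts(session, trials, anchor, window, bin_s)
    mean_rate = counts.mean(axis=0) / bin_s  # (n_neurons, n_bins)
    smoothed = _smooth_rows(mean_rate, smooth_sd_ms / bin_ms)
    active = counts.sum(axis=(0, 2)) > 0
    excluded = [nid for nid, a in zip(session.neuron_ids, active) if not a]
    if excluded:
        log.info("build_psth: dropping %d silent neurons", len(excluded))
    rates = smoothed[active]
    peaks = rates.max(axis=1, keepdims=True)
    rates = np.divide(rates, peaks, out=np.zeros_like(rates), where=peaks > 0)
    ids = [nid for nid, a in zip(session.neuron_ids, active) if a]
    return Psth(rates, ids, bin_s, smooth_sd_ms, anchor, window, excluded)


def sort_by_peak(psth: Psth) -> list[str]:
    """Neuron ids in ascending order of peak latency; ties broken by id.

    The peak is the argmax of the smoothed normalized row; the first bin wins
    among equal maxima.
    """
    peak_bin = psth.rates.argmax(axis=1)
    order = sorted(range(len(psth.neuron_ids)), key=lambda i: (peak_bin[i], psth.neuron_ids[i]))
    return [psth.neuron_ids[i] for i in order]


def trial_psths(
    session: Session,
    trials: pd.DataFrame,
    anchor: str = "poke_in",
    window: tuple[float, float] = (0.0, 1.2),
    smooth_sd_ms: float = 150.0,
    bin_ms: float = 1.0,
) -> np.ndarray:
    """Per-trial smoothed, peak-normalized rate tensor
    (n_trials, n_neurons, n_bins), neurons in canonical session order."""
    bin_s = bin_ms / 1000.0
    counts = window_spike_counts(session, trials, anchor, window, bin_s)
    rates = _smooth_rows(counts / bin_s, smooth_sd_ms / bin_ms)
    peaks = rates.max(axis=2, keepdims=True)
    return np.divide(rates, peaks, out=np.zeros_like(rates), where=peaks > 0)


def psth_similarity(
    session: Session,
    trials: pd.DataFrame,
    n_per_odor: int = 14,
    odors: tuple[str, ...] = ("A", "B", "C", "D"),
    anchor: str = "poke_in",
    window: tuple[float, float] = (0.0, 1.2),
    smooth_sd_ms: float = 150.0,
    bin_ms: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Pearson correlations between all pairs of trial-specific PSTHs.

    Takes the first ``n_per_odor`` trials per odor from ``trials`` (caller
    pre-filters to correct InSeq), vectorizes each trial's smoothed normalized
    PSTH in canonical neuron order, correlates every pair, groups pairs into
    same-odor vs different-odor classes, and summarizes with a one-way ANOVA
    plus Dunnett contrasts of each different-odor class against the pooled
    same-odor class.
    """
    chosen = []
    for od in odors:
        sub = trials[trials.odor == od]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 trials for odor {od}")
        chosen.append(sub.head(n_per_odor))
    sel = pd.concat(chosen)
    vec = trial_psths(session, sel, anchor, window, smooth_sd_ms, bin_ms).reshape(len(sel), -1)
    odor_lab = sel.odor.to_numpy()
    tid = sel.trial_id.to_numpy()

    rows = []
    for i, j in itertools.combinations(range(len(sel)), 2):
        vi, vj = vec[i], vec[j]
        if vi.std() == 0 or vj.std() == 0:
            log.info("psth_similarity: skipping constant PSTH pair (%s, %s)", tid[i], tid[j])
            continue
        r = float(np.corrcoef(vi, vj)[0, 1])
        rows.append(dict(trial_i=tid[i], trial_j=tid[j], odor_i=odor_lab[i],
                         odor_j=odor_lab[j], r=r,
                         same_odor=odor_lab[i] == odor_lab[j]))
    table = pd.DataFrame(rows)

    same = table[table.same_odor].r.to_numpy()
    diff_groups = {
        f"{a}v{b}": table[(~table.same_odor)
                          & (table.odor_i.isin((a, b))) & (table.odor_j.isin((a, b)))].r.to_numpy()
        for a, b in itertools.combinations(odors, 2)
    }
    diff_groups = {k: v for k, v in diff_groups.items() if v.size > 1}
    groups = [same] + list(diff_groups.values())
    f, p = stats.f_oneway(*groups)
    dunnett = stats.dunnett(*diff_groups.values(), control=same)
    summary = {
        "mean_same": float(same.mean()),
        "mean_diff": float(table[~table.same_odor].r.mean()),
        "anova_F": float(f),
        "anova_p": float(p),
        "dunnett_p": dict(zip(diff_groups.keys(), (float(x) for x in dunnett.pvalue))),
    }
    return table, summary
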