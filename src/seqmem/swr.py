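"""Sharp-wave-ripple detection and trial-exclusion control.

A SWR is the temporal overlap of a sharp-wave event (high-passed > 4 Hz) on
the stratum-radiatum tetrode and a ripple event (band-passed 150-250 Hz) on
the pyramidal-layer tetrode. Band events are supra-threshold excursions of
the analytic-signal envelope (z-scored against the whole-session mean/SD of
that channel's envelope); excursions within 15 ms of each other merge into
one event. SWR boundaries take the union of the contributing sharp-wave and
ripple intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .session import LfpChannel, Session

log = logging.getLogger(__name__)


@dataclass
class SwrEvent:
    start: float
    end: float
    sharpwave_tetrode: str
    ripple_tetrode: str
    peak_z: float


def merge_intervals(intervals: list[tuple[float, float]], gap: float) -> list[tuple[float, float]]:
    """Merge intervals separated by less than ``gap`` seconds. Idempotent."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a - out[-1][1] < gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(iv) for iv in out]


def band_envelope_z(
    channel: LfpChannel, band: tuple[float, float] | float, order: int = 3
) -> np.ndarray:
    """Z-scored analytic envelope of the band-filtered trace.

    ``band`` is (lo, hi) for a bandpass or a scalar cutoff for a high-pass.
    """
    x = channel.samples
    if x.std() == 0:
        raise ValueError(f"tetrode {channel.tetrode_id}: constant signal")
    if np.isscalar(band):
        sos = signal.butter(order, band, btype="highpass", fs=channel.fs, output="sos")
    else:
        sos = signal.butter(order, band, btype="bandpass", fs=channel.fs, output="sos")
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, x)))
    return (env - env.mean()) / env.std()


def detect_band_events(
    channel: LfpChannel,
    band: tuple[float, float] | float,
    threshold_sd: float = 3.0,
    merge_gap: float = 0.015,
) -> list[tuple[float, float]]:
    """Supra-threshold envelope excursions, gap-merged, as (start, end) s."""
    if channel.samples.size < 2 * channel.fs:
        raise ValueError("need at least 2 s of signal")
    z = band_envelope_z(channel, band)
    above = z > threshold_sd
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    ivs = [(channel.t0 + s / channel.fs, channel.t0 + e / channel.fs)
           for s, e in zip(starts, ends)]
    return merge_intervals(ivs, merge_gap)


def detect_swr(
    session: Session,
    threshold_sd: float = 3.0,
    merge_gap: float = 0.015,
    ripple_band: tuple[float, float] = (150.0, 250.0),
    sharpwave_cutoff: float = 4.0,
) -> list[SwrEvent]:
    """Overlap-joined sharp-wave + ripple events with union boundaries."""
    rip_tet = session.meta.get("ripple_tetrode")
    sw_tet = session.meta.get("sharpwave_tetrode")
    if rip_tet is None or sw_tet is None:
        raise ValueError("session must designate ripple_tetrode and sharpwave_tetrode")
    rip_ch = session.lfp_channel(rip_tet)
    sw_ch = session.lfp_channel(sw_tet)
    ripples = detect_band_events(rip_ch, ripple_band, threshold_sd, merge_gap)
    sharps = detect_band_events(sw_ch, sharpwave_cutoff, threshold_sd, merge_gap)
    z_rip = band_envelope_z(rip_ch, ripple_band)
    events = []
    for r0, r1 in ripples:
        for s0, s1 in sharps:
            if r0 < s1 and s0 < r1:  # temporal overlap
                a, b = min(r0, s0), max(r1, s1)
                i0 = max(0, int((r0 - rip_ch.t0) * rip_ch.fs))
                i1 = min(z_rip.size, int((r1 - rip_ch.t0) * rip_ch.fs) + 1)
                events.append(SwrEvent(a, b, sw_tet, rip_tet,
                                       float(z_rip[i0:i1].max())))
                break
    merged = merge_intervals([(e.start, e.end) for e in events], 0.0)
    out = []
    for a, b in merged:
        peak = max(e.peak_z for e in events if e.start >= a - 1e-9 and e.end <= b + 1e-9)
        out.append(SwrEvent(a, b, sw_tet, rip_tet, peak))
    log.info("detect_swr: %d events", len(out))
    return out


def exclude_swr_trials(
    trials: pd.DataFrame,
    events: list[SwrEvent] | list[tuple[float, float]],
    flank: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Remove trials whose odor period (or its +/- ``flank`` windows)
    intersects any event; reports counts per window."""
    ivs = [(e.start, e.end) if isinstance(e, SwrEvent) else tuple(e) for e in events]
    report = {"odor_period": 0, "pre_flank": 0, "post_flank": 0}
    drop = []
    for _, tr in trials.iterrows():
        wins = {
            "odor_period": (tr.poke_in, tr.poke_out),
            "pre_flank": (tr.poke_in - flank, tr.poke_in),
            "post_flank": (tr.poke_out, tr.poke_out + flank),
        }
        hit = False
        for name, (a, b) in wins.items():
            if any(a < e1 and e0 < b for e0, e1 in ivs):
                report[name] += 1
                hit = True
        if hit:
            drop.append(tr.trial_id)
    out = trials[~trials.trial_id.isin(drop)].copy()
    report["n_removed"] = len(drop)
    log.info("exclude_swr_trials: removed %d/%d trials", len(drop), len(trials))
    return out, report
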