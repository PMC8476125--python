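"""Candidate-event detection: sharp-wave ripples and high multiunit activity.

SWR detection follows the consensus-trace recipe: each LFP is band-pass
filtered in the ripple band (150-250 Hz, zero-phase FIR), squared, summed
across tetrodes, smoothed with a 4 ms Gaussian, square-rooted, and z-scored
over the whole session.  Candidate times require the z-score to exceed 2 for
at least 15 ms while the animal moves slower than 4 cm/s; detections are
then extended on both sides until the trace returns to its session mean, and
overlapping extended intervals are merged.

High-MUA detection applies the same threshold/persistence/speed gating
directly to a z-scored multiunit rate trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import filtfilt, firwin

__all__ = ["EventList", "detect_swr", "detect_high_mua", "filter_events", "ripple_band_power"]

RIPPLE_BAND = (150.0, 250.0)
FIR_ORDER = 101


@dataclass
class EventList:
    """Sorted, non-overlapping candidate intervals."""

    intervals: list[tuple[float, float]]
    kind: str
    peak_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_tetrodes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals)
        for s, e in ivals:
            if e <= s:
                raise ValueError("event end must exceed start")
        for (a, b), (c, _) in zip(ivals[:-1], ivals[1:]):
            if c < b:
                raise ValueError("event intervals must not overlap")
        self.intervals = ivals
        if len(self.peak_z) == 0:
            self.peak_z = np.full(len(ivals), np.nan)
        if len(self.n_tetrodes) == 0:
            self.n_tetrodes = np.zeros(len(ivals), dtype=int)

    def __len__(self) -> int:
        return len(self.intervals)


def ripple_band_power(
    traces: np.ndarray, fs: float, smooth_sd: float = 0.004
) -> np.ndarray:
    """Session consensus ripple power: bandpass, square, sum, smooth, sqrt."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < traces.shape[1]:
        raise ValueError("traces must be (n_samples, n_tetrodes)")
    taps = firwin(
        FIR_ORDER, RIPPLE_BAND, pass_zero=False, fs=fs, window="hamming"
    )
    filtered = filtfilt(taps, [1.0], traces, axis=0)
    power = (filtered**2).sum(axis=1)
    power = gaussian_filter1d(power, smooth_sd * fs, mode="nearest")
    return np.sqrt(power)


def _threshold_events(
    z: np.ndarray,
    fs: float,
    speed: np.ndarray | None,
    z_thresh: float,
    min_dur: float,
    speed_max: float,
    extend: bool,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Shared threshold/persistence/speed-gate/extension logic."""
    above = z >= z_thresh
    if speed is not None:
        above &= np.asarray(speed) < speed_max
    # contiguous runs of `above`
    padded = np.concatenate([[False], above, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    min_samples = int(np.ceil(min_dur * fs))
    raw = [(s, e) for s, e in zip(starts, ends) if (e - s) >= min_samples]

    intervals, peaks = [], []
    below_mean = z <= 0.0
    for s, e in raw:
        if extend:
            while s > 0 and not below_mean[s - 1]:
                s -= 1
            while e < len(z) and not below_mean[e]:
                e += 1
        if intervals and s / fs <= intervals[-1][1]:
            prev_s, _ = intervals[-1]
            intervals[-1] = (prev_s, e / fs)
            peaks[-1] = max(peaks[-1], float(z[s:e].max()))
        else:
            intervals.append((s / fs, e / fs))
            peaks.append(float(z[s:e].max()))
    return intervals, np.asarray(peaks)


def detect_swr(
    lfps: np.ndarray,
    fs: float,
    speed: np.ndarray | None = None,
    z_thresh: float = 2.0,
    min_dur: float = 0.015,
    speed_max: float = 4.0,
    smooth_sd: float = 0.004,
) -> EventList:
    """Detect sharp-wave ripples from multi-tetrode LFP.

    ``lfps`` is (n_samples, n_tetrodes) at sampling rate ``fs`` (Hz);
    ``speed`` (cm/s), if given, must be sampled on the same clock.
    """
    lfps = np.atleast_2d(np.asarray(lfps, dtype=float))
    if lfps.shape[1] < 1:
        raise ValueError("need at least one LFP trace")
    if speed is not None and len(speed) != lfps.shape[0]:
        raise ValueError("speed series must match the LFP length")
    power = ripple_band_power(lfps, fs, smooth_sd)
    z = (power - power.mean()) / power.std()
    intervals, peaks = _threshold_events(
        z, fs, speed, z_thresh, min_dur, speed_max, extend=True
    )
    return EventList(intervals=intervals, kind="swr", peak_z=peaks)


def detect_high_mua(
    mua_rate: np.ndarray,
    fs: float,
    speed: np.ndarray | None = None,
    z_thresh: float = 2.0,
    min_dur: float = 0.015,
    speed_max: float = 4.0,
) -> EventList:
    """Detect periods of high z-scored multiunit population rate."""
    mua_rate = np.asarray(mua_rate, dtype=float)
    if speed is not None and len(speed) != len(mua_rate):
        raise ValueError("speed series must match the rate length")
    sd = mua_rate.std()
    if sd == 0:
        return EventList(intervals=[], kind="mua")
    z = (mua_rate - mua_rate.mean()) / sd
    intervals, peaks = _threshold_events(
        z, fs, speed, z_thresh, min_dur, speed_max, extend=True
    )
    return EventList(intervals=intervals, kind="mua", peak_z=peaks)


def filter_events(events: EventList, spike_times_per_tetrode: list[np.ndarray], min_tetrodes: int = 2) -> EventList:
    """Keep only events with spikes from at least ``min_tetrodes`` tetrodes."""
    kept, kept_z, kept_n = [], [], []
    for (s, e), z in zip(events.intervals, events.peak_z):
        n_active = sum(
            1
            for st in spike_times_per_tetrode
            if np.any((np.asarray(st) >= s) & (np.asarray(st) < e))
        )
        if n_active >= min_tetrodes:
            kept.append((s, e))
            kept_z.append(z)
            kept_n.append(n_active)
    return EventList(
        intervals=kept,
        kind=events.kind,
        peak_z=np.asarray(kept_z),
        n_tetrodes=np.asarray(kept_n, dtype=int),
    )
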