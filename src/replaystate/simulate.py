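"""Synthetic data generators for validating the replay decoder.

These emulate the simulation study used to characterize the switching
state-space model: a bank of Gaussian place fields on a 180 cm linear track
(19 cells, SD 6 cm, 15 Hz peak, peaks every 10 cm), inhomogeneous-Poisson
encoding runs, a constructed spiking sequence exhibiting the three movement
dynamics (stationary / continuous / fragmented), constant-speed test
trajectories, Gaussian waveform marks for the clusterless pathway, and
ripple-bearing LFP for exercising the event detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlaceFieldBank",
    "SpikeTrainSet",
    "MarkedSpikeSet",
    "simulate_encoding_run",
    "make_test_sequence",
    "make_constant_speed_sweep",
    "attach_marks",
    "default_mark_means",
    "simulate_lfp_with_ripples",
]

TIME_STEP = 0.002  # 2 ms decoding resolution (s)


@dataclass
class PlaceFieldBank:
    """Gaussian place fields on a linear track.

    Defaults reproduce the simulation study: 19 cells with peaks every 10 cm
    on a 180 cm track, field SD 6 cm (variance 36 cm^2), 15 Hz peak rate.
    """

    peak_locations: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 181.0, 10.0)
    )
    field_sd: float = 6.0
    peak_rate: float = 15.0
    track_length: float = 180.0

    def __post_init__(self) -> None:
        self.peak_locations = np.asarray(self.peak_locations, dtype=float)
        if self.field_sd <= 0:
            raise ValueError("field_sd must be positive")
        if self.peak_rate < 0:
            raise ValueError("peak_rate must be non-negative")
        if np.any(self.peak_locations < 0) or np.any(self.peak_locations > self.track_length):
            raise ValueError("place-field peaks must lie on the track")

    @property
    def n_cells(self) -> int:
        return len(self.peak_locations)

    def rates(self, position: np.ndarray) -> np.ndarray:
        """Firing rate (Hz) of every cell at the given positions.

        Returns array of shape ``(len(position), n_cells)``.
        """
        position = np.atleast_1d(np.asarray(position, dtype=float))
        z = (position[:, None] - self.peak_locations[None, :]) / self.field_sd
        return self.peak_rate * np.exp(-0.5 * z**2)


@dataclass
class SpikeTrainSet:
    """Spike times (s) per putative cell, on a common clock."""

    spike_times: list[np.ndarray]
    duration: float
    sampling_step: float = TIME_STEP
    cell_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.spike_times = [np.sort(np.asarray(st, dtype=float)) for st in self.spike_times]
        for st in self.spike_times:
            if len(st) and st[0] < 0:
                raise ValueError("negative spike time")
        if self.cell_ids is None:
            self.cell_ids = np.arange(len(self.spike_times))

    @property
    def n_cells(self) -> int:
        return len(self.spike_times)

    def counts(self, time_bins: np.ndarray | None = None) -> np.ndarray:
        """Spike counts per (time bin, cell).  ``time_bins`` are bin edges."""
        if time_bins is None:
            n = int(round(self.duration / self.sampling_step))
            time_bins = np.arange(n + 1) * self.sampling_step
        out = np.zeros((len(time_bins) - 1, self.n_cells), dtype=int)
        for i, st in enumerate(self.spike_times):
            out[:, i], _ = np.histogram(st, bins=time_bins)
        return out


@dataclass
class MarkedSpikeSet:
    """Unsorted spikes per tetrode with 4-channel peak-amplitude marks (uV)."""

    spike_times: list[np.ndarray]
    marks: list[np.ndarray]
    duration: float
    tetrode_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.spike_times) != len(self.marks):
            raise ValueError("spike_times and marks must align per tetrode")
        times, marks = [], []
        for st, m in zip(self.spike_times, self.marks):
            st = np.asarray(st, dtype=float)
            m = np.atleast_2d(np.asarray(m, dtype=float))
            if len(st) and m.shape != (len(st), 4):
                raise ValueError("marks must be (n_spikes, 4) per tetrode")
            if len(st) == 0:
                m = np.zeros((0, 4))
            order = np.argsort(st)
            times.append(st[order])
            marks.append(m[order])
        self.spike_times = times
        self.marks = marks
        if self.tetrode_ids is None:
            self.tetrode_ids = np.arange(len(self.spike_times))

    @property
    def n_tetrodes(self) -> int:
        return len(self.spike_times)


def _traversal_positions(
    track_length: float, n_traversals: int, dt: float, speed: float
) -> np.ndarray:
    """Back-and-forth end-to-end sweeps of the track at constant speed."""
    per_leg = track_length / speed
    t_total = n_traversals * per_leg
    t = np.arange(0.0, t_total, dt)
    phase = (t * speed) % (2 * track_length)
    return np.where(phase <= track_length, phase, 2 * track_length - phase), t


def simulate_encoding_run(
    bank: PlaceFieldBank,
    n_traversals: int = 15,
    dt: float = TIME_STEP,
    speed: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SpikeTrainSet]:
    """Inhomogeneous-Poisson encoding data from track traversals.

    The animal sweeps the track end-to-end ``n_traversals`` times at constant
    ``speed``; per-cell spike counts in each ``dt`` bin are Poisson with mean
    ``rate(x_t) * dt``.

    Returns ``(time, position, spikes)``.
    """
    if dt <= 0 or speed <= 0:
        raise ValueError("dt and speed must be positive")
    if n_traversals < 1:
        raise ValueError("n_traversals must be >= 1")
    rng = np.random.default_rng(seed)
    position, t = _traversal_positions(bank.track_length, n_traversals, dt, speed)
    lam = bank.rates(position) * dt
    counts = rng.poisson(lam)
    spike_times = []
    for i in range(bank.n_cells):
        idx = np.nonzero(counts[:, i])[0]
        st = np.repeat(t[idx], counts[idx, i]) + 0.5 * dt
        spike_times.append(st)
    duration = t[-1] + dt if len(t) else 0.0
    return t, position, SpikeTrainSet(spike_times=spike_times, duration=duration, sampling_step=dt)


def make_test_sequence(
    bank: PlaceFieldBank,
    segment_spec: list[tuple[str, float]],
    seed: int = 0,
    dt: float = TIME_STEP,
    stationary_cell: int | None = None,
) -> tuple[SpikeTrainSet, np.ndarray]:
    """Construct a spike raster exhibiting the requested movement dynamics.

    ``segment_spec`` is a list of ``(kind, duration_ms)`` with kind one of
    ``stationary`` (one cell fires repeatedly — every 2 ms step — at a fixed
    location), ``continuous`` (cells fire in spatial order, sweeping the
    full track), or ``fragmented`` (cells fire in random spatial order, one
    per step).  Durations must be positive multiples of the 2 ms step.  The
    stationary cell defaults to the cell whose field peaks a quarter of the
    way along the track (an interior field, clear of edge effects).

    Returns ``(spikes, latent_position)`` where ``latent_position`` gives the
    position represented in each 2 ms bin (NaN during fragmented segments).
    """
    rng = np.random.default_rng(seed)
    order = np.argsort(bank.peak_locations)
    if stationary_cell is None:
        stationary_cell = int(order[round(0.25 * (bank.n_cells - 1))])
    step_ms = dt * 1000.0
    bins_per_seg = []
    for kind, dur in segment_spec:
        if kind not in ("stationary", "continuous", "fragmented"):
            raise ValueError(f"unknown segment kind: {kind!r}")
        n = dur / step_ms
        if dur <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("durations must be positive multiples of the time step")
        bins_per_seg.append(int(round(n)))

    n_bins = sum(bins_per_seg)
    counts = np.zeros((n_bins, bank.n_cells), dtype=int)
    latent = np.full(n_bins, np.nan)
    start = 0
    for (kind, _), nb in zip(segment_spec, bins_per_seg):
        sl = slice(start, start + nb)
        if kind == "stationary":
            counts[sl, stationary_cell] = 1
            latent[sl] = bank.peak_locations[stationary_cell]
        elif kind == "continuous":
            # trajectory sweeps the track; the nearest-peak cell fires each
            # step, so cells fire short sequential bursts in spatial order
            frac = (np.arange(nb) + 0.5) / nb
            latent[sl] = (
                bank.peak_locations[order[0]]
                + frac * (bank.peak_locations[order[-1]] - bank.peak_locations[order[0]])
            )
            nearest = np.argmin(
                np.abs(latent[sl][:, None] - bank.peak_locations[None, :]), axis=1
            )
            counts[np.arange(start, start + nb), nearest] = 1
        else:  # fragmented
            cells = rng.integers(0, bank.n_cells, size=nb)
            counts[np.arange(start, start + nb), cells] = 1
        start += nb

    t_centers = (np.arange(n_bins) + 0.5) * dt
    spike_times = [np.repeat(t_centers, counts[:, i]) for i in range(bank.n_cells)]
    spikes = SpikeTrainSet(
        spike_times=spike_times, duration=n_bins * dt, sampling_step=dt
    )
    return spikes, latent


def make_constant_speed_sweep(
    bank: PlaceFieldBank,
    speeds: np.ndarray,
    dt: float = TIME_STEP,
    dwell_halfwidth: float | None = None,
) -> list[SpikeTrainSet]:
    """One test sequence per speed: a linear traversal at constant speed in
    which each cell spikes while the trajectory passes through its
    place-field peak.

    A cell fires one spike in every ``dt`` bin during which the trajectory
    lies within ``dwell_halfwidth`` cm of its peak; the default is half the
    field spacing, so the firing windows tile the track and exactly one cell
    fires at any moment.  Slow traversals thus produce sustained firing from
    one cell at a time while fast traversals degenerate to a single spike
    per cell at its crossing time.
    """
    speeds = np.atleast_1d(np.asarray(speeds, dtype=float))
    if np.any(speeds <= 0):
        raise ValueError("speeds must be positive")
    if dwell_halfwidth is None:
        peaks = np.sort(bank.peak_locations)
        spacing = np.median(np.diff(peaks)) if len(peaks) > 1 else bank.field_sd
        dwell_halfwidth = 0.5 * float(spacing)
    out = []
    for v in speeds:
        duration = bank.track_length / v
        n_bins = max(1, int(np.ceil(duration / dt - 1e-12)))
        centers = (np.arange(n_bins) + 0.5) * dt
        spike_times = []
        for peak in bank.peak_locations:
            t_in = (peak - dwell_halfwidth) / v
            t_out = (peak + dwell_halfwidth) / v
            st = centers[(centers >= t_in) & (centers <= t_out)]
            if len(st) == 0:  # crossing faster than one time bin
                st = np.array([min(max(peak / v, 0.5 * dt), (n_bins - 0.5) * dt)])
            spike_times.append(st)
        out.append(
            SpikeTrainSet(spike_times=spike_times, duration=n_bins * dt, sampling_step=dt)
        )
    return out


def default_mark_means(n_cells: int, base: float = 100.0, spacing: float = 80.0) -> np.ndarray:
    """Cluster mark means on a 4D grid, >= 3 bandwidths (24 uV) apart."""
    means = np.zeros((n_cells, 4))
    for i in range(n_cells):
        digits = np.array([(i // 3**d) % 3 for d in range(4)])
        means[i] = base + spacing * digits
    return means


def attach_marks(
    spikes: SpikeTrainSet,
    cluster_mark_means: np.ndarray,
    mark_sd: float = 10.0,
    seed: int = 0,
    cell_to_tetrode: np.ndarray | None = None,
) -> MarkedSpikeSet:
    """Give each spike a Gaussian waveform mark around its cell's mean and
    discard cell identity, producing clusterless (multiunit) data.

    By default all cells land on a single tetrode; ``cell_to_tetrode`` can
    split them.
    """
    if mark_sd <= 0:
        raise ValueError("mark_sd must be positive")
    cluster_mark_means = np.atleast_2d(np.asarray(cluster_mark_means, dtype=float))
    if cluster_mark_means.shape != (spikes.n_cells, 4):
        raise ValueError("need one 4-vector mark mean per cell")
    if cell_to_tetrode is None:
        cell_to_tetrode = np.zeros(spikes.n_cells, dtype=int)
    cell_to_tetrode = np.asarray(cell_to_tetrode, dtype=int)
    rng = np.random.default_rng(seed)
    n_tet = int(cell_to_tetrode.max()) + 1
    times = [[] for _ in range(n_tet)]
    marks = [[] for _ in range(n_tet)]
    for c in range(spikes.n_cells):
        st = spikes.spike_times[c]
        m = cluster_mark_means[c] + mark_sd * rng.standard_normal((len(st), 4))
        times[cell_to_tetrode[c]].append(st)
        marks[cell_to_tetrode[c]].append(m)
    out_t, out_m = [], []
    for tet in range(n_tet):
        if times[tet]:
            t = np.concatenate(times[tet])
            m = np.vstack(marks[tet]) if len(t) else np.zeros((0, 4))
        else:
            t, m = np.zeros(0), np.zeros((0, 4))
        out_t.append(t)
        out_m.append(m)
    return MarkedSpikeSet(spike_times=out_t, marks=out_m, duration=spikes.duration)


def simulate_lfp_with_ripples(
    duration: float,
    ripple_intervals: list[tuple[float, float]],
    ripple_freq: float = 200.0,
    fs: float = 1500.0,
    n_tetrodes: int = 4,
    noise_sd: float = 1.0,
    ripple_amplitude: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Broadband-noise LFP with amplitude-modulated ripple-band bursts.

    Bursts are Hann-windowed sinusoids at ``ripple_freq`` (must lie in the
    150-250 Hz ripple band) added to every trace in the stated intervals.

    Returns ``(time, traces)`` with traces of shape ``(n_samples, n_tetrodes)``.
    """
    if not 150.0 <= ripple_freq <= 250.0:
        raise ValueError("ripple_freq must lie in the 150-250 Hz band")
    ivals = sorted(ripple_intervals)
    for (s0, e0), (s1, _) in zip(ivals[:-1], ivals[1:]):
        if s1 < e0:
            raise ValueError("ripple intervals must not overlap")
    for s, e in ivals:
        if s < 0 or e > duration or e <= s:
            raise ValueError("ripple intervals must lie within the duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    traces = noise_sd * rng.standard_normal((n, n_tetrodes))
    for s, e in ivals:
        sel = (t >= s) & (t < e)
        m = sel.sum()
        if m == 0:
            continue
        window = np.hanning(m)
        burst = ripple_amplitude * noise_sd * window * np.sin(
            2 * np.pi * ripple_freq * (t[sel] - s)
        )
        traces[sel] += burst[:, None]
    return t, traces
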