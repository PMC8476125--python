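"""Per-time-bin observation log-likelihoods over the position grid.

Both likelihood models are Poisson in 2 ms bins and are evaluated in log
space up to an additive per-bin constant (constants drop out when each
filter slice is renormalized):

* sorted:      ``sum_i  N_ki log(lambda_i(x) dt) - lambda_i(x) dt``
* clusterless: ``sum_i [ sum_j log(lambda_i(m_kj | x) dt) - Lambda_i(x) dt ]``

Bins with no spikes still carry the ``-lambda dt`` terms, so silence is
informative (it favors positions with low expected rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import ClusterlessEncodingModel, SortedEncodingModel
from .simulate import MarkedSpikeSet, SpikeTrainSet
from .track import PositionGrid

__all__ = ["LikelihoodMatrix", "sorted_likelihood", "clusterless_likelihood", "make_time_bins"]


@dataclass
class LikelihoodMatrix:
    """Log-likelihood (time bins x grid bins), up to per-bin constants."""

    log_likelihood: np.ndarray
    time_bin_edges: np.ndarray

    @property
    def n_time(self) -> int:
        return self.log_likelihood.shape[0]

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.time_bin_edges)))


def make_time_bins(duration: float, bin_width: float = 0.002, start: float = 0.0) -> np.ndarray:
    """Uniform time-bin edges covering ``[start, start + duration]``."""
    n = max(1, int(round(duration / bin_width)))
    return start + np.arange(n + 1) * bin_width


def _check_grid(model_centers: np.ndarray, grid: PositionGrid) -> None:
    if model_centers is not None and (
        len(model_centers) != grid.n_bins
        or not np.allclose(model_centers, grid.bin_centers)
    ):
        raise ValueError("encoding model was fit on a different grid")


def sorted_likelihood(
    model: SortedEncodingModel,
    spikes: SpikeTrainSet,
    time_bins: np.ndarray,
    grid: PositionGrid,
) -> LikelihoodMatrix:
    """Poisson log-likelihood from sorted spike trains."""
    _check_grid(model.grid_bin_centers, grid)
    time_bins = np.asarray(time_bins, dtype=float)
    dt = float(np.median(np.diff(time_bins)))
    counts = np.zeros((len(time_bins) - 1, model.n_cells), dtype=int)
    n_dropped = 0
    for i, st in enumerate(spikes.spike_times):
        inside = (st >= time_bins[0]) & (st <= time_bins[-1])
        n_dropped += int((~inside).sum())
        counts[:, i], _ = np.histogram(st[inside], bins=time_bins)
    if n_dropped:
        warnings.warn(f"{n_dropped} spikes outside the time range were dropped")

    log_rate_dt = np.log(model.rate_map * dt)        # (n_cells, n_bins)
    rate_dt_sum = (model.rate_map * dt).sum(axis=0)  # (n_bins,)
    ll = counts @ log_rate_dt - rate_dt_sum[None, :]
    return LikelihoodMatrix(log_likelihood=ll, time_bin_edges=time_bins)


def clusterless_likelihood(
    model: ClusterlessEncodingModel,
    marks: MarkedSpikeSet,
    time_bins: np.ndarray,
    grid: PositionGrid,
) -> LikelihoodMatrix:
    """Marked-point-process log-likelihood from unsorted spikes with marks."""
    _check_grid(model.grid_bin_centers, grid)
    time_bins = np.asarray(time_bins, dtype=float)
    n_time = len(time_bins) - 1
    dt = float(np.median(np.diff(time_bins)))

    ground_dt = np.sum(model.ground_rate, axis=0) * dt  # (n_bins,)
    ll = np.tile(-ground_dt, (n_time, 1))

    for tet in range(marks.n_tetrodes):
        st = marks.spike_times[tet]
        mk = marks.marks[tet]
        inside = (st >= time_bins[0]) & (st <= time_bins[-1])
        st, mk = st[inside], mk[inside]
        if len(st) == 0:
            continue
        lam = model.joint_mark_intensity(tet, mk)  # (n_spikes, n_bins)
        log_lam_dt = np.log(lam * dt)
        bins = np.clip(np.searchsorted(time_bins, st, side="right") - 1, 0, n_time - 1)
        np.add.at(ll, bins, log_lam_dt)
    return LikelihoodMatrix(log_likelihood=ll, time_bin_edges=time_bins)
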