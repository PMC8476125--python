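"""Encoding models fit during movement: place-field GLMs and mark KDEs.

Two encoders relate spiking to position using data from movement periods
(running speed above 4 cm/s):

* **Sorted spikes** — per-cell Poisson GLM with a log link on cubic B-spline
  bases over linearized position (knots every 5 cm, placed per track segment
  so bases never bridge the 1D-layout gaps), maximized by Newton-Raphson with
  a small L2 penalty (0.5) on the spline weights.

* **Clusterless** — per-tetrode Gaussian product-kernel density estimates of
  the occupancy ``pi(x)``, the spike-triggered occupancy ``p_i(x)``, and the
  joint position-mark density ``p_i(x, m)`` (bandwidths 6 cm position, 24 uV
  amplitude), combined with the tetrode mean rate ``mu_i`` into the joint
  mark intensity ``lambda_i(m | x) = mu_i p_i(x, m) / pi(x)`` and the ground
  rate ``Lambda_i(x) = mu_i p_i(x) / pi(x)``.

Position kernels are renormalized over the track grid so all densities are
proper on the bounded track (they integrate to one under the Riemann sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .simulate import MarkedSpikeSet, SpikeTrainSet
from .track import LinearizedPosition, PositionGrid

__all__ = [
    "SortedEncodingModel",
    "ClusterlessEncodingModel",
    "fit_sorted_encoder",
    "fit_clusterless_encoder",
    "movement_mask",
    "compute_speed",
]

_LOG_2PI = np.log(2.0 * np.pi)
RATE_FLOOR = 1e-10  # Hz; keeps log-likelihoods finite
DENSITY_FLOOR = 1e-15


def compute_speed(time: np.ndarray, position: np.ndarray, smooth_sd: float = 0.05) -> np.ndarray:
    """Absolute speed (cm/s) from a 1D position series, lightly smoothed.

    ``smooth_sd`` is the Gaussian smoothing SD in seconds.
    """
    from scipy.ndimage import gaussian_filter1d

    time = np.asarray(time, dtype=float)
    position = np.asarray(position, dtype=float)
    if len(time) < 2:
        return np.zeros_like(position)
    dt = np.median(np.diff(time))
    speed = np.abs(np.gradient(position, time))
    if smooth_sd > 0 and dt > 0:
        speed = gaussian_filter1d(speed, smooth_sd / dt, mode="nearest")
    return speed


def movement_mask(
    time: np.ndarray, position: np.ndarray, speed_threshold: float = 4.0
) -> np.ndarray:
    """Boolean mask of movement samples (speed above threshold)."""
    return compute_speed(time, position) > speed_threshold


def _as_time_position(linpos) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a LinearizedPosition or a (time, linear_position) pair."""
    if isinstance(linpos, LinearizedPosition):
        seg = linpos.segment_id
        return linpos.time, linpos.linear_position, seg
    time, pos = linpos
    return np.asarray(time, float), np.asarray(pos, float), None


# ---------------------------------------------------------------------------
# sorted spikes: spline GLM
# ---------------------------------------------------------------------------

def _segment_knots(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Clamped cubic B-spline knot vector with interior knots every ``spacing``."""
    n_int = max(1, int(np.ceil((hi - lo) / spacing)))
    interior = np.linspace(lo, hi, n_int + 1)
    return np.concatenate([[lo] * 3, interior, [hi] * 3])


class _SplineBasis:
    """Per-segment cubic B-spline design, block diagonal across segments."""

    def __init__(self, grid: PositionGrid, knot_spacing: float):
        self.knot_spacing = knot_spacing
        self.segments = []
        centers, edge_ids = grid.bin_centers, grid.edge_ids
        for eid in np.unique(edge_ids):
            sel = edge_ids == eid
            lo = centers[sel].min() - 0.5 * grid.bin_widths[sel][0]
            hi = centers[sel].max() + 0.5 * grid.bin_widths[sel][-1]
            self.segments.append((int(eid), lo, hi, _segment_knots(lo, hi, knot_spacing)))
        self.n_columns = sum(len(kv) - 4 for _, _, _, kv in self.segments)

    def design(self, position: np.ndarray) -> np.ndarray:
        """Evaluate the basis at 1D positions (rows: samples, cols: bases)."""
        position = np.asarray(position, dtype=float)
        out = np.zeros((len(position), self.n_columns))
        col = 0
        for _, lo, hi, kv in self.segments:
            ncol = len(kv) - 4
            inside = (position >= lo) & (position <= hi)
            if inside.any():
                x = np.clip(position[inside], lo, hi - 1e-9 * max(1.0, abs(hi)))
                dm = BSpline.design_matrix(x, kv, 3).toarray()
                out[np.nonzero(inside)[0], col : col + ncol] = dm
            col += ncol
        return out


@dataclass
class SortedEncodingModel:
    """Fitted place-field GLMs: coefficients and rate maps on the grid."""

    coefficients: list[np.ndarray]          # per cell: [beta0, spline weights...]
    rate_map: np.ndarray                    # (n_cells, n_bins) Hz
    knot_spacing: float
    l2_penalty: float
    converged: np.ndarray
    grid_bin_centers: np.ndarray = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.coefficients)


def _fit_poisson_glm(
    X: np.ndarray,
    y: np.ndarray,
    exposure: float,
    l2: float,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson for an L2-penalized Poisson GLM with log link.

    Column 0 of ``X`` is the unpenalized intercept.  ``exposure`` is the bin
    width in seconds (counts ~ Poisson(exp(X beta) * exposure)).  Starts at
    beta0 = log(mean rate); step-halves on penalized-likelihood decrease.
    """
    n, p = X.shape
    pen = np.full(p, 2.0 * l2)
    pen[0] = 0.0
    beta = np.zeros(p)
    mean_rate = max(y.mean() / exposure, RATE_FLOOR)
    beta[0] = np.log(mean_rate)

    def penalized_ll(b):
        eta = X @ b
        return float(y @ eta - exposure * np.exp(eta).sum() - 0.5 * (pen * b * b).sum())

    ll = penalized_ll(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = exposure * np.exp(eta)
        grad = X.T @ (y - mu) - pen * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = (X * mu[:, None]).T @ X
        H[np.diag_indices(p)] += pen + 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.diag(H) + 1e-8)
        # step halving
        new_ll, scale = -np.inf, 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll = penalized_ll(cand)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = new_ll
    else:
        eta = X @ beta
        grad = X.T @ (y - exposure * np.exp(eta)) - pen * beta
        converged = bool(np.max(np.abs(grad)) < tol)
        if not converged:
            warnings.warn(
                f"GLM did not converge; last gradient inf-norm {np.max(np.abs(grad)):.2e}"
            )
    return beta, converged


def fit_sorted_encoder(
    spikes: SpikeTrainSet,
    linpos,
    grid: PositionGrid,
    knot_spacing: float = 5.0,
    l2: float = 0.5,
    speed_threshold: float = 4.0,
) -> SortedEncodingModel:
    """Fit per-cell spline Poisson GLM place fields on movement data.

    ``linpos`` is a :class:`LinearizedPosition` or ``(time, linear_position)``
    pair sampled on a uniform clock; spikes are binned onto that clock.
    """
    time, position, _ = _as_time_position(linpos)
    dt = float(np.median(np.diff(time)))
    moving = movement_mask(time, position, speed_threshold)
    if not moving.any():
        raise ValueError("no movement samples above the speed threshold")

    edges = np.concatenate([time - 0.5 * dt, [time[-1] + 0.5 * dt]])
    counts = spikes.counts(edges)

    basis = _SplineBasis(grid, knot_spacing)
    B = basis.design(position[moving])
    X = np.column_stack([np.ones(B.shape[0]), B])
    B_grid = basis.design(grid.bin_centers)
    X_grid = np.column_stack([np.ones(grid.n_bins), B_grid])

    coefs, rate_maps, converged = [], [], []
    for i in range(spikes.n_cells):
        y = counts[moving, i].astype(float)
        if y.sum() == 0:
            warnings.warn(f"cell {i} has no movement-period spikes; rate map pinned near zero")
            beta = np.full(X.shape[1], 0.0)
            beta[0] = np.log(RATE_FLOOR)
            coefs.append(beta)
            rate_maps.append(np.full(grid.n_bins, RATE_FLOOR))
            converged.append(True)
            continue
        beta, ok = _fit_poisson_glm(X, y, dt, l2)
        coefs.append(beta)
        converged.append(ok)
        rate_maps.append(np.maximum(np.exp(X_grid @ beta), RATE_FLOOR))

    return SortedEncodingModel(
        coefficients=coefs,
        rate_map=np.asarray(rate_maps),
        knot_spacing=knot_spacing,
        l2_penalty=l2,
        converged=np.asarray(converged),
        grid_bin_centers=grid.bin_centers.copy(),
    )


# ---------------------------------------------------------------------------
# clusterless: kernel density encoder
# ---------------------------------------------------------------------------

def _normalized_position_kernels(
    train_pos: np.ndarray, grid: PositionGrid, bw: float
) -> np.ndarray:
    """(n_train, n_bins) Gaussian position kernels, each renormalized to
    integrate to one over the grid (Riemann sum with bin widths)."""
    z = (grid.bin_centers[None, :] - train_pos[:, None]) / bw
    k = np.exp(-0.5 * z * z)
    mass = (k * grid.bin_widths[None, :]).sum(axis=1)
    mass = np.maximum(mass, DENSITY_FLOOR)
    return k / mass[:, None]


@dataclass
class ClusterlessEncodingModel:
    """Per-tetrode KDE encoder for clusterless decoding."""

    occupancy: np.ndarray                  # pi(x) on grid
    spike_occupancy: list[np.ndarray]      # p_i(x) on grid, per tetrode
    ground_rate: list[np.ndarray]          # Lambda_i(x) Hz on grid
    mean_rates: np.ndarray                 # mu_i Hz
    train_pos_kernels: list[np.ndarray]    # per tetrode (n_train, n_bins)
    train_marks: list[np.ndarray]          # per tetrode (n_train, 4)
    bw_pos: float
    bw_mark: float
    grid_bin_centers: np.ndarray = field(repr=False, default=None)

    @property
    def n_tetrodes(self) -> int:
        return len(self.spike_occupancy)

    def joint_mark_intensity(self, tetrode: int, marks: np.ndarray) -> np.ndarray:
        """lambda_i(m | x) = mu_i p_i(x, m) / pi(x) for query ``marks``.

        Returns an ``(n_query, n_bins)`` array in Hz per (uV)^4; the mark
        density uses unbounded Gaussian kernels, the position density uses
        the track-normalized kernels.
        """
        marks = np.atleast_2d(np.asarray(marks, dtype=float))
        kp = self.train_pos_kernels[tetrode]
        tm = self.train_marks[tetrode]
        if marks.shape[1] != tm.shape[1]:
            raise ValueError("mark dimensionality does not match the encoder")
        n_train = len(tm)
        if n_train == 0:
            return np.full((len(marks), kp.shape[1]), DENSITY_FLOOR)
        d = tm.shape[1]
        # log mark-kernel weights, (n_query, n_train)
        sq = (
            (marks**2).sum(axis=1)[:, None]
            - 2.0 * marks @ tm.T
            + (tm**2).sum(axis=1)[None, :]
        )
        logw = -0.5 * sq / self.bw_mark**2 - 0.5 * d * _LOG_2PI - d * np.log(self.bw_mark)
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        joint = (w @ kp) / n_train  # p(x, m) up to the per-query max factor
        scale = np.exp(logw.max(axis=1))
        joint = joint * scale[:, None]
        lam = self.mean_rates[tetrode] * joint / np.maximum(self.occupancy, DENSITY_FLOOR)
        return np.maximum(lam, DENSITY_FLOOR)


def fit_clusterless_encoder(
    marks: MarkedSpikeSet,
    linpos,
    grid: PositionGrid,
    bw_pos: float = 6.0,
    bw_mark: float = 24.0,
    speed_threshold: float = 4.0,
) -> ClusterlessEncodingModel:
    """Fit the KDE joint mark intensity model on movement-period data."""
    time, position, _ = _as_time_position(linpos)
    moving = movement_mask(time, position, speed_threshold)
    if not moving.any():
        raise ValueError("no movement samples above the speed threshold")
    dt = float(np.median(np.diff(time)))
    movement_duration = moving.sum() * dt

    occ_kernels = _normalized_position_kernels(position[moving], grid, bw_pos)
    occupancy = occ_kernels.mean(axis=0)

    spike_occ, ground, mus, kernels, train_marks = [], [], [], [], []
    for tet in range(marks.n_tetrodes):
        st = marks.spike_times[tet]
        mk = marks.marks[tet]
        # spike position: sample of the position series at spike time
        idx = np.clip(np.searchsorted(time, st), 0, len(time) - 1)
        keep = moving[idx]
        st, mk, idx = st[keep], mk[keep], idx[keep]
        if len(st) == 0:
            warnings.warn(f"tetrode {tet} has no movement-period spikes; excluded")
            spike_occ.append(np.full(grid.n_bins, DENSITY_FLOOR))
            ground.append(np.zeros(grid.n_bins))
            mus.append(0.0)
            kernels.append(np.zeros((0, grid.n_bins)))
            train_marks.append(np.zeros((0, 4)))
            continue
        kp = _normalized_position_kernels(position[idx], grid, bw_pos)
        p_x = kp.mean(axis=0)
        mu = len(st) / movement_duration
        spike_occ.append(p_x)
        mus.append(mu)
        ground.append(mu * p_x / np.maximum(occupancy, DENSITY_FLOOR))
        kernels.append(kp)
        train_marks.append(mk)

    return ClusterlessEncodingModel(
        occupancy=occupancy,
        spike_occupancy=spike_occ,
        ground_rate=ground,
        mean_rates=np.asarray(mus),
        train_pos_kernels=kernels,
        train_marks=train_marks,
        bw_pos=bw_pos,
        bw_mark=bw_mark,
        grid_bin_centers=grid.bin_centers.copy(),
    )
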