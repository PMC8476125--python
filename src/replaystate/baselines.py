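"""Standard ('Bayesian') decoder baselines and shuffle controls.

For comparison with the switching state-space decoder, this module
implements the conventional pipeline: a 20 ms-bin posterior with a uniform
prior, constant-speed line fitting by Radon-style dense line search with a
circular-shuffle significance test, line fitting by linear regression on
posterior samples, and replay speed from the per-bin MAP position.  It also
provides the two encoding-shuffle controls (position resampling, and
run-order permutation with within-run circular shifts) used to verify that
classification depends on place-specific firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihoods import clusterless_likelihood, make_time_bins, sorted_likelihood
from .track import LinearizedPosition, PositionGrid

__all__ = [
    "LineFit",
    "standard_posterior",
    "radon_fit",
    "linreg_fit",
    "map_speed_20ms",
    "shuffle_positions_resample",
    "shuffle_runs_circular",
]


@dataclass
class LineFit:
    """A constant-speed line fit to a posterior."""

    slope: float            # cm/s
    intercept: float        # cm at the first time-bin center
    score: float            # Radon probability sum, or R^2
    p_value: float | None
    arm_combination: int    # index of the winning arm mask

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def standard_posterior(
    encoder,
    data,
    grid: PositionGrid,
    bin_width: float = 0.020,
    time_bins: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-prior posterior of position in (default) 20 ms bins.

    Returns ``(posterior, time_bin_edges)`` with posterior rows summing to 1.
    """
    from .encoding import ClusterlessEncodingModel, SortedEncodingModel

    if time_bins is None:
        time_bins = make_time_bins(data.duration, bin_width)
    if isinstance(encoder, SortedEncodingModel):
        lik = sorted_likelihood(encoder, data, time_bins, grid)
    elif isinstance(encoder, ClusterlessEncodingModel):
        lik = clusterless_likelihood(encoder, data, time_bins, grid)
    else:
        raise TypeError(f"unsupported encoder type {type(encoder).__name__}")
    ll = lik.log_likelihood
    post = np.exp(ll - ll.max(axis=1, keepdims=True)) * grid.bin_widths[None, :]
    post /= post.sum(axis=1, keepdims=True)
    return post, np.asarray(time_bins)


def _line_scores(
    post: np.ndarray,
    t_centers: np.ndarray,
    bin_centers: np.ndarray,
    bin_size: float,
    slopes: np.ndarray,
    intercepts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Summed posterior along each candidate line.

    Lines are ``x(t) = intercept + slope * (t - t_centers[0])``; at every
    time bin the nearest position bin on the line contributes (bins farther
    than half a bin from any center contribute zero).

    Returns (scores[n_lines], line_bin_index[n_lines, n_t], valid mask).
    """
    rel_t = t_centers - t_centers[0]
    # (n_slopes, n_intercepts, n_t) line positions
    pos = intercepts[None, :, None] + slopes[:, None, None] * rel_t[None, None, :]
    pos = pos.reshape(-1, len(rel_t))
    idx = np.clip(np.searchsorted(bin_centers, pos), 1, len(bin_centers) - 1)
    left = bin_centers[idx - 1]
    right = bin_centers[idx]
    idx = np.where(np.abs(pos - left) <= np.abs(pos - right), idx - 1, idx)
    valid = np.abs(pos - bin_centers[idx]) <= 0.5 * bin_size + 1e-9
    vals = post[np.arange(len(rel_t))[None, :], idx] * valid
    return vals.sum(axis=1), idx, valid


def radon_fit(
    post: np.ndarray,
    time_bin_edges: np.ndarray,
    grid: PositionGrid,
    n_shuffles: int = 1000,
    seed: int = 0,
    n_slopes: int = 101,
    max_speed: float = 1.0e4,
    arm_masks: list[np.ndarray] | None = None,
    shuffle_mode: str = "per_bin",
) -> LineFit:
    """Best constant-speed line by dense (slope, intercept) search.

    The default slope grid has an odd point count so the zero-slope
    (stationary) line is always a candidate.  Grid spacing limits recovery:
    a slope is found only to within one grid step, and a line's score decays
    once its drift over the event exceeds half a position bin.

    Significance is assessed by circularly shuffling the posterior columns
    ``n_shuffles`` times and comparing best scores;
    ``p = (1 + #{shuffle >= observed}) / (1 + n)``.  Each time bin is
    shifted by an independent random offset by default
    (``shuffle_mode='per_bin'``); a common offset per shuffle
    (``shuffle_mode='common'``) is available but preserves line structure
    exactly (a circularly shifted line is still a line), so it cannot
    reject any constant-speed trajectory.
    When ``arm_masks`` are given (e.g. center+left vs center+right), the fit
    runs on each restricted posterior and the best-scoring mask wins.
    """
    post = np.atleast_2d(np.asarray(post, dtype=float))
    if post.shape[0] < 2:
        raise ValueError("need at least two time bins for a line fit")
    t_centers = 0.5 * (np.asarray(time_bin_edges)[:-1] + np.asarray(time_bin_edges)[1:])
    slopes = np.linspace(-max_speed, max_speed, n_slopes)
    rng = np.random.default_rng(seed)
    if arm_masks is None:
        arm_masks = [np.ones(post.shape[1], dtype=bool)]

    best = None
    for mi, mask in enumerate(arm_masks):
        sub = post[:, mask]
        centers = grid.bin_centers[mask]
        intercepts = centers.copy()
        scores, _, _ = _line_scores(sub, t_centers, centers, grid.bin_size, slopes, intercepts)
        k = int(np.argmax(scores))
        obs = float(scores[k])
        slope = float(slopes[k // len(intercepts)])
        intercept = float(intercepts[k % len(intercepts)])

        n_ge = 0
        n_bins = sub.shape[1]
        for _ in range(n_shuffles):
            if shuffle_mode == "common":
                off = int(rng.integers(n_bins))
                shuf = np.roll(sub, off, axis=1)
            elif shuffle_mode == "per_bin":
                offs = rng.integers(n_bins, size=sub.shape[0])
                shuf = np.array([np.roll(row, o) for row, o in zip(sub, offs)])
            else:
                raise ValueError("shuffle_mode must be 'common' or 'per_bin'")
            s, _, _ = _line_scores(shuf, t_centers, centers, grid.bin_size, slopes, intercepts)
            if s.max() >= obs:
                n_ge += 1
        p = (1 + n_ge) / (1 + n_shuffles)
        fit = LineFit(slope=slope, intercept=intercept, score=obs, p_value=p, arm_combination=mi)
        if best is None or fit.score > best.score:
            best = fit
    return best


def linreg_fit(
    post: np.ndarray,
    time_bin_edges: np.ndarray,
    grid: PositionGrid,
    n_samples: int = 1000,
    seed: int = 0,
    arm_masks: list[np.ndarray] | None = None,
) -> LineFit:
    """Line fit by OLS on positions sampled from each time bin's posterior.

    Fits are made per arm mask and the best R^2 wins.  A zero-variance
    sample set yields slope 0 with an undefined (NaN) score.
    """
    post = np.atleast_2d(np.asarray(post, dtype=float))
    if post.shape[0] < 2:
        raise ValueError("need at least two time bins for a line fit")
    t_centers = 0.5 * (np.asarray(time_bin_edges)[:-1] + np.asarray(time_bin_edges)[1:])
    rng = np.random.default_rng(seed)
    if arm_masks is None:
        arm_masks = [np.ones(post.shape[1], dtype=bool)]

    best = None
    for mi, mask in enumerate(arm_masks):
        sub = post[:, mask]
        centers = grid.bin_centers[mask]
        xs, ts = [], []
        for k in range(sub.shape[0]):
            p = sub[k] / sub[k].sum()
            xs.append(centers[rng.choice(len(centers), size=n_samples, p=p)])
            ts.append(np.full(n_samples, t_centers[k]))
        x = np.concatenate(xs)
        t = np.concatenate(ts)
        if np.var(x) == 0 or np.var(t) == 0:
            fit = LineFit(slope=0.0, intercept=float(x[0]), score=np.nan, p_value=None, arm_combination=mi)
        else:
            slope, icpt = np.polyfit(t - t_centers[0], x, 1)
            resid = x - (icpt + slope * (t - t_centers[0]))
            r2 = 1.0 - resid.var() / x.var()
            fit = LineFit(slope=float(slope), intercept=float(icpt), score=float(r2), p_value=None, arm_combination=mi)
        if best is None or (np.isnan(best.score) and not np.isnan(fit.score)) or (
            not np.isnan(fit.score) and fit.score > best.score
        ):
            best = fit
    return best


def map_speed_20ms(
    post: np.ndarray, time_bin_edges: np.ndarray, grid: PositionGrid
) -> np.ndarray:
    """Replay speed (cm/s) from per-bin MAP positions of a binned posterior."""
    post = np.atleast_2d(np.asarray(post, dtype=float))
    map_cm = grid.bin_centers[np.argmax(post, axis=1)]
    if len(map_cm) < 2:
        return np.zeros(len(map_cm))
    dt = float(np.median(np.diff(time_bin_edges)))
    return np.abs(np.gradient(map_cm, dt))


def _positions_of(linpos):
    if isinstance(linpos, LinearizedPosition):
        return linpos.time, linpos.linear_position
    return np.asarray(linpos[0], float), np.asarray(linpos[1], float)


def shuffle_positions_resample(linpos, seed: int = 0, mask: np.ndarray | None = None):
    """Resample positions with replacement, preserving the time axis.

    Breaks the spike-position relationship while preserving the occupancy
    marginal; spike trains are untouched.  Returns a ``(time, position)``
    pair.
    """
    time, pos = _positions_of(linpos)
    rng = np.random.default_rng(seed)
    out = pos.copy()
    if mask is None:
        mask = np.ones(len(pos), dtype=bool)
    vals = pos[mask]
    out[mask] = vals[rng.integers(len(vals), size=mask.sum())]
    return time, out


def shuffle_runs_circular(linpos, run_intervals: list[tuple[int, int]], seed: int = 0):
    """Permute the order of well-to-well runs and circularly shift position
    within each run.

    ``run_intervals`` are (start, end) sample-index pairs partitioning the
    series into runs.  The multiset of run durations is preserved; samples
    outside every run are left in place.  Returns a ``(time, position)``
    pair.
    """
    time, pos = _positions_of(linpos)
    rng = np.random.default_rng(seed)
    out = pos.copy()
    order = rng.permutation(len(run_intervals))
    # destination slots follow the original run boundaries in time order,
    # but are filled with the runs in permuted order, clipped/cycled to fit
    src_segments = []
    for i in order:
        s, e = run_intervals[i]
        seg = pos[s:e]
        shift = int(rng.integers(len(seg))) if len(seg) else 0
        src_segments.append(np.roll(seg, shift))
    stream = np.concatenate(src_segments) if src_segments else np.zeros(0)
    cursor = 0
    for s, e in run_intervals:
        n = e - s
        take = stream[cursor : cursor + n]
        if len(take) < n:  # permuted runs have different lengths; cycle
            take = np.resize(stream, n) if len(stream) else pos[s:e]
        out[s:e] = take
        cursor += n
    return time, out
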