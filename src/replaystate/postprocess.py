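"""Posterior summaries: dynamics marginal, classification, HPD, MAP, speed.

The acausal joint posterior over (dynamic, position) is reduced to the
quantities used to characterize replay content:

* ``Pr(I_k | O_{1:T})`` — position integrated out (Riemann sum);
* ``p(x_k | O_{1:T})`` — dynamics summed out;
* a five-way speed-category label per 2 ms bin at a 0.80 threshold:
  stationary, stationary-continuous-mixture, continuous,
  fragmented-continuous-mixture, fragmented — else unclassified;
* the 95% highest-posterior-density region size (cm), a spatial-certainty
  measure;
* the MAP position track and its smoothed absolute derivative (replay speed);
* per-event flags: spatially coherent / incoherent content and non-local
  stationary representations (>= 30 cm from the animal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .state_space import Posterior
from .track import PositionGrid, distance_from_animal

__all__ = [
    "CATEGORIES",
    "COHERENT_CATEGORIES",
    "INCOHERENT_CATEGORIES",
    "ClassificationTrack",
    "EventSummary",
    "dynamics_marginal",
    "position_marginal",
    "classify",
    "hpd_region",
    "map_position",
    "estimate_speed",
    "summarize_event",
]

CATEGORIES = (
    "stationary",
    "stationary-continuous-mixture",
    "continuous",
    "fragmented-continuous-mixture",
    "fragmented",
    "unclassified",
)
COHERENT_CATEGORIES = frozenset(
    {"stationary", "stationary-continuous-mixture", "continuous"}
)
INCOHERENT_CATEGORIES = frozenset({"fragmented", "fragmented-continuous-mixture"})


def dynamics_marginal(post: Posterior) -> np.ndarray:
    """Pr(I_k | O_{1:T}): (n_time, n_dynamics), rows sum to 1."""
    marg = post.joint.sum(axis=2)
    return marg / marg.sum(axis=1, keepdims=True)


def position_marginal(post: Posterior) -> np.ndarray:
    """p(x_k | O_{1:T}): (n_time, n_bins), rows sum to 1."""
    marg = post.joint.sum(axis=1)
    return marg / marg.sum(axis=1, keepdims=True)


@dataclass
class ClassificationTrack:
    """Per-bin speed-category labels and merged contiguous segments."""

    labels: np.ndarray                       # (n_time,) of CATEGORIES entries
    segments: list[tuple[float, float, str]] # (start s, end s, category)
    time_bin_edges: np.ndarray
    threshold: float

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.time_bin_edges)))

    def duration_by_category(self) -> dict[str, float]:
        """Total seconds spent in each category."""
        w = self.bin_width
        return {c: float((self.labels == c).sum() * w) for c in CATEGORIES}


def classify(
    marg: np.ndarray,
    threshold: float = 0.80,
    dynamics: tuple[str, ...] = ("stationary", "continuous", "fragmented"),
    time_bin_edges: np.ndarray | None = None,
) -> ClassificationTrack:
    """Label each time bin with one of the five speed categories.

    An individual dynamic wins when its probability is strictly above
    ``threshold``; otherwise a mixture (stationary+continuous or
    fragmented+continuous) wins when the pair sum is strictly above
    ``threshold`` (the larger sum if both qualify, ties to the slower
    mixture); else the bin is unclassified.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    marg = np.atleast_2d(np.asarray(marg, dtype=float))
    n_time = marg.shape[0]
    if time_bin_edges is None:
        time_bin_edges = np.arange(n_time + 1) * 0.002
    idx = {d: i for i, d in enumerate(dynamics)}
    p_of = lambda d: marg[:, idx[d]] if d in idx else np.zeros(n_time)
    p_stat, p_cont, p_frag = p_of("stationary"), p_of("continuous"), p_of("fragmented")

    labels = np.full(n_time, "unclassified", dtype=object)
    scm = p_stat + p_cont
    fcm = p_frag + p_cont
    mix_scm = (scm > threshold) & ((scm >= fcm) | (fcm <= threshold))
    mix_fcm = (fcm > threshold) & ~mix_scm
    labels[mix_scm] = "stationary-continuous-mixture"
    labels[mix_fcm] = "fragmented-continuous-mixture"
    labels[p_stat > threshold] = "stationary"
    labels[p_cont > threshold] = "continuous"
    labels[p_frag > threshold] = "fragmented"

    segments = []
    start = 0
    for k in range(1, n_time + 1):
        if k == n_time or labels[k] != labels[start]:
            segments.append(
                (float(time_bin_edges[start]), float(time_bin_edges[k]), str(labels[start]))
            )
            start = k
    return ClassificationTrack(
        labels=labels.astype(str),
        segments=segments,
        time_bin_edges=np.asarray(time_bin_edges, dtype=float),
        threshold=threshold,
    )


def hpd_region(
    marg_pos: np.ndarray, grid: PositionGrid, coverage: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """95% highest-posterior-density region per time bin.

    The region is the smallest set of bins (taken in descending posterior
    order, ties broken by bin index) whose mass reaches ``coverage``; its
    size is the summed width (cm) of the member bins.

    Returns ``(member_mask, size_cm)`` with shapes (n_time, n_bins) and
    (n_time,).
    """
    marg_pos = np.atleast_2d(np.asarray(marg_pos, dtype=float))
    n_time, n_bins = marg_pos.shape
    member = np.zeros((n_time, n_bins), dtype=bool)
    size = np.zeros(n_time)
    for k in range(n_time):
        order = np.argsort(-marg_pos[k], kind="stable")
        csum = np.cumsum(marg_pos[k][order])
        n_needed = int(np.searchsorted(csum, coverage * csum[-1] - 1e-12) + 1)
        chosen = order[:n_needed]
        member[k, chosen] = True
        size[k] = grid.bin_widths[chosen].sum()
    return member, size


def map_position(marg_pos: np.ndarray, grid: PositionGrid) -> tuple[np.ndarray, np.ndarray]:
    """MAP position per time bin: (bin indices, bin-center coordinates cm).

    Ties are broken to the lowest bin index.
    """
    marg_pos = np.atleast_2d(np.asarray(marg_pos, dtype=float))
    idx = np.argmax(marg_pos, axis=1)
    return idx, grid.bin_centers[idx]


def estimate_speed(
    map_track: np.ndarray,
    dt: float = 0.002,
    smooth_sd: float = 0.0025,
) -> np.ndarray:
    """Instantaneous replay speed (cm/s) from the MAP track.

    Central-difference gradient, then Gaussian smoothing (SD ``smooth_sd``
    seconds), then absolute value.
    """
    map_track = np.asarray(map_track, dtype=float)
    if len(map_track) < 2:
        return np.zeros_like(map_track)
    deriv = np.gradient(map_track, dt)
    if smooth_sd > 0:
        deriv = gaussian_filter1d(deriv, smooth_sd / dt, mode="nearest")
    return np.abs(deriv)


def segment_mean_speeds(
    track: ClassificationTrack,
    map_track: np.ndarray,
    dt: float = 0.002,
    smooth_sd: float = 0.0025,
    min_duration: float = 0.020,
) -> list[tuple[float, float, str, float]]:
    """Mean speed per classified segment, excluding segments shorter than
    ``min_duration`` seconds and unclassified segments.

    Returns (start, end, category, mean_speed_cm_s) tuples.
    """
    speed = estimate_speed(map_track, dt, smooth_sd)
    edges = track.time_bin_edges
    out = []
    for start, end, cat in track.segments:
        if cat == "unclassified" or (end - start) < min_duration:
            continue
        sel = (edges[:-1] >= start - 1e-12) & (edges[:-1] < end - 1e-12)
        if sel.sum() < 2:
            continue
        out.append((start, end, cat, float(speed[sel].mean())))
    return out


@dataclass
class EventSummary:
    """Per-event content summary."""

    categories_present: set
    duration_by_category: dict[str, float]      # seconds
    mean_speed_by_category: dict[str, float]    # cm/s over qualifying segments
    mean_distance_from_animal: float | None     # cm
    mean_hpd_size: float                        # cm
    spatially_coherent: bool
    spatially_incoherent: bool
    non_local_stationary: bool
    classified_fraction: float
    extras: dict = field(default_factory=dict)


def summarize_event(
    track: ClassificationTrack,
    marg_pos: np.ndarray,
    grid: PositionGrid,
    animal_xy: np.ndarray | None = None,
    non_local_threshold: float = 30.0,
    hpd_coverage: float = 0.95,
    min_speed_duration: float = 0.020,
) -> EventSummary:
    """Aggregate one decoded event into the headline per-event measures."""
    dt = track.bin_width
    map_idx, map_cm = map_position(marg_pos, grid)
    _, hpd_size = hpd_region(marg_pos, grid, hpd_coverage)
    durations = track.duration_by_category()
    present = {c for c in CATEGORIES[:-1] if durations[c] > 0}

    seg_speeds = segment_mean_speeds(track, map_cm, dt, min_duration=min_speed_duration)
    speed_by_cat: dict[str, list[float]] = {}
    for _, _, cat, v in seg_speeds:
        speed_by_cat.setdefault(cat, []).append(v)
    mean_speed = {c: float(np.mean(v)) for c, v in speed_by_cat.items()}

    distances = None
    non_local = False
    mean_dist = None
    if animal_xy is not None and grid.track is not None:
        distances = np.array(
            [distance_from_animal(grid, int(i), animal_xy) for i in map_idx]
        )
        mean_dist = float(distances.mean())
        stat_bins = track.labels == "stationary"
        non_local = bool(stat_bins.any() and (distances[stat_bins] >= non_local_threshold).any())

    classified = track.labels != "unclassified"
    return EventSummary(
        categories_present=present,
        duration_by_category=durations,
        mean_speed_by_category=mean_speed,
        mean_distance_from_animal=mean_dist,
        mean_hpd_size=float(hpd_size.mean()),
        spatially_coherent=bool(present & COHERENT_CATEGORIES),
        spatially_incoherent=bool(present & INCOHERENT_CATEGORIES),
        non_local_stationary=non_local,
        classified_fraction=float(classified.mean()),
    )
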