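"""Track topology, position linearization, and latent-position grids.

A track is represented as a graph whose nodes are 2D coordinates (cm) and
whose edges are straight track segments.  Positions recorded in 2D are
assigned to segments with a small hidden Markov model (Viterbi) and projected
onto the track, giving a 1D "linearized" coordinate.  Each segment occupies a
disjoint interval of the 1D axis, separated by a fixed gap so that spatial
smoothing on the 1D axis cannot bleed between physically distant segments.

The latent position used for decoding lives on a discrete grid: every edge is
partitioned into bins no wider than the requested bin size, and shortest-path
distances between all bin centers are computed on the graph (so distances are
topological, not 1D-layout based — the layout gaps never enter them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "TrackGraph",
    "PositionGrid",
    "LinearizedPosition",
    "linear_track",
    "w_track",
    "linearize",
    "make_grid_1d",
    "make_grid_2d",
    "project_to_track",
    "distance_from_animal",
]


@dataclass
class TrackGraph:
    """Graph of straight track segments with a 1D layout.

    Parameters
    ----------
    node_positions : (n_nodes, 2) array
        2D coordinates of the graph nodes in cm.
    edges : list of (int, int)
        Node-index pairs; each edge is a straight segment.  The edge order
        defines the order of the 1D layout intervals.
    gap_size : float
        Gap (cm) inserted between consecutive edge intervals on the 1D axis.
    origin_node : int
        Node at linear position reference (e.g. the center well); its edge
        interval is laid out first by convention of ``edges`` ordering.
    """

    node_positions: np.ndarray
    edges: list[tuple[int, int]]
    gap_size: float = 15.0
    origin_node: int = 0
    edge_lengths: np.ndarray = field(init=False)
    linear_offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        if self.node_positions.ndim != 2 or self.node_positions.shape[1] != 2:
            raise ValueError("node_positions must be (n_nodes, 2)")
        lengths = []
        for u, v in self.edges:
            lengths.append(np.linalg.norm(self.node_positions[v] - self.node_positions[u]))
        self.edge_lengths = np.asarray(lengths)
        if np.any(self.edge_lengths <= 0):
            raise ValueError("zero-length track segment")
        # disjoint 1D intervals separated by gap_size
        offsets = np.concatenate(
            [[0.0], np.cumsum(self.edge_lengths[:-1] + self.gap_size)]
        )
        self.linear_offsets = offsets

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, xy in enumerate(self.node_positions):
            g.add_node(i, pos=tuple(xy))
        for eid, ((u, v), length) in enumerate(zip(self.edges, self.edge_lengths)):
            g.add_edge(u, v, distance=float(length), edge_id=eid)
        return g

    # -- geometry helpers ---------------------------------------------------
    def _segment_endpoints(self, edge_id: int) -> tuple[np.ndarray, np.ndarray]:
        u, v = self.edges[edge_id]
        return self.node_positions[u], self.node_positions[v]

    def project_point(self, xy: np.ndarray, edge_id: int) -> tuple[np.ndarray, float]:
        """Orthogonal projection of ``xy`` onto segment ``edge_id``.

        Returns the projected 2D point and its offset (cm) from the edge's
        first node, clipped to the segment.
        """
        a, b = self._segment_endpoints(edge_id)
        ab = b - a
        t = float(np.dot(xy - a, ab) / np.dot(ab, ab))
        t = min(max(t, 0.0), 1.0)
        return a + t * ab, t * self.edge_lengths[edge_id]

    def point_segment_distance(self, xy: np.ndarray, edge_id: int) -> float:
        proj, _ = self.project_point(xy, edge_id)
        return float(np.linalg.norm(xy - proj))

    def linear_position(self, edge_id: int, offset: float) -> float:
        """1D coordinate of a point ``offset`` cm along edge ``edge_id``."""
        return float(self.linear_offsets[edge_id] + offset)

    def node_shortest_paths(self) -> dict:
        return dict(nx.all_pairs_dijkstra_path_length(self.as_networkx(), weight="distance"))

    def graph_distance_between_points(
        self,
        edge_a: int,
        offset_a: float,
        edge_b: int,
        offset_b: float,
        node_dist: dict | None = None,
    ) -> float:
        """Shortest along-track distance between two points on the graph."""
        if edge_a == edge_b:
            return abs(offset_a - offset_b)
        if node_dist is None:
            node_dist = self.node_shortest_paths()
        ua, va = self.edges[edge_a]
        ub, vb = self.edges[edge_b]
        la, lb = self.edge_lengths[edge_a], self.edge_lengths[edge_b]
        best = np.inf
        for na, da in ((ua, offset_a), (va, la - offset_a)):
            for nb, db in ((ub, offset_b), (vb, lb - offset_b)):
                best = min(best, da + node_dist[na][nb] + db)
        return float(best)


def linear_track(length: float = 180.0) -> TrackGraph:
    """A single straight segment of the given length (cm)."""
    nodes = np.array([[0.0, 0.0], [length, 0.0]])
    return TrackGraph(node_positions=nodes, edges=[(0, 1)], gap_size=15.0)


def w_track(center_length: float = 77.0, arm_length: float = 77.0, arm_spacing: float = 30.0) -> TrackGraph:
    """W-shaped track: center arm plus left/right arms joined by cross pieces.

    Node 0 is the center well (linear position 0 by layout convention).
    """
    nodes = np.array(
        [
            [0.0, 0.0],              # 0 center well
            [0.0, center_length],    # 1 center junction (choice point)
            [-arm_spacing, center_length],  # 2 left junction
            [-arm_spacing, center_length - arm_length],  # 3 left well
            [arm_spacing, center_length],   # 4 right junction
            [arm_spacing, center_length - arm_length],   # 5 right well
        ]
    )
    edges = [(0, 1), (1, 2), (2, 3), (1, 4), (4, 5)]
    return TrackGraph(node_positions=nodes, edges=edges, gap_size=15.0, origin_node=0)


@dataclass
class LinearizedPosition:
    """Per-frame track assignment and 1D coordinate."""

    time: np.ndarray
    segment_id: np.ndarray
    linear_position: np.ndarray
    projected_2d: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.time)


def _interpolate_gaps(xy: np.ndarray, max_gap: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill NaN runs shorter than ``max_gap`` frames; flag the rest."""
    xy = np.array(xy, dtype=float)
    bad = ~np.all(np.isfinite(xy), axis=1)
    valid = ~bad
    if not bad.any():
        return xy, valid
    idx = np.arange(len(xy))
    # identify NaN runs
    run_start = None
    for i in range(len(xy) + 1):
        if i < len(xy) and bad[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            if run_len < max_gap and run_start > 0 and i < len(xy):
                for d in range(2):
                    xy[run_start:i, d] = np.interp(
                        idx[run_start:i], [run_start - 1, i], [xy[run_start - 1, d], xy[i, d]]
                    )
                valid[run_start:i] = True
            run_start = None
    return xy, valid


def linearize(
    track: TrackGraph,
    xy: np.ndarray,
    time: np.ndarray | None = None,
    obs_sd: float = 5.0,
    diag_bias: float = 0.1,
) -> LinearizedPosition:
    """Assign 2D positions to track segments (Viterbi) and project to 1D.

    The segment HMM has a Gaussian observation model on the point-to-segment
    distance (SD ``obs_sd`` cm).  The transition model is built per frame:
    segments are favored when the along-graph distance between the successive
    projected points matches the Euclidean displacement (Gaussian penalty on
    the mismatch, SD ``obs_sd``), with a ``diag_bias`` added to the diagonal
    to discourage single-frame segment flips; rows are normalized.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if time is None:
        time = np.arange(len(xy), dtype=float)
    time = np.asarray(time, dtype=float)
    xy, valid = _interpolate_gaps(xy)
    n_frames, n_seg = len(xy), track.n_edges

    # projections and observation log-likelihoods for every (frame, segment)
    proj = np.zeros((n_frames, n_seg, 2))
    offs = np.zeros((n_frames, n_seg))
    dist = np.full((n_frames, n_seg), np.nan)
    for k in range(n_frames):
        if not valid[k]:
            continue
        for s in range(n_seg):
            p, off = track.project_point(xy[k], s)
            proj[k, s], offs[k, s] = p, off
            dist[k, s] = np.linalg.norm(xy[k] - p)
    with np.errstate(invalid="ignore"):
        obs_ll = -0.5 * (dist / obs_sd) ** 2
    obs_ll[~valid] = 0.0  # uninformative frames

    node_dist = track.node_shortest_paths()

    def transition_ll(k: int) -> np.ndarray:
        """Row-stochastic transition matrix between frames k-1 and k (log)."""
        eucl = np.linalg.norm(xy[k] - xy[k - 1])
        mat = np.zeros((n_seg, n_seg))
        for s_prev in range(n_seg):
            for s_new in range(n_seg):
                gd = track.graph_distance_between_points(
                    s_prev, offs[k - 1, s_prev], s_new, offs[k, s_new], node_dist
                )
                mat[s_prev, s_new] = np.exp(-0.5 * ((gd - eucl) / obs_sd) ** 2)
        mat[np.diag_indices(n_seg)] += diag_bias
        mat /= mat.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):  # far segments underflow to 0
            return np.log(mat)

    # Viterbi
    back = np.zeros((n_frames, n_seg), dtype=int)
    score = np.full(n_seg, -np.log(n_seg)) + obs_ll[0]
    for k in range(1, n_frames):
        trans = transition_ll(k) if (valid[k] and valid[k - 1]) else np.log(
            np.full((n_seg, n_seg), 1.0 / n_seg)
        )
        cand = score[:, None] + trans + obs_ll[k][None, :]
        back[k] = np.argmax(cand, axis=0)
        score = cand[back[k], np.arange(n_seg)]
    seg = np.zeros(n_frames, dtype=int)
    seg[-1] = int(np.argmax(score))
    for k in range(n_frames - 2, -1, -1):
        seg[k] = back[k + 1][seg[k + 1]]

    linpos = np.array(
        [track.linear_position(seg[k], offs[k, seg[k]]) for k in range(n_frames)]
    )
    proj2d = proj[np.arange(n_frames), seg]
    return LinearizedPosition(
        time=time, segment_id=seg, linear_position=linpos, projected_2d=proj2d, valid=valid
    )


@dataclass
class PositionGrid:
    """Discretized latent-position support with pairwise graph distances."""

    bin_centers: np.ndarray          # linear coordinate (1D) or flat index coords (2D)
    bin_widths: np.ndarray
    centers_xy: np.ndarray           # 2D coordinates of bin centers
    edge_ids: np.ndarray             # owning edge per bin (-1 for 2D grids)
    edge_offsets: np.ndarray         # offset along owning edge (cm)
    graph_distance: np.ndarray       # (n_bins, n_bins) shortest path cm
    bin_size: float
    track: TrackGraph | None = None
    shape_2d: tuple[int, int] | None = None
    valid_mask: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def make_grid_1d(track: TrackGraph, bin_size: float = 3.0) -> PositionGrid:
    """Partition every edge into equal bins <= ``bin_size`` wide.

    Bin centers are inserted as nodes into the track graph and all-pairs
    shortest-path distances between centers are computed on the augmented
    graph, so distances respect the track topology (never the layout gaps).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if track.n_edges == 0:
        raise ValueError("empty track graph")

    g = track.as_networkx()
    centers_lin, widths, centers_xy, edge_ids, edge_offsets = [], [], [], [], []
    center_nodes = []
    next_node = max(g.nodes) + 1
    for eid, ((u, v), length) in enumerate(zip(track.edges, track.edge_lengths)):
        n_bins = int(np.ceil(length / bin_size - 1e-12))
        width = length / n_bins
        g.remove_edge(u, v)
        prev, prev_off = u, 0.0
        a, b = track.node_positions[u], track.node_positions[v]
        for i in range(n_bins):
            off = (i + 0.5) * width
            node = next_node
            next_node += 1
            g.add_node(node)
            g.add_edge(prev, node, distance=off - prev_off)
            prev, prev_off = node, off
            centers_lin.append(track.linear_position(eid, off))
            widths.append(width)
            centers_xy.append(a + (off / length) * (b - a))
            edge_ids.append(eid)
            edge_offsets.append(off)
            center_nodes.append(node)
        g.add_edge(prev, v, distance=length - prev_off)

    dist_all = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    n = len(center_nodes)
    dmat = np.zeros((n, n))
    for i, ni in enumerate(center_nodes):
        row = dist_all[ni]
        for j, nj in enumerate(center_nodes):
            dmat[i, j] = row[nj]
    dmat = 0.5 * (dmat + dmat.T)

    return PositionGrid(
        bin_centers=np.asarray(centers_lin),
        bin_widths=np.asarray(widths),
        centers_xy=np.asarray(centers_xy),
        edge_ids=np.asarray(edge_ids, dtype=int),
        edge_offsets=np.asarray(edge_offsets),
        graph_distance=dmat,
        bin_size=bin_size,
        track=track,
    )


def make_grid_2d(xy: np.ndarray, bin_size: float = 3.0) -> PositionGrid:
    """Grid over occupied 2D bins, cleaned by morphological opening.

    Distances are shortest paths on the 4-connected adjacency graph of valid
    bins, scaled by ``bin_size``.
    """
    from scipy.ndimage import binary_closing, convolve

    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) < 1:
        raise ValueError("need at least one position")
    mins = xy.min(axis=0)
    maxs = xy.max(axis=0)
    nx_bins = max(1, int(np.ceil((maxs[0] - mins[0]) / bin_size - 1e-12)))
    ny_bins = max(1, int(np.ceil((maxs[1] - mins[1]) / bin_size - 1e-12)))
    ix = np.clip(((xy[:, 0] - mins[0]) / bin_size).astype(int), 0, nx_bins - 1)
    iy = np.clip(((xy[:, 1] - mins[1]) / bin_size).astype(int), 0, ny_bins - 1)
    occupied = np.zeros((nx_bins, ny_bins), dtype=bool)
    occupied[ix, iy] = True
    # morphological cleanup: fill unoccupied holes smaller than a bin, then
    # drop isolated occupied specks (single bins with no 4-neighbors).  A
    # full opening would erode track arms only one or two bins wide.
    padded = np.pad(occupied, 1)  # closing zero-pads and would erode borders
    mask = binary_closing(padded)[1:-1, 1:-1]
    cross = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    n_neighbors = convolve(mask.astype(int), cross, mode="constant")
    cleaned = mask & (n_neighbors > 0)
    if cleaned.any():
        mask = cleaned

    valid_idx = np.argwhere(mask)
    n = len(valid_idx)
    index_of = {tuple(p): i for i, p in enumerate(valid_idx)}
    adj = lil_matrix((n, n))
    for i, (gx, gy) in enumerate(valid_idx):
        for dx, dy in ((1, 0), (0, 1)):
            nb = (gx + dx, gy + dy)
            j = index_of.get(nb)
            if j is not None:
                adj[i, j] = bin_size
                adj[j, i] = bin_size
    dmat = _csgraph_shortest_path(adj.tocsr(), directed=False)

    centers_xy = np.column_stack(
        [mins[0] + (valid_idx[:, 0] + 0.5) * bin_size, mins[1] + (valid_idx[:, 1] + 0.5) * bin_size]
    )
    return PositionGrid(
        bin_centers=np.arange(n, dtype=float),
        bin_widths=np.full(n, bin_size),
        centers_xy=centers_xy,
        edge_ids=np.full(n, -1, dtype=int),
        edge_offsets=np.zeros(n),
        graph_distance=dmat,
        bin_size=bin_size,
        shape_2d=(nx_bins, ny_bins),
        valid_mask=mask,
    )


def project_to_track(
    track: TrackGraph, xy: np.ndarray, max_distance: float | None = None
) -> tuple[int, float, np.ndarray]:
    """Nearest-segment projection of a single 2D point.

    Returns (edge_id, offset_cm, projected_xy).  Raises if the point is
    farther than ``max_distance`` from every segment.
    """
    xy = np.asarray(xy, dtype=float)
    best = (None, None, None, np.inf)
    for s in range(track.n_edges):
        p, off = track.project_point(xy, s)
        d = float(np.linalg.norm(xy - p))
        if d < best[3]:
            best = (s, off, p, d)
    if max_distance is not None and best[3] > max_distance:
        raise ValueError(f"position {xy} is {best[3]:.1f} cm from the nearest track segment")
    return best[0], best[1], best[2]


def distance_from_animal(
    grid: PositionGrid,
    decoded_bin: int,
    animal_xy: np.ndarray,
    max_projection_distance: float | None = None,
) -> float:
    """Shortest along-track distance (cm) between a decoded bin center and
    the animal's 2D position projected onto the track."""
    if grid.track is None:
        raise ValueError("distance_from_animal requires a 1D track-graph grid")
    if not 0 <= decoded_bin < grid.n_bins:
        raise ValueError("decoded_bin out of range")
    seg, off, _ = project_to_track(grid.track, animal_xy, max_projection_distance)
    return grid.track.graph_distance_between_points(
        seg, off, int(grid.edge_ids[decoded_bin]), float(grid.edge_offsets[decoded_bin])
    )
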