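"""On-disk containers: CSV tables and compressed array archives.

Simple columnar dialects keep runs reproducible and diffable: position
series, spikes, and event/classification tables are CSV; marks, LFP, and
posteriors are compressed ``.npz`` archives with named arrays plus a JSON
metadata string carrying parameter provenance and the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MarkedSpikeSet, SpikeTrainSet
from .state_space import Posterior

__all__ = [
    "write_position_csv",
    "read_position_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_marks_npz",
    "read_marks_npz",
    "write_lfp_npz",
    "read_lfp_npz",
    "write_events_csv",
    "write_posterior_npz",
    "read_posterior_npz",
    "write_track_graph_csv",
    "config_hash",
]


def config_hash(params: dict) -> str:
    """Stable short hash of a parameter dictionary."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_position_csv(path, time, x, y=None) -> None:
    cols = {"time_s": np.asarray(time), "x_cm": np.asarray(x)}
    if y is not None:
        cols["y_cm"] = np.asarray(y)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_position_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spikes_csv(path, spikes: SpikeTrainSet) -> None:
    rows = [
        (int(cid), float(t))
        for cid, st in zip(spikes.cell_ids, spikes.spike_times)
        for t in st
    ]
    pd.DataFrame(rows, columns=["cell_id", "time_s"]).to_csv(path, index=False)


def read_spikes_csv(path, duration: float, n_cells: int | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path)
    if n_cells is None:
        n_cells = int(df["cell_id"].max()) + 1 if len(df) else 0
    trains = [
        df.loc[df["cell_id"] == i, "time_s"].to_numpy(dtype=float) for i in range(n_cells)
    ]
    return SpikeTrainSet(spike_times=trains, duration=duration)


def write_marks_npz(path, marks: MarkedSpikeSet) -> None:
    arrays = {"n_tetrodes": np.array(marks.n_tetrodes), "duration": np.array(marks.duration)}
    for i in range(marks.n_tetrodes):
        arrays[f"times_{i}"] = marks.spike_times[i]
        arrays[f"marks_{i}"] = marks.marks[i]
    np.savez_compressed(path, **arrays)


def read_marks_npz(path) -> MarkedSpikeSet:
    with np.load(path) as f:
        n = int(f["n_tetrodes"])
        return MarkedSpikeSet(
            spike_times=[f[f"times_{i}"] for i in range(n)],
            marks=[f[f"marks_{i}"] for i in range(n)],
            duration=float(f["duration"]),
        )


def write_lfp_npz(path, fs: float, traces: np.ndarray) -> None:
    np.savez_compressed(path, fs=np.array(fs), traces=np.asarray(traces))


def read_lfp_npz(path) -> tuple[float, np.ndarray]:
    with np.load(path) as f:
        return float(f["fs"]), f["traces"]


def write_events_csv(path, events) -> None:
    rows = [
        (s, e, events.kind, z, int(n))
        for (s, e), z, n in zip(events.intervals, events.peak_z, events.n_tetrodes)
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "kind", "peak_z", "n_tetrodes"]).to_csv(
        path, index=False
    )


def write_posterior_npz(path, post: Posterior, extra_metadata: dict | None = None) -> None:
    meta = dict(post.metadata)
    if extra_metadata:
        meta.update(extra_metadata)
    np.savez_compressed(
        path,
        causal=post.causal,
        acausal=post.acausal if post.acausal is not None else np.zeros(0),
        time_bin_edges=post.time_bin_edges,
        dynamics=np.array(post.dynamics),
        metadata=np.array(json.dumps(meta, default=str)),
    )


def read_posterior_npz(path) -> Posterior:
    with np.load(path, allow_pickle=False) as f:
        acausal = f["acausal"]
        return Posterior(
            causal=f["causal"],
            acausal=acausal if acausal.size else None,
            time_bin_edges=f["time_bin_edges"],
            dynamics=tuple(str(d) for d in f["dynamics"]),
            metadata=json.loads(str(f["metadata"])),
        )


def write_track_graph_csv(path_prefix, track) -> None:
    """Write ``<prefix>_nodes.csv`` (node coordinates) and ``<prefix>_edges.csv``."""
    prefix = Path(path_prefix)
    pd.DataFrame(
        {
            "node_id": np.arange(len(track.node_positions)),
            "x_cm": track.node_positions[:, 0],
            "y_cm": track.node_positions[:, 1],
        }
    ).to_csv(f"{prefix}_nodes.csv", index=False)
    pd.DataFrame(track.edges, columns=["node_a", "node_b"]).to_csv(
        f"{prefix}_edges.csv", index=False
    )
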