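"""Run configuration with the model's standard parameter defaults.

Defaults are the values used throughout the method: 3 cm position bins,
6 cm / 24 uV KDE bandwidths, 0.98 stay probability, 6.0 cm^2 random-walk
variance, 0.80 classification threshold, and SWR detection at z = 2 for
15 ms below 4 cm/s.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters and input paths for a reproducible pipeline run."""

    # inputs (optional; the demo pipeline generates its own)
    position_path: str | None = None
    spikes_path: str | None = None
    marks_path: str | None = None
    lfp_path: str | None = None
    events_path: str | None = None
    output_dir: str = "replaystate_output"

    # grid / encoding
    bin_size: float = 3.0               # cm
    knot_spacing: float = 5.0           # cm (sorted GLM)
    l2_penalty: float = 0.5
    bw_pos: float = 6.0                 # cm (clusterless KDE)
    bw_mark: float = 24.0               # uV
    speed_threshold: float = 4.0        # cm/s encoding-period gate

    # state space
    stay_prob: float = 0.98
    rw_variance: float = 6.0            # cm^2 per 2 ms step
    time_bin_width: float = 0.002       # s
    dynamics: tuple = ("stationary", "continuous", "fragmented")

    # classification
    classification_threshold: float = 0.80
    hpd_coverage: float = 0.95
    non_local_threshold: float = 30.0   # cm

    # event detection
    swr_z_threshold: float = 2.0
    swr_min_duration: float = 0.015     # s
    swr_speed_max: float = 4.0          # cm/s
    swr_smooth_sd: float = 0.004        # s
    min_tetrodes: int = 2

    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dynamics"] = list(self.dynamics)
        return d

    @property
    def hash(self) -> str:
        from .io import config_hash

        return config_hash(self.to_dict())

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        extras = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if "dynamics" in kwargs:
            kwargs["dynamics"] = tuple(kwargs["dynamics"])
        if extras:
            kwargs.setdefault("extras", {}).update(extras)
        return cls(**kwargs)
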