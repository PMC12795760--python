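"""Tubulin-cluster transport statistics.

Tracks are time series of positions along the axon axis (µm; injury site
at 0, anterograde positive). Net displacement is endpoint-to-endpoint.
Classification: retrograde if net < -0.2 µm (a dead band so jitter-only
tracks are not called retrograde), else anterograde-beyond-5-µm if
net > 5, else within-1-µm if |net| <= 1, else intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ANTERO_GT5, INTERMEDIATE, WITHIN_1, RETROGRADE = (
    "anterograde_gt5", "intermediate", "within_1um", "retrograde")


@dataclass
class Track:
    track_id: int
    time_s: np.ndarray
    position_um: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_um = np.asarray(self.position_um, dtype=float)
        if len(self.time_s) < 2:
            raise ValueError("a track needs at least two points")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class TransportSummary:
    n_tracks: int
    fraction_anterograde_gt5: float
    fraction_within_1um: float
    fraction_retrograde: float
    fraction_intermediate: float
    density_per_100um: float = float("nan")


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    out = []
    for tid, grp in table.groupby("track_id"):
        grp = grp.sort_values("time_s")
        out.append(Track(track_id=int(tid), time_s=grp["time_s"].to_numpy(),
                         position_um=grp["position_um"].to_numpy()))
    return out


def net_displacement(track: Track) -> float:
    """Signed net displacement (µm): last position minus first."""
    return float(track.position_um[-1] - track.position_um[0])


def classify_track(track: Track, anterograde_um: float = 5.0,
                   stationary_um: float = 1.0, deadband_um: float = 0.2) -> str:
    net = net_displacement(track)
    if net < -deadband_um:
        return RETROGRADE
    if net > anterograde_um:
        return ANTERO_GT5
    if abs(net) <= stationary_um:
        return WITHIN_1
    return INTERMEDIATE


def classify_tracks(tracks: list[Track], anterograde_um: float = 5.0,
                    stationary_um: float = 1.0, deadband_um: float = 0.2) -> TransportSummary:
    if not tracks:
        raise ValueError("need at least one track")
    classes = [classify_track(t, anterograde_um, stationary_um, deadband_um) for t in tracks]
    n = len(classes)
    return TransportSummary(
        n_tracks=n,
        fraction_anterograde_gt5=classes.count(ANTERO_GT5) / n,
        fraction_within_1um=classes.count(WITHIN_1) / n,
        fraction_retrograde=classes.count(RETROGRADE) / n,
        fraction_intermediate=classes.count(INTERMEDIATE) / n,
    )


def cluster_density(n_particles: int, axon_length_um: float) -> float:
    """Particles per 100 µm of axon."""
    if axon_length_um <= 0:
        raise ValueError("axon length must be positive")
    return n_particles / axon_length_um * 100.0
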