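"""Per-track migration statistics and zone-occupancy summaries.

Works on tracked-neuron tables (TrackMate-style exports or simulated
trajectories).  All distances are Euclidean in 2D (um), times in minutes;
statistics therefore stay comparable across tracks with unequal frame gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Track",
    "TrackStats",
    "ZoneGeometry",
    "track_distances",
    "mean_straight_line_speed",
    "directionality_index",
    "compute_stats",
    "assign_zone_groups",
    "split_crossing_tracks",
    "top_n_by_net_distance",
    "start_end_distribution",
]


@dataclass
class Track:
    """A timed 2D trajectory: samples are ordered (t_min, x_um, y_um)."""

    track_id: str
    samples: np.ndarray  # (N, 3)
    channel: str = "green"

    def __post_init__(self) -> None:
        self.track_id = str(self.track_id)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (N, 3) array of (t, x, y)")
        if self.samples.shape[0] >= 2 and np.any(np.diff(self.samples[:, 0]) <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:]

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class TrackStats:
    d_tot: float
    d_net: float
    t_net: float
    mean_straight_line_speed: float
    directionality: float


@dataclass(frozen=True)
class ZoneGeometry:
    """Boundary between the lower (VZ/SVZ + IZ) and upper (CP) zones."""

    y_mid: float
    pial_side: str = "high"  # "high": larger y is pial

    def is_upper(self, y: np.ndarray | float) -> np.ndarray | bool:
        """Strictly-above convention: samples exactly on y_mid are lower."""
        y = np.asarray(y, dtype=float)
        out = y > self.y_mid if self.pial_side == "high" else y < self.y_mid
        return bool(out) if out.ndim == 0 else out


def _require_samples(track: Track, n: int) -> None:
    if len(track) < n:
        raise ValueError(f"track {track.track_id}: need >= {n} samples")


def track_distances(track: Track) -> tuple[float, float, float]:
    """Return (d_tot, d_net, t_net).

    d_tot is the summed inter-frame Euclidean path length, d_net the
    straight-line start-to-end distance, t_net the elapsed time.
    """
    _require_samples(track, 2)
    steps = np.diff(track.xy, axis=0)
    d_tot = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    d_net = float(np.hypot(*(track.xy[-1] - track.xy[0])))
    t_net = float(track.times[-1] - track.times[0])
    return d_tot, d_net, t_net


def mean_straight_line_speed(track: Track) -> float:
    """d_net / t_net in um/min (robust to per-track frame-gap differences)."""
    _, d_net, t_net = track_distances(track)
    if t_net <= 0:
        raise ValueError(f"track {track.track_id}: non-positive elapsed time")
    return d_net / t_net


def directionality_index(track: Track) -> float:
    """Meandering index d_net / d_tot in [0, 1]; 1 for a straight path."""
    d_tot, d_net, _ = track_distances(track)
    if d_tot == 0:
        raise ValueError(f"track {track.track_id}: stationary track, index undefined")
    return min(d_net / d_tot, 1.0)


def compute_stats(track: Track) -> TrackStats:
    d_tot, d_net, t_net = track_distances(track)
    if t_net <= 0:
        raise ValueError(f"track {track.track_id}: non-positive elapsed time")
    if d_tot == 0:
        raise ValueError(f"track {track.track_id}: stationary track")
    return TrackStats(
        d_tot=d_tot,
        d_net=d_net,
        t_net=t_net,
        mean_straight_line_speed=d_net / t_net,
        directionality=min(d_net / d_tot, 1.0),
    )


def assign_zone_groups(
    tracks: list[Track], geometry: ZoneGeometry
) -> dict[str, list[Track]]:
    """Partition tracks by the any-frame rule.

    A track belongs to the upper zone if in *any* frame the cell was in the
    upper zone; to the lower zone only if it never was.
    """
    groups: dict[str, list[Track]] = {"upper": [], "lower": []}
    for tr in tracks:
        key = "upper" if np.any(geometry.is_upper(tr.xy[:, 1])) else "lower"
        groups[key].append(tr)
    return groups


def split_crossing_tracks(track: Track, y_mid: float) -> tuple[list[Track], bool]:
    """Split a track into sub-tracks at each strict crossing of ``y_mid``.

    The sample after a crossing starts the new sub-track (no interpolated
    sample is inserted).  Returns (sub_tracks, crossed).
    """
    above = track.xy[:, 1] > y_mid
    change = np.flatnonzero(above[1:] != above[:-1]) + 1
    if change.size == 0:
        return [track], False
    pieces = np.split(np.arange(len(track)), change)
    subs = [
        Track(
            track_id=f"{track.track_id}.{k}",
            samples=track.samples[idx],
            channel=track.channel,
        )
        for k, idx in enumerate(pieces)
    ]
    return subs, True


def top_n_by_net_distance(tracks: list[Track], n: int = 15) -> list[Track]:
    """Rank tracks by d_net descending; ties broken by track_id (stable)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    keyed = sorted(
        tracks, key=lambda tr: (-track_distances(tr)[1], tr.track_id)
    )
    return keyed[: min(n, len(keyed))]


def start_end_distribution(
    tracks: list[Track],
    geometry: ZoneGeometry,
    t_start: float,
    t_end: float,
    max_gap: float | None = None,
) -> dict[str, dict[str, float]]:
    """Per-zone fractions of cells at two timepoints.

    Yellow-labelled tracks are excluded.  A track contributes to a timepoint
    only if it has a sample within ``max_gap`` minutes of it (default: one
    median frame interval); tracks without one are skipped with a warning.
    """
    result: dict[str, dict[str, float]] = {}
    usable = [tr for tr in tracks if tr.channel != "yellow"]
    n_yellow = len(tracks) - len(usable)
    if n_yellow:
        warnings.warn(f"excluded {n_yellow} yellow track(s)", stacklevel=2)
    for name, t_ref in (("start", t_start), ("end", t_end)):
        upper = lower = 0
        for tr in usable:
            gap = (
                max_gap
                if max_gap is not None
                else float(np.median(np.diff(tr.times))) if len(tr) > 1 else 0.0
            )
            dt = np.abs(tr.times - t_ref)
            i = int(np.argmin(dt))
            if dt[i] > gap:
                warnings.warn(
                    f"track {tr.track_id}: no sample near t={t_ref}; excluded",
                    stacklevel=2,
                )
                continue
            if geometry.is_upper(tr.xy[i, 1]):
                upper += 1
            else:
                lower += 1
        total = upper + lower
        result[name] = {
            "upper": upper / total if total else float("nan"),
            "lower": lower / total if total else float("nan"),
            "n": float(total),
        }
    if not usable:
        warnings.warn("no usable (non-yellow) tracks", stacklevel=2)
    return result
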