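"""Migration metrics from time-lapse cell tracks.

Tracks are ordered, time-stamped 2-D positions (minutes, micrometres) of
individual migrating interneurons imaged every few minutes in slice
grafts.  The first hour of each movie is discarded before measurement
(slices settle in the chamber), then two per-track metrics are computed:

* speed = total path length / observed duration (um/h)
* directional persistence = net displacement / total path length, in [0, 1]

Two graft groups (e.g. PSB- vs CGE-derived cells) are compared per metric
with an unpaired two-sided Student's t-test (pooled variance; Welch
available via a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "MigrationMetrics",
    "TrackExcludedError",
    "preprocess_track",
    "preprocess_tracks",
    "track_metrics",
    "compare_groups",
    "tracks_to_frame",
    "tracks_from_frame",
]


class TrackExcludedError(ValueError):
    """Raised when preprocessing leaves fewer than two usable samples."""


@dataclass
class Track:
    """One cell's trajectory: strictly increasing times (min), x/y in um."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError(f"track {self.track_id}: t/x/y must be 1-D and equal length")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class MigrationMetrics:
    track_id: str
    group: str
    speed: float  # um per hour
    persistence: float  # net displacement / path length, in [0, 1]
    path_length: float  # um
    net_displacement: float  # um
    duration: float  # hours
    stationary: bool = False


def preprocess_track(
    track: Track,
    burn_in_min: float = 60.0,
    max_gap_frames: int = 2,
) -> list[Track]:
    """Trim burn-in, bridge short gaps, split on long ones.

    Samples with t < ``burn_in_min`` are dropped and times re-zeroed to
    the first retained sample.  Gaps of up to ``max_gap_frames`` missing
    frames (frame interval = median sampling step) are linearly bridged;
    longer gaps split the track into independently re-zeroed segments
    (ids suffixed ``/1``, ``/2``, ...).  Raises
    :class:`TrackExcludedError` if fewer than two samples survive.
    """
    if len(track) == 0:
        raise TrackExcludedError(f"track {track.track_id}: empty track")
    if np.any(np.diff(track.t) <= 0):
        raise ValueError(f"track {track.track_id}: timestamps must be strictly increasing")

    keep = track.t >= burn_in_min
    t, x, y = track.t[keep], track.x[keep], track.y[keep]
    if t.size < 2:
        raise TrackExcludedError(
            f"track {track.track_id}: fewer than 2 samples after {burn_in_min}-min burn-in"
        )

    dt = float(np.median(np.diff(t)))
    gaps = np.diff(t)
    # split where more than max_gap_frames frames are missing
    split_after = np.flatnonzero(gaps > (max_gap_frames + 1) * dt + 1e-9)
    bounds = [0, *list(split_after + 1), t.size]
    segments: list[Track] = []
    multi = len(bounds) > 2
    for si in range(len(bounds) - 1):
        lo, hi = bounds[si], bounds[si + 1]
        if hi - lo < 2:
            continue
        ts, xs, ys = t[lo:hi], x[lo:hi], y[lo:hi]
        # bridge remaining short gaps onto the regular frame grid
        grid = np.round((ts - ts[0]) / dt).astype(int)
        full = np.arange(grid[-1] + 1)
        if full.size != grid.size:
            xs = np.interp(full, grid, xs)
            ys = np.interp(full, grid, ys)
            ts = ts[0] + full * dt
        tid = f"{track.track_id}/{si + 1}" if multi else track.track_id
        segments.append(Track(tid, ts - ts[0], xs, ys, group=track.group))
    if not segments:
        raise TrackExcludedError(
            f"track {track.track_id}: no segment with >= 2 samples after gap splitting"
        )
    return segments


def preprocess_tracks(
    tracks: list[Track],
    burn_in_min: float = 60.0,
    max_gap_frames: int = 2,
) -> tuple[list[Track], dict[str, str]]:
    """Preprocess many tracks; returns (kept segments, exclusions with reasons)."""
    kept: list[Track] = []
    excluded: dict[str, str] = {}
    for tr in tracks:
        try:
            kept.extend(preprocess_track(tr, burn_in_min, max_gap_frames))
        except TrackExcludedError as e:
            excluded[tr.track_id] = str(e)
    return kept, excluded


def track_metrics(track: Track) -> MigrationMetrics:
    """Speed, persistence, path length, net displacement for one track."""
    if len(track) < 2:
        raise ValueError(f"track {track.track_id}: need >= 2 samples")
    if np.any(np.diff(track.t) == 0):
        raise ValueError(f"track {track.track_id}: duplicate timestamps")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(steps.sum())
    net = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    duration_h = float(track.t[-1] - track.t[0]) / 60.0
    stationary = path == 0.0
    return MigrationMetrics(
        track_id=track.track_id,
        group=track.group,
        speed=path / duration_h,
        persistence=0.0 if stationary else net / path,
        path_length=path,
        net_displacement=net,
        duration=duration_h,
        stationary=stationary,
    )


def metrics_frame(metrics: list[MigrationMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metrics]).set_index("track_id")


def compare_groups(
    metrics_a: list[MigrationMetrics],
    metrics_b: list[MigrationMetrics],
    welch: bool = False,
    fields: tuple[str, ...] = ("speed", "persistence"),
) -> dict[str, dict[str, float]]:
    """Per-metric group means +- s.e.m. and an unpaired two-sided t-test.

    Pooled-variance Student's t by default; ``welch=True`` switches to the
    unequal-variance form.  Degenerate case (zero variance in both groups,
    equal means) reports t = 0, p = 1.
    """
    if len(metrics_a) < 2 or len(metrics_b) < 2:
        raise ValueError("each group needs at least 2 tracks")
    out: dict[str, dict[str, float]] = {}
    for f in fields:
        a = np.array([getattr(m, f) for m in metrics_a], dtype=float)
        b = np.array([getattr(m, f) for m in metrics_b], dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        if not np.isfinite(t):  # zero variance in both groups
            t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
        out[f] = {
            "mean_a": float(a.mean()),
            "sem_a": float(stats.sem(a)),
            "mean_b": float(b.mean()),
            "sem_b": float(stats.sem(b)),
            "n_a": len(a),
            "n_b": len(b),
            "t": float(t),
            "p": float(p),
        }
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tidy long-form table (track_id, group, t_min, x_um, y_um)."""
    rows = []
    for tr in tracks:
        rows.append(
            pd.DataFrame(
                {"track_id": tr.track_id, "group": tr.group, "t_min": tr.t, "x_um": tr.x, "y_um": tr.y}
            )
        )
    return pd.concat(rows, ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_min")
        group = str(g["group"].iloc[0]) if "group" in g else ""
        tracks.append(Track(str(tid), g["t_min"].to_numpy(), g["x_um"].to_numpy(), g["y_um"].to_numpy(), group))
    return tracks
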