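"""Track-table I/O, track filtering, lifetimes, density and velocity.

A *track table* is a :class:`pandas.DataFrame` with one row per localization
and columns ``track_id, channel, frame, x, y, amplitude``.  Rows belonging to
one particle track share ``(track_id, channel)`` and must occupy contiguous
frames (the upstream trackers emit gap-closed tracks).  Coordinates are
0-based pixel positions with the origin at the top-left corner and y
increasing downward; frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

TRACK_COLUMNS = ["track_id", "channel", "frame", "x", "y", "amplitude"]

#: minimum track length, in frames, for a lifetime to be analyzable
MIN_TRACK_FRAMES = 5

#: margin, in frames and pixels, of the standard track filter
EDGE_FRAMES = 10
EDGE_PIXELS = 10.0


@dataclass(frozen=True)
class MovieMeta:
    """Acquisition metadata of a time-lapse movie.

    Parameters
    ----------
    width, height : int
        Movie dimensions in pixels.
    n_frames : int
        Number of frames.
    frame_rate : float
        Acquisition rate in frames per second; the frame interval
        ``dt = 1 / frame_rate`` sets the time resolution of every lifetime.
    pixel_size : float, optional
        Pixel edge in micrometers, used only to express densities per area.
    """

    width: int
    height: int
    n_frames: int
    frame_rate: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.n_frames < 1:
            raise ValueError("movie dimensions and frame count must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive when given")

    @property
    def frame_interval(self) -> float:
        """Frame interval dt in seconds."""
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        """Total imaging time in seconds (= upper lifetime bound)."""
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class LifetimeDataset:
    """Observed track lifetimes together with their truncation window.

    Lifetimes are in seconds and are integer multiples of the frame interval.
    The window ``[t_low, t_high]`` is imposed by the five-frame minimum track
    length and by the movie duration; the mixture fit must use densities
    renormalized to this window.
    """

    lifetimes: np.ndarray
    frame_interval: float
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lifetimes", np.asarray(self.lifetimes, dtype=float))
        dt = self.frame_interval
        if dt <= 0:
            raise ValueError("frame_interval must be positive")
        if not np.isclose(self.t_low, 5 * dt):
            raise ValueError(f"t_low must equal 5 frame intervals, got {self.t_low}")
        if self.t_low >= self.t_high:
            raise ValueError("t_low must be smaller than t_high")
        lt = self.lifetimes
        if lt.size and (lt.min() < self.t_low - 1e-9 or lt.max() > self.t_high + 1e-9):
            raise ValueError("lifetimes outside the truncation window")
        frames = lt / dt
        if lt.size and np.abs(frames - np.round(frames)).max() > 1e-6:
            off = lt[np.abs(frames - np.round(frames)) > 1e-6][0]
            raise ValueError(f"lifetime {off} is not an integer multiple of dt={dt}")

    @property
    def n_lifetimes(self) -> int:
        return int(self.lifetimes.size)


def _require_columns(df: pd.DataFrame) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table is missing column(s): {', '.join(missing)}")


def _validate_rows(df: pd.DataFrame, movie: MovieMeta) -> None:
    frame = df["frame"].to_numpy()
    bad = np.flatnonzero((frame < 0) | (frame >= movie.n_frames))
    if bad.size:
        raise ValueError(
            f"row {bad[0]}: frame {frame[bad[0]]} outside [0, {movie.n_frames})"
        )
    for axis, bound in (("x", movie.width), ("y", movie.height)):
        v = df[axis].to_numpy()
        bad = np.flatnonzero((v < 0) | (v >= bound))
        if bad.size:
            raise ValueError(
                f"row {bad[0]}: {axis}={v[bad[0]]} outside [0, {bound})"
            )


def _check_contiguous(df: pd.DataFrame) -> None:
    for (tid, ch), grp in df.groupby(["track_id", "channel"], sort=False):
        f = grp["frame"].to_numpy()
        if f.size > 1 and not np.array_equal(np.diff(f), np.ones(f.size - 1)):
            raise ValueError(
                f"track {tid!r} (channel {ch!r}) has non-contiguous frames"
            )


def read_track_table(path: str | Path, movie: MovieMeta) -> pd.DataFrame:
    """Read a delimited track table and validate it against the movie.

    Rows are grouped into tracks by ``(track_id, channel)`` and sorted by
    frame.  A missing column, an out-of-bounds coordinate or frame, or a
    track with frame gaps raises :class:`ValueError`.
    """
    df = pd.read_csv(path)
    if df.empty and not df.columns.size:
        raise ValueError("track table is empty (no header)")
    _require_columns(df)
    df = df.loc[:, TRACK_COLUMNS]
    _validate_rows(df, movie)
    df = df.sort_values(["track_id", "channel", "frame"], kind="stable")
    df = df.reset_index(drop=True)
    _check_contiguous(df)
    return df


def write_track_table(tracks: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as comma-delimited UTF-8 text (lossless floats)."""
    _require_columns(tracks)
    tracks.loc[:, TRACK_COLUMNS].to_csv(path, index=False)


def filter_tracks(tracks: pd.DataFrame, movie: MovieMeta) -> pd.DataFrame:
    """Apply the standard single-channel track filter.

    A track is retained iff it (a) is absent from the first and last 10
    frames of the movie, (b) never comes within 10 pixels of any movie edge,
    and (c) persists for at least 5 frames.  Tracks are never modified and
    input order is preserved; the operation is idempotent.
    """
    _require_columns(tracks)
    if tracks.empty:
        return tracks.copy()
    g = tracks.groupby(["track_id", "channel"], sort=False)
    stats = g.agg(
        first=("frame", "min"),
        last=("frame", "max"),
        n=("frame", "size"),
        xmin=("x", "min"),
        xmax=("x", "max"),
        ymin=("y", "min"),
        ymax=("y", "max"),
    )
    ok = (
        (stats["first"] >= EDGE_FRAMES)
        & (stats["last"] <= movie.n_frames - EDGE_FRAMES - 1)
        & (stats["n"] >= MIN_TRACK_FRAMES)
        & (stats["xmin"] >= EDGE_PIXELS)
        & (stats["xmax"] < movie.width - EDGE_PIXELS)
        & (stats["ymin"] >= EDGE_PIXELS)
        & (stats["ymax"] < movie.height - EDGE_PIXELS)
    )
    keep = set(stats.index[ok])
    mask = [
        (tid, ch) in keep
        for tid, ch in zip(tracks["track_id"], tracks["channel"])
    ]
    return tracks.loc[mask].reset_index(drop=True)


class TrackFilter(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping :func:`filter_tracks`.

    Stateless; ``fit`` only records bookkeeping counts so the filter can sit
    in a :class:`sklearn.pipeline.Pipeline` next to downstream estimators.
    """

    def __init__(self, movie: MovieMeta | None = None):
        self.movie = movie

    def fit(self, X: pd.DataFrame, y=None) -> "TrackFilter":
        if self.movie is None:
            raise ValueError("TrackFilter requires a MovieMeta")
        self.n_tracks_in_ = int(
            X.groupby(["track_id", "channel"]).ngroups
        ) if len(X) else 0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.movie is None:
            raise ValueError("TrackFilter requires a MovieMeta")
        return filter_tracks(X, self.movie)


def lifetimes_from_tracks(tracks: pd.DataFrame, movie: MovieMeta) -> LifetimeDataset:
    """Convert filtered tracks to a :class:`LifetimeDataset`.

    The lifetime of a track is its frame count times the frame interval.
    Tracks shorter than five frames (which the filter should have removed)
    raise :class:`ValueError`.
    """
    _require_columns(tracks)
    dt = movie.frame_interval
    counts = tracks.groupby(["track_id", "channel"], sort=False)["frame"].size()
    if (counts < MIN_TRACK_FRAMES).any():
        tid = counts.index[counts < MIN_TRACK_FRAMES][0]
        raise ValueError(
            f"track {tid!r} has fewer than {MIN_TRACK_FRAMES} frames; "
            "run filter_tracks first"
        )
    return LifetimeDataset(
        lifetimes=counts.to_numpy(dtype=float) * dt,
        frame_interval=dt,
        t_low=5 * dt,
        t_high=movie.n_frames * dt,
    )


def compute_density(
    tracks: pd.DataFrame,
    movie: MovieMeta,
    *,
    roi_side: int = 100,
    window: int = 100,
    per_area: bool = False,
) -> float:
    """Mean number of tracks present in a centered ROI per frame.

    A square ``roi_side`` x ``roi_side`` pixel ROI is placed in the center of
    the movie; for each of ``window`` frames centered on the middle frame the
    tracks with at least one localization inside the ROI are counted, and the
    counts are averaged.  With ``per_area=True`` (requires ``pixel_size``)
    the mean count is expressed per square micrometer.
    """
    if movie.width < roi_side or movie.height < roi_side:
        raise ValueError(f"movie smaller than the {roi_side}x{roi_side} px ROI")
    if movie.n_frames < window + 1:
        raise ValueError(f"movie shorter than {window + 1} frames")
    _require_columns(tracks)
    mid = movie.n_frames // 2
    f0, f1 = mid - window // 2, mid + window // 2  # [f0, f1)
    x0 = (movie.width - roi_side) // 2
    y0 = (movie.height - roi_side) // 2
    if tracks.empty:
        mean_count = 0.0
    else:
        inside = (
            (tracks["frame"] >= f0)
            & (tracks["frame"] < f1)
            & (tracks["x"] >= x0)
            & (tracks["x"] < x0 + roi_side)
            & (tracks["y"] >= y0)
            & (tracks["y"] < y0 + roi_side)
        )
        sub = tracks.loc[inside]
        # one count per track per frame, even with several localizations
        counts = (
            sub.drop_duplicates(["frame", "track_id", "channel"])
            .groupby("frame")
            .size()
        )
        mean_count = float(counts.sum()) / window
    if per_area:
        if movie.pixel_size is None:
            raise ValueError("per_area requires MovieMeta.pixel_size")
        return mean_count / (roi_side * movie.pixel_size) ** 2
    return mean_count


def max_frame_velocity(track: pd.DataFrame, movie: MovieMeta) -> float:
    """Maximum frame-to-frame speed of a single track, in pixels per second.

    Organelle tracks are profiled by the maximum velocity they exhibit; this
    is the largest Euclidean displacement between consecutive frames divided
    by the frame interval.
    """
    if len(track) < 2:
        raise ValueError("velocity requires a track with at least 2 frames")
    t = track.sort_values("frame")
    dx = np.diff(t["x"].to_numpy())
    dy = np.diff(t["y"].to_numpy())
    step = np.hypot(dx, dy)
    return float(step.max() * movie.frame_rate)
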