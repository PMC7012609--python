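"""Cohort-averaged intensity profiles and CCP phase segmentation.

A clathrin-coated pit develops in three phases visible in its fluorescence
time course: a roughly linear assembly rise, a maturation plateau, and a
sharp scission drop.  The cohort profile averages the normalized intensity
trajectories of tracks whose lifetime lies within +/-3 frames of the overall
mean lifetime; the phase transitions are read off the slope of the smoothed
profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tracks import MovieMeta, _require_columns

COHORT_HALF_WINDOW = 3  # frames around the mean track length

#: default lowess span: ~3-point window at typical cohort lengths, kept
#: below half the shortest phase so the maturation plateau survives
DEFAULT_SPAN = 0.08

#: phase transitions sit where the slope crosses this fraction of the
#: relevant extreme slope
SLOPE_THRESHOLD_FRACTION = 0.2


@dataclass(frozen=True)
class MeanProfile:
    """Cohort-averaged normalized intensity profile.

    ``offsets`` are in seconds, spaced by the frame interval: from 0 at
    track start (start-aligned) or ending at 0 at the master-track departure
    (end-aligned).  ``sem`` is the pointwise standard error over the cohort.
    """

    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_tracks: int
    cohort_window: tuple[int, int]  # (min, max) track length in frames

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if not (self.offsets.size == self.mean.size == self.sem.size):
            raise ValueError("offsets, mean and sem must have equal length")
        if self.n_tracks < 1:
            raise ValueError("a profile requires at least one track")
        if self.offsets.size >= 2:
            d = np.diff(self.offsets)
            if np.abs(d - d[0]).max() > 1e-9:
                raise ValueError("offsets must be uniformly spaced")
        if np.any(self.sem < 0):
            raise ValueError("SEM must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_s": self.offsets, "mean": self.mean, "sem": self.sem,
             "n": self.n_tracks}
        )


@dataclass(frozen=True)
class PhaseSegmentation:
    """Assembly/maturation/scission segmentation of a cohort profile."""

    assembly_end: float       # seconds from profile start
    maturation_end: float     # seconds from profile start
    fractions: tuple[float, float, float]
    thresholds: tuple[float, float]  # (rise, fall) slope thresholds, 1/s

    def __post_init__(self) -> None:
        if not (0 < self.assembly_end < self.maturation_end):
            raise ValueError("need 0 < assembly_end < maturation_end")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")


def _normalized_trajectories(tracks: pd.DataFrame, channel=None):
    """Per-track amplitude series normalized to unit (smoothed) peak."""
    _require_columns(tracks)
    if channel is not None:
        tracks = tracks[tracks["channel"] == channel]
    out = []
    for _, grp in tracks.groupby(["track_id", "channel"], sort=False):
        y = grp.sort_values("frame")["amplitude"].to_numpy(dtype=float)
        out.append(y)
    return out


def _normalize(y: np.ndarray) -> np.ndarray:
    # peak from a lightly smoothed copy so a single noise spike does not
    # set the scale
    if y.size >= 5:
        t = np.arange(y.size, dtype=float)
        peak = lowess(y, t, frac=max(0.3, 5 / y.size), return_sorted=False).max()
    else:
        peak = y.max()
    if peak <= 0:
        peak = max(y.max(), np.finfo(float).tiny)
    return y / peak


def mean_cohort_profile(
    tracks: pd.DataFrame,
    movie: MovieMeta,
    mode: str = "start",
    channel=None,
    half_window: int = COHORT_HALF_WINDOW,
) -> MeanProfile:
    """Average the normalized trajectories of mean-lifetime cohort tracks.

    Tracks whose length is within ``half_window`` frames of the rounded mean
    track length form the cohort.  Each trajectory is normalized to unit
    peak and the cohort is averaged on a common grid:

    * ``mode="start"`` (cohort profile): trajectories are rescaled to the
      cohort mean length before averaging, so phase positions expressed as
      fractions of the lifetime line up across tracks.
    * ``mode="end"`` (departure alignment): trajectories are aligned on
      their final frame and averaged pointwise in real time, as required
      when the offset axis is time relative to departure.
    """
    if mode not in ("start", "end"):
        raise ValueError("mode must be 'start' or 'end'")
    trajs = _normalized_trajectories(tracks, channel)
    if not trajs:
        raise ValueError("no tracks available for a cohort profile")
    lengths = np.array([len(y) for y in trajs])
    mean_len = int(round(lengths.mean()))
    cohort = [y for y in trajs if abs(len(y) - mean_len) <= half_window]
    if not cohort:
        raise ValueError(
            f"empty cohort: no track length within +/-{half_window} frames "
            f"of the mean length {mean_len}"
        )
    dt = movie.frame_interval
    m = len(cohort)
    window = (min(len(y) for y in cohort), max(len(y) for y in cohort))

    if mode == "start":
        L = int(round(np.mean([len(y) for y in cohort])))
        grid = np.linspace(0.0, 1.0, L)
        stack = np.array(
            [np.interp(grid, np.linspace(0.0, 1.0, len(y)), _normalize(y))
             for y in cohort]
        )
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(L)
        offsets = dt * np.arange(L)
    else:
        M = max(len(y) for y in cohort)
        stack = np.full((m, M), np.nan)
        for i, y in enumerate(cohort):
            stack[i, M - len(y):] = _normalize(y)
        mean = np.nanmean(stack, axis=0)
        n_at = np.sum(~np.isnan(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if m > 1 else np.zeros(M)
        sem = np.where(n_at > 1, sd / np.sqrt(np.maximum(n_at, 1)), 0.0)
        offsets = dt * (np.arange(M) - (M - 1))
    return MeanProfile(offsets, mean, np.nan_to_num(sem), m, window)


def smooth_profile(profile: MeanProfile, span: float = DEFAULT_SPAN) -> MeanProfile:
    """Smooth the mean series with a lowess (locally linear) curve.

    ``span`` is the fraction of points in each local regression window.
    Offsets, SEM and cohort bookkeeping are unchanged.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if profile.mean.size < 5:
        raise ValueError("profile too short to smooth")
    sm = lowess(profile.mean, profile.offsets, frac=span, return_sorted=False)
    return MeanProfile(profile.offsets, sm, profile.sem, profile.n_tracks,
                       profile.cohort_window)


def _interp_crossing(s: np.ndarray, j: int, thr: float, direction: int) -> float:
    """Sub-frame index where the slope trace crosses ``thr`` next to ``j``."""
    k = j - direction
    if s[k] == s[j]:
        return float(j)
    frac = (s[k] - thr) / (s[k] - s[j])
    return k + direction * frac


def segment_phases(
    profile: MeanProfile,
    threshold_fraction: float = SLOPE_THRESHOLD_FRACTION,
) -> PhaseSegmentation:
    """Segment a smoothed rise-plateau-fall profile into the three phases.

    The slope series (central differences) must have a positive maximum
    (the assembly rise) and a negative minimum (the scission fall).  The
    assembly->maturation transition is the first point after the slope
    maximum where the slope drops below ``threshold_fraction`` of the
    maximum slope; the maturation->scission transition is the last point
    before the slope minimum where the slope still exceeds
    ``threshold_fraction`` of the minimum slope.  Crossings are interpolated
    to sub-frame resolution; fractions are transition times over the profile
    span.  Both thresholds are relative to the slope extremes, so the
    segmentation is invariant to scaling and shifting the intensities.
    """
    y, t = profile.mean, profile.offsets
    if y.size < 5:
        raise ValueError("profile too short to segment")
    s = np.gradient(y, t)
    imax, imin = int(np.argmax(s)), int(np.argmin(s))
    if s[imax] <= 0 or s[imin] >= 0 or imax >= imin:
        raise ValueError("phases not identifiable: profile has no rise/fall")
    thr_up = threshold_fraction * s[imax]
    thr_dn = threshold_fraction * s[imin]

    after = s[imax:] < thr_up
    if not after.any():
        raise ValueError("phases not identifiable: slope never leaves the rise")
    j = imax + int(np.argmax(after))
    i1 = _interp_crossing(s, j, thr_up, +1) if j > imax else float(imax)

    before = s[: imin + 1][::-1] > thr_dn
    if not before.any():
        raise ValueError("phases not identifiable: slope never leaves the fall")
    k = imin - int(np.argmax(before))
    i2 = _interp_crossing(s, k, thr_dn, -1) if k < imin else float(imin)

    if i2 < i1:  # degenerate plateau (triangle); transitions coincide
        i1 = i2 = 0.5 * (i1 + i2)
    T = y.size - 1
    dt = t[1] - t[0]
    f1, f2 = i1 / T, i2 / T
    fractions = (f1, f2 - f1, 1.0 - f2)
    return PhaseSegmentation(
        assembly_end=float(max(i1, 1e-12) * dt),
        maturation_end=float(max(i2, 2e-12) * dt),
        fractions=tuple(float(v) for v in fractions),
        thresholds=(float(thr_up), float(thr_dn)),
    )


class PhaseSegmenter(BaseEstimator):
    """Estimator wrapper around smoothing + phase segmentation.

    ``fit`` takes a :class:`MeanProfile` and exposes the recovered
    transition times and phase fractions as fitted attributes.
    """

    def __init__(self, span: float = DEFAULT_SPAN,
                 threshold_fraction: float = SLOPE_THRESHOLD_FRACTION,
                 smooth: bool = True):
        self.span = span
        self.threshold_fraction = threshold_fraction
        self.smooth = smooth

    def fit(self, X: MeanProfile, y=None) -> "PhaseSegmenter":
        prof = smooth_profile(X, self.span) if self.smooth else X
        seg = segment_phases(prof, self.threshold_fraction)
        self.segmentation_ = seg
        self.assembly_end_ = seg.assembly_end
        self.maturation_end_ = seg.maturation_end
        self.fractions_ = seg.fractions
        self.smoothed_profile_ = prof
        return self


def departure_profile(
    master: pd.DataFrame,
    slave: pd.DataFrame,
    movie: MovieMeta,
    half_window: int = COHORT_HALF_WINDOW,
) -> tuple[MeanProfile, MeanProfile]:
    """Two-channel departure assay: align both channels on master track end.

    Master tracks within the mean +/- ``half_window`` frame cohort are
    aligned on their final frame (departure = offset 0); the slave-channel
    amplitudes of the same track ids are averaged on the same offsets.
    Track ids present in only one channel raise ValueError.
    """
    _require_columns(master)
    _require_columns(slave)
    m_ids = set(master["track_id"].unique())
    s_ids = set(slave["track_id"].unique())
    unmatched = sorted(m_ids.symmetric_difference(s_ids))
    if unmatched:
        raise ValueError(f"unmatched track ids between channels: {unmatched}")

    m_trajs, s_trajs, m_ends = {}, {}, {}
    for tid, grp in master.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        m_trajs[tid] = grp["amplitude"].to_numpy(dtype=float)
        m_ends[tid] = int(grp["frame"].iloc[-1])
    for tid, grp in slave.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        s_trajs[tid] = (grp["frame"].to_numpy(int), grp["amplitude"].to_numpy(float))

    lengths = np.array([len(v) for v in m_trajs.values()])
    mean_len = int(round(lengths.mean()))
    cohort = [tid for tid, v in m_trajs.items()
              if abs(len(v) - mean_len) <= half_window]
    if not cohort:
        raise ValueError(
            f"empty master cohort around mean length {mean_len}"
        )

    dt = movie.frame_interval
    max_back = max(
        max(len(m_trajs[tid]), m_ends[tid] - int(s_trajs[tid][0][0]) + 1)
        for tid in cohort
    )
    m_stack = np.full((len(cohort), max_back), np.nan)
    s_stack = np.full((len(cohort), max_back), np.nan)
    for i, tid in enumerate(cohort):
        ym = _normalize(m_trajs[tid])
        m_stack[i, max_back - len(ym):] = ym
        fr, ys = s_trajs[tid]
        ys = _normalize(ys)
        pos = max_back - 1 - (m_ends[tid] - fr)  # offset of each slave frame
        ok = (pos >= 0) & (pos < max_back)
        s_stack[i, pos[ok]] = ys[ok]

    offsets = dt * (np.arange(max_back) - (max_back - 1))
    window = (min(len(m_trajs[t]) for t in cohort),
              max(len(m_trajs[t]) for t in cohort))

    def reduce(stack, keep):
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack[:, keep], axis=0)
            sd = np.nanstd(stack[:, keep], axis=0, ddof=1)
        n_at = np.sum(~np.isnan(stack[:, keep]), axis=0)
        sem = np.where(n_at > 1, sd / np.sqrt(np.maximum(n_at, 1)), 0.0)
        return np.nan_to_num(mean), np.nan_to_num(sem)

    # keep the offsets where the master cohort has data
    keep = np.sum(~np.isnan(m_stack), axis=0) > 0
    m_mean, m_sem = reduce(m_stack, keep)
    s_mean, s_sem = reduce(s_stack, keep)
    mp = MeanProfile(offsets[keep], m_mean, m_sem, len(cohort), window)
    sp = MeanProfile(offsets[keep], s_mean, s_sem, len(cohort), window)
    return mp, sp
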