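"""Endosomal pick-up analysis.

In plant cells the early endosome / trans-Golgi network (EE/TGN) is a
mobile compartment that passes beneath the plasma membrane.  The pick-up
statistic asks whether endocytic (clathrin) tracks preferentially *end*
while such an endosome is passing: for every filtered endosome a mobile
square ROI follows its trajectory, and the percentage of endocytic tracks
whose final position falls inside a concurrent ROI is compared — per cell —
against the same percentage computed on deterministically displaced
*control* endosome trajectories.  A paired two-sided t test across cells
summarizes the comparison.

Endosome tables are DataFrames with columns ``label, frame, x, y``; labels
are positive integers assigned in order of detection (their parity drives
the control offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import MovieMeta, _require_columns

ENDOSOME_COLUMNS = ["label", "frame", "x", "y"]

#: default mobile ROI: square of this side (pixels), centered on the endosome
ROI_SIDE = 30.0

#: rigid displacement applied to build control trajectories (pixels)
CONTROL_OFFSET = 50.0

#: endosome filter: minimum straight-line displacement (pixels)
MIN_DISPLACEMENT = 10.0
EDGE_FRAMES = 10


@dataclass(frozen=True)
class PickupSummary:
    """Per-cell pick-up percentages and the paired test result."""

    per_cell: pd.DataFrame      # cell, pct_endosome, pct_control, counts
    t_statistic: float
    p_value: float
    n_cells: int
    mean_endosome: float
    mean_control: float
    sd_endosome: float
    sd_control: float

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_cells": self.n_cells,
            "mean_endosome_pct": self.mean_endosome,
            "mean_control_pct": self.mean_control,
            "sd_endosome_pct": self.sd_endosome,
            "sd_control_pct": self.sd_control,
        }


def _require_endosome_columns(df: pd.DataFrame) -> None:
    missing = [c for c in ENDOSOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"endosome table missing column(s): {', '.join(missing)}")


def filter_endosomes(endosomes: pd.DataFrame, movie: MovieMeta) -> pd.DataFrame:
    """Keep mobile, interior-in-time endosome tracks.

    Retained iff the straight-line displacement from first to last position
    exceeds 10 pixels and the track is absent from the first and last 10
    frames of the movie.
    """
    _require_endosome_columns(endosomes)
    if endosomes.empty:
        return endosomes.copy()
    keep = []
    for label, grp in endosomes.groupby("label", sort=False):
        grp = grp.sort_values("frame")
        disp = float(np.hypot(
            grp["x"].iloc[-1] - grp["x"].iloc[0],
            grp["y"].iloc[-1] - grp["y"].iloc[0],
        ))
        first, last = int(grp["frame"].iloc[0]), int(grp["frame"].iloc[-1])
        if (disp > MIN_DISPLACEMENT and first >= EDGE_FRAMES
                and last <= movie.n_frames - EDGE_FRAMES - 1):
            keep.append(label)
    keep = set(keep)
    return endosomes[endosomes["label"].isin(keep)].reset_index(drop=True)


def _control_shift(x0: float, y0: float, label: int, movie: MovieMeta,
                   offset: float) -> tuple[float, float]:
    """Offset vector for one endosome, from its first coordinate and label.

    Quadrants are defined by the movie midlines (ties go to the upper/left
    side; the origin is top-left with y increasing downward).  Top
    quadrants: odd labels move along x (+offset upper-left, -offset
    upper-right), even labels move +offset along y.  Bottom quadrants
    reverse those directions.
    """
    left = x0 <= movie.width / 2
    top = y0 <= movie.height / 2
    odd = label % 2 == 1
    if top and left:
        return (offset, 0.0) if odd else (0.0, offset)
    if top and not left:
        return (-offset, 0.0) if odd else (0.0, offset)
    if not top and left:
        return (-offset, 0.0) if odd else (0.0, -offset)
    return (offset, 0.0) if odd else (0.0, -offset)


def control_endosome(endosomes: pd.DataFrame, movie: MovieMeta,
                     offset: float = CONTROL_OFFSET) -> pd.DataFrame:
    """Build control endosome trajectories by rigid per-track offsets.

    Each trajectory is displaced as a whole by ``offset`` pixels along one
    axis, chosen from the quadrant of its first coordinate and the parity
    of its label (see :func:`_control_shift`).  Trajectory shape is exactly
    preserved; positions may leave the movie bounds, in which case the
    corresponding ROI area simply falls outside the frame.
    """
    _require_endosome_columns(endosomes)
    out = endosomes.copy()
    for label, grp in endosomes.groupby("label", sort=False):
        grp = grp.sort_values("frame")
        dx, dy = _control_shift(
            float(grp["x"].iloc[0]), float(grp["y"].iloc[0]), int(label),
            movie, offset,
        )
        sel = out["label"] == label
        out.loc[sel, "x"] += dx
        out.loc[sel, "y"] += dy
    return out


def fraction_ending_in_rois(
    tracks: pd.DataFrame,
    endosomes: pd.DataFrame,
    roi_side: float = ROI_SIDE,
) -> float:
    """Percentage of endocytic tracks that end inside a mobile endosome ROI.

    A track "ends in" an ROI if at its final frame some endosome exists and
    the track's final position lies within the axis-aligned square of side
    ``roi_side`` centered on that endosome's concurrent position.  Tracks
    ending in several overlapping ROIs count once; tracks whose final frame
    has no live endosome only enter the denominator.
    """
    _require_columns(tracks)
    _require_endosome_columns(endosomes)
    ends = (
        tracks.sort_values("frame")
        .groupby(["track_id", "channel"], sort=False)
        .tail(1)
    )
    if ends.empty:
        raise ValueError("no endocytic tracks")
    if endosomes.empty:
        raise ValueError("endosome set is empty")
    half = roi_side / 2.0
    eg = {f: g for f, g in endosomes.groupby("frame", sort=False)}
    n_in = 0
    for _, row in ends.iterrows():
        g = eg.get(row["frame"])
        if g is None:
            continue
        dx = np.abs(g["x"].to_numpy() - row["x"])
        dy = np.abs(g["y"].to_numpy() - row["y"])
        if np.any((dx <= half) & (dy <= half)):
            n_in += 1
    return 100.0 * n_in / len(ends)


def pickup_test(per_cell: pd.DataFrame | list[tuple[float, float]]) -> PickupSummary:
    """Paired two-sided t test of endosome-ROI vs control-ROI percentages.

    ``per_cell`` holds one (endosome %, control %) pair per cell, either as
    a DataFrame with columns ``pct_endosome, pct_control`` or as a list of
    pairs.  All-zero differences raise a degenerate-variance error.
    """
    if isinstance(per_cell, pd.DataFrame):
        df = per_cell.copy()
        if not {"pct_endosome", "pct_control"} <= set(df.columns):
            raise ValueError(
                "per_cell needs columns 'pct_endosome' and 'pct_control'"
            )
    else:
        df = pd.DataFrame(per_cell, columns=["pct_endosome", "pct_control"])
    if len(df) < 2:
        raise ValueError("paired test requires at least 2 cells")
    a = df["pct_endosome"].to_numpy(dtype=float)
    b = df["pct_control"].to_numpy(dtype=float)
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError(
            "degenerate variance: all per-cell differences are equal"
        )
    res = stats.ttest_rel(a, b)
    return PickupSummary(
        per_cell=df.reset_index(drop=True),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_cells=len(df),
        mean_endosome=float(a.mean()),
        mean_control=float(b.mean()),
        sd_endosome=float(a.std(ddof=1)),
        sd_control=float(b.std(ddof=1)),
    )
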