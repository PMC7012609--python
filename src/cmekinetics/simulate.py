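"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the pipeline can be exercised without external
data: lifetimes are drawn from the same truncated mixture family the fit
assumes, intensity trajectories follow the three-phase
(assembly/maturation/scission) trapezoid with additive Gaussian noise, and
endosome scenes couple directed endosome trajectories with endocytic tracks
whose termination points are, with a tunable probability, placed inside a
passing endosome's mobile ROI.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import MovieMeta, LifetimeDataset, MIN_TRACK_FRAMES
from .mixture import _cdf
from .pickup import ROI_SIDE

#: sd of the per-frame positional jitter applied to simulated tracks (px)
POSITION_JITTER_SD = 0.5

#: margin keeping simulated endosome paths clear of the movie edge, so the
#: +/-50 px control offsets keep control ROIs fully inside the frame (px)
ENDOSOME_MARGIN = 60.0


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth lifetime mixture within an acquisition window.

    ``components`` is a list of ``(kind, scale, fraction)`` tuples where
    ``kind`` is ``"exponential"`` or ``"rayleigh"``, ``scale`` is the mean
    lifetime 1/rate (exponential) or sigma (rayleigh) in seconds, and
    ``fraction`` is the *observed* (post-truncation) mixture fraction.
    The window is [5 frames, movie duration]:
    ``t_low = 5 dt`` and ``t_high = n_frames * dt``.
    """

    components: tuple
    frame_interval: float = 1.0
    n_frames: int = 601

    def __post_init__(self) -> None:
        comps = tuple(tuple(c) for c in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("mixture needs at least one component")
        fr = np.array([c[2] for c in comps], dtype=float)
        if (fr < 0).any():
            raise ValueError("component fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {fr.sum()}")
        for kind, scale, _ in comps:
            if kind not in ("exponential", "rayleigh"):
                raise ValueError(f"unknown component kind {kind!r}")
            if scale <= 0:
                raise ValueError("component scale parameters must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames * self.frame_interval <= self.t_low:
            raise ValueError("movie too short: t_high must exceed t_low")

    @property
    def t_low(self) -> float:
        return 5.0 * self.frame_interval

    @property
    def t_high(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c[2] for c in self.components], dtype=float)


@dataclass(frozen=True)
class PhaseSpec:
    """Three-phase intensity trajectory shape.

    ``assembly_fraction`` and ``maturation_fraction`` are fractions of the
    total lifetime; the scission fall takes the remainder.  Noise is
    additive zero-mean Gaussian with sd ``noise_sd``.
    """

    assembly_fraction: float = 0.42
    maturation_fraction: float = 0.178
    peak_amplitude: float = 100.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        a, m = self.assembly_fraction, self.maturation_fraction
        if not (0 < a < 1 and 0 < m < 1):
            raise ValueError("phase fractions must lie in (0, 1)")
        if a + m >= 1:
            raise ValueError("assembly + maturation fractions must be < 1")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Coupled endosome/endocytosis scene for the pick-up analysis."""

    movie: MovieMeta
    n_endosomes: int = 8
    endosome_speed: float = 1.0      # pixels per frame
    n_endocytic_tracks: int = 150
    pickup_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.n_endosomes < 0 or self.n_endocytic_tracks < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.pickup_probability <= 1.0:
            raise ValueError("pickup_probability must be in [0, 1]")
        if self.endosome_speed <= 0:
            raise ValueError("endosome_speed must be positive")


# ---------------------------------------------------------------------------
# lifetimes
# ---------------------------------------------------------------------------

def _truncated_inverse_cdf(kind: str, scale: float, u: np.ndarray,
                           a: float, b: float) -> np.ndarray:
    """Inverse CDF of a component truncated to [a, b], evaluated at u."""
    Fa = _cdf(kind, 1.0 / scale if kind == "exponential" else scale, a)
    Fb = _cdf(kind, 1.0 / scale if kind == "exponential" else scale, b)
    F = Fa + u * (Fb - Fa)
    if kind == "exponential":
        return -scale * np.log1p(-F)
    return scale * np.sqrt(-2.0 * np.log1p(-F))


def sample_mixture_lifetimes(
    spec: MixtureSpec,
    n_events: int,
    seed: int | None,
    return_labels: bool = False,
):
    """Draw frame-quantized lifetimes from a truncated mixture.

    Component membership is drawn with the observed fractions; within a
    component the lifetime is drawn by inverse CDF from the component
    density truncated to the half-frame-extended window
    ``[t_low - dt/2, t_high + dt/2)`` and then rounded to the nearest frame
    multiple (a true duration of 4.6 s is observed as 5 frames) and clamped
    to ``[t_low, t_high]``.

    With ``return_labels=True`` also returns the ground-truth component
    index of every event.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    dt = spec.frame_interval
    a = spec.t_low - dt / 2.0
    b = spec.t_high + dt / 2.0
    labels = rng.choice(len(spec.components), size=n_events, p=spec.fractions)
    u = rng.random(n_events)
    t = np.empty(n_events)
    for i, (kind, scale, _) in enumerate(spec.components):
        sel = labels == i
        t[sel] = _truncated_inverse_cdf(kind, scale, u[sel], a, b)
    t = np.clip(np.round(t / dt) * dt, spec.t_low, spec.t_high)
    ds = LifetimeDataset(t, dt, spec.t_low, spec.t_high)
    return (ds, labels) if return_labels else ds


# ---------------------------------------------------------------------------
# intensity trajectories
# ---------------------------------------------------------------------------

def simulate_intensity_trajectory(
    phases: PhaseSpec,
    lifetime_frames: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-frame amplitude of one three-phase track.

    The noiseless series is piecewise linear: a rise from 0 to
    ``peak_amplitude`` over the assembly fraction of the lifetime, a flat
    plateau over the maturation fraction, and a fall back to 0 over the
    remainder; zero-mean Gaussian noise of sd ``noise_sd`` is added.
    """
    if lifetime_frames < MIN_TRACK_FRAMES:
        raise ValueError(
            f"lifetime_frames must be >= {MIN_TRACK_FRAMES} (minimum track length)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    L = int(lifetime_frames)
    t = np.arange(L, dtype=float)
    b1 = phases.assembly_fraction * (L - 1)
    b2 = (phases.assembly_fraction + phases.maturation_fraction) * (L - 1)
    y = np.interp(t, [0.0, b1, b2, L - 1.0],
                  [0.0, phases.peak_amplitude, phases.peak_amplitude, 0.0])
    if phases.noise_sd > 0:
        y = y + rng.normal(0.0, phases.noise_sd, L)
    return y


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------

def simulate_track_table(
    spec: MixtureSpec,
    phases: PhaseSpec,
    movie: MovieMeta,
    n_tracks: int,
    seed: int | None,
    channel: str = "ch0",
    jitter_sd: float = POSITION_JITTER_SD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a track table plus its ground truth.

    Each track gets a uniform-random start frame and position, a lifetime
    drawn from the mixture, a three-phase intensity trajectory, and small
    Gaussian positional jitter; tracks extending past the movie end are
    truncated there.  Returns ``(tracks, truth)`` where ``truth`` has one
    row per track with the sampled lifetime (frames), component label and
    start frame.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    if n_tracks > 0:
        ds, labels = sample_mixture_lifetimes(
            spec, n_tracks, rng.integers(2**31 - 1), return_labels=True
        )
        frames_per_track = np.round(ds.lifetimes / spec.frame_interval).astype(int)
        for tid in range(n_tracks):
            L = int(frames_per_track[tid])
            start = int(rng.integers(0, movie.n_frames))
            x0 = rng.uniform(0.0, movie.width)
            y0 = rng.uniform(0.0, movie.height)
            amp = simulate_intensity_trajectory(phases, L, rng=rng)
            end = min(start + L, movie.n_frames)  # truncate at movie end
            n_obs = end - start
            jx = rng.normal(0.0, jitter_sd, n_obs) if jitter_sd > 0 else 0.0
            jy = rng.normal(0.0, jitter_sd, n_obs) if jitter_sd > 0 else 0.0
            x = np.clip(x0 + jx, 0.0, np.nextafter(movie.width, 0.0))
            y = np.clip(y0 + jy, 0.0, np.nextafter(movie.height, 0.0))
            for k in range(n_obs):
                rows.append(
                    (tid, channel, start + k, float(np.atleast_1d(x)[k]),
                     float(np.atleast_1d(y)[k]), float(amp[k]))
                )
            truth_rows.append((tid, L, int(labels[tid]), start, n_obs))
    tracks = pd.DataFrame(
        rows, columns=["track_id", "channel", "frame", "x", "y", "amplitude"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["track_id", "lifetime_frames", "component", "start_frame",
                 "observed_frames"],
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# endosome scenes
# ---------------------------------------------------------------------------

def _endosome_path(rng, movie: MovieMeta, speed: float):
    """One straight constant-velocity path inside the interior margin."""
    n = movie.n_frames
    box = min(movie.width, movie.height) - 2 * ENDOSOME_MARGIN
    # long enough to pass the >10 px displacement filter, short enough to
    # stay inside the interior margin at this speed
    dur_min = max(15, int(np.ceil(12.0 / speed)))
    dur_max = int(min(200, n - 2 * 10 - 2, box / speed))
    if dur_max <= dur_min:
        raise ValueError("movie too small for an endosome path at this speed")
    dur = int(rng.integers(dur_min, dur_max + 1))
    first = int(rng.integers(10, n - 10 - dur))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    dx, dy = speed * np.cos(theta), speed * np.sin(theta)
    span_x, span_y = dx * (dur - 1), dy * (dur - 1)
    lo_x = ENDOSOME_MARGIN + max(0.0, -span_x)
    hi_x = movie.width - ENDOSOME_MARGIN - max(0.0, span_x)
    lo_y = ENDOSOME_MARGIN + max(0.0, -span_y)
    hi_y = movie.height - ENDOSOME_MARGIN - max(0.0, span_y)
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("movie too small for an endosome path at this speed")
    x0 = rng.uniform(lo_x, hi_x)
    y0 = rng.uniform(lo_y, hi_y)
    frames = np.arange(first, first + dur)
    return frames, x0 + dx * np.arange(dur), y0 + dy * np.arange(dur)


def simulate_endosome_scene(
    scene: SceneSpec, seed: int | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cell: mobile endosomes plus endocytic tracks.

    Endosomes move on straight constant-velocity paths that pass the
    standard endosome filter by construction (displacement > 10 px, absent
    from the first/last 10 frames) and stay ``ENDOSOME_MARGIN`` pixels from
    the movie edge.  Each endocytic track, independently with probability
    ``pickup_probability``, terminates inside the mobile ROI of a randomly
    chosen endosome at a frame that endosome traverses; otherwise its end
    point is uniform over the filter-compliant interior.  Endocytic tracks
    are stationary at their end point (with per-frame jitter on the
    non-final frames) and pass the standard track filter by construction.

    Returns ``(endosomes, tracks)``.
    """
    rng = np.random.default_rng(seed)
    movie = scene.movie
    n = movie.n_frames
    if n < 120:
        raise ValueError("scene movies need at least 120 frames")

    e_rows = []
    paths = []
    for label in range(1, scene.n_endosomes + 1):
        frames, xs, ys = _endosome_path(rng, movie, scene.endosome_speed)
        paths.append((frames, xs, ys))
        for f, x, y in zip(frames, xs, ys):
            e_rows.append((label, int(f), float(x), float(y)))
    endosomes = pd.DataFrame(e_rows, columns=["label", "frame", "x", "y"])

    t_rows = []
    half = ROI_SIDE / 2.0 - 1.0  # strictly inside the ROI square
    for tid in range(scene.n_endocytic_tracks):
        L = int(rng.integers(MIN_TRACK_FRAMES, 41))
        picked = paths and rng.random() < scene.pickup_probability
        if picked:
            frames, xs, ys = paths[rng.integers(len(paths))]
            lo = max(int(frames[0]), 10 + L - 1)
            hi = min(int(frames[-1]), n - 11)
            if lo > hi:  # endosome lifespan cannot host this track; retry uniform
                picked = False
            else:
                f_end = int(rng.integers(lo, hi + 1))
                k = f_end - int(frames[0])
                x_end = float(xs[k] + rng.uniform(-half, half))
                y_end = float(ys[k] + rng.uniform(-half, half))
        if not picked:
            f_end = int(rng.integers(10 + L - 1, n - 10))
            x_end = rng.uniform(10.0, movie.width - 10.0 - 1e-9)
            y_end = rng.uniform(10.0, movie.height - 10.0 - 1e-9)
        f_start = f_end - L + 1
        jx = rng.normal(0.0, POSITION_JITTER_SD, L - 1)
        jy = rng.normal(0.0, POSITION_JITTER_SD, L - 1)
        for k in range(L):
            if k == L - 1:
                x, y = x_end, y_end
            else:
                x = float(np.clip(x_end + jx[k], 10.0, movie.width - 10.0 - 1e-9))
                y = float(np.clip(y_end + jy[k], 10.0, movie.height - 10.0 - 1e-9))
            t_rows.append((tid, "ch0", f_start + k, x, y, 1.0))
    tracks = pd.DataFrame(
        t_rows, columns=["track_id", "channel", "frame", "x", "y", "amplitude"]
    )
    return endosomes, tracks
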