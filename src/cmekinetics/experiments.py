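"""Reference parameter-recovery experiments at published study conditions.

The generators invert the models being fitted, so the pipeline's headline
quantities can be reproduced as parameter-recovery experiments with known
ground truth: lifetimes are simulated from the three-population truncated
exponential mixture measured in root epidermis (means 2, 9 and 42 s with
observed fractions 6.31%, 50.6% and 43.9%, observed at 1 frame/s over 601
frames), and cohort intensity trajectories are simulated with the root
profile's phase fractions (42% assembly, 17.8% maturation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracks import MovieMeta
from .mixture import MixtureFit, fit_mixture, select_components
from .profiles import (
    PhaseSegmentation,
    mean_cohort_profile,
    smooth_profile,
    segment_phases,
)
from .simulate import (
    MixtureSpec,
    PhaseSpec,
    sample_mixture_lifetimes,
    simulate_intensity_trajectory,
)

#: reference three-population mixture of clathrin track lifetimes in root
#: epidermis: component mean lifetimes (s) and observed percentages.  The
#: published percentages sum to 100.81 and are renormalized to the simplex.
ROOT_COMPONENT_MEANS = (2.0, 9.0, 42.0)
ROOT_COMPONENT_PERCENTS = (6.31, 50.6, 43.9)

#: full single-channel root data set size (tracks after filtering)
ROOT_N_TRACKS = 149162

#: root cohort intensity profile phase fractions
ROOT_ASSEMBLY_FRACTION = 0.42
ROOT_MATURATION_FRACTION = 0.178

#: root acquisition: 1 frame per second, 601 frames
ROOT_MOVIE = MovieMeta(width=300, height=300, n_frames=601, frame_rate=1.0)

#: mean lifetime (frames) of the bona fide endocytic population, which sets
#: the cohort window for the profile experiment
ROOT_MEAN_LIFETIME_FRAMES = 42


def root_mixture_spec(frame_interval: float = 1.0,
                      n_frames: int = 601) -> MixtureSpec:
    """Ground-truth mixture spec at the root acquisition settings."""
    w = np.asarray(ROOT_COMPONENT_PERCENTS, dtype=float)
    w = w / w.sum()
    return MixtureSpec(
        components=[("exponential", m, f)
                    for m, f in zip(ROOT_COMPONENT_MEANS, w)],
        frame_interval=frame_interval,
        n_frames=n_frames,
    )


def recover_root_mixture(
    n_events: int = ROOT_N_TRACKS,
    seed: int = 0,
    n_starts: int = 50,
    fit_seed: int | None = None,
) -> MixtureFit:
    """Simulate the root lifetime data set and fit the n=3 mixture."""
    spec = root_mixture_spec()
    ds = sample_mixture_lifetimes(spec, n_events, seed)
    return fit_mixture(ds, n=3, n_starts=n_starts,
                       seed=seed if fit_seed is None else fit_seed)


def select_root_mixture(
    n_events: int = ROOT_N_TRACKS,
    seed: int = 0,
    n_starts: int = 50,
    n_range=range(1, 6),
):
    """Simulate the root lifetime data set and run BIC model selection."""
    spec = root_mixture_spec()
    ds = sample_mixture_lifetimes(spec, n_events, seed)
    return select_components(ds, n_range=n_range, n_starts=n_starts, seed=seed)


def simulate_root_cohort_tracks(
    n_tracks: int = 200,
    seed: int = 0,
    noise_fraction: float = 0.10,
    peak_amplitude: float = 100.0,
    movie: MovieMeta = ROOT_MOVIE,
) -> pd.DataFrame:
    """Track table of three-phase cohort trajectories at root conditions.

    Lifetimes are drawn uniformly from the mean +/- 3 frame cohort window;
    noise sd is ``noise_fraction`` of the peak amplitude.  Tracks are placed
    mid-movie away from edges so they pass the standard filter.
    """
    rng = np.random.default_rng(seed)
    phases = PhaseSpec(
        assembly_fraction=ROOT_ASSEMBLY_FRACTION,
        maturation_fraction=ROOT_MATURATION_FRACTION,
        peak_amplitude=peak_amplitude,
        noise_sd=noise_fraction * peak_amplitude,
    )
    lo = ROOT_MEAN_LIFETIME_FRAMES - 3
    hi = ROOT_MEAN_LIFETIME_FRAMES + 3
    rows = []
    for tid in range(n_tracks):
        L = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(20, movie.n_frames - 20 - L))
        x = rng.uniform(20.0, movie.width - 20.0)
        y = rng.uniform(20.0, movie.height - 20.0)
        amp = simulate_intensity_trajectory(phases, L, rng=rng)
        for k in range(L):
            rows.append((tid, "ch0", start + k, x, y, float(amp[k])))
    return pd.DataFrame(
        rows, columns=["track_id", "channel", "frame", "x", "y", "amplitude"]
    )


def recover_root_phases(
    n_tracks: int = 200,
    seed: int = 0,
    movie: MovieMeta = ROOT_MOVIE,
) -> PhaseSegmentation:
    """Cohort profile -> smooth -> segment on simulated root trajectories."""
    tracks = simulate_root_cohort_tracks(n_tracks=n_tracks, seed=seed,
                                         movie=movie)
    prof = mean_cohort_profile(tracks, movie, mode="start")
    return segment_phases(smooth_profile(prof))
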