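# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data experiments do and do not demonstrate.

## Lifetime mixture model

Track lifetimes are observed on a truncation window: tracks shorter than 5
frames are discarded (`t_low = 5Δt`, with `Δt` the frame interval) and no
track can outlive the movie (`t_high = n_frames·Δt`). Lifetimes are frame
counts, so the data live on the uniform grid `t_low, t_low+Δt, …, t_high`
(N grid points), and the normalized histogram satisfies `Σ h(tᵢ)Δt = 1`.

The histogram is modeled as a mixture of `n` window-renormalized
exponential (rate λᵢ) or Rayleigh (scale σᵢ) densities with observed
fractions μᵢ on the simplex, estimated by minimizing the unweighted
least-squares cost `Λ = Σᵢ (h(tᵢ) − ĥ(tᵢ))²`. The free parameters are the
`n` rates and `n−1` fractions (`k = 2n−1`); models are compared with
`AIC = 2k + N ln(Λ*/N)` and `BIC = k ln N + N ln(Λ*/N)`. Reported component
mean lifetimes are the untruncated means (1/λ, or σ√(π/2)); observed
fractions are converted to truncation-corrected fractions through the
window masses `ωᵢ = cdfᵢ(t_high) − cdfᵢ(t_low)` by solving
`μᵢ = ωᵢμᵢ⁰ / Σⱼ ωⱼμⱼ⁰`, i.e. `μᵢ⁰ ∝ μᵢ/ωᵢ`.

### Frame quantization (the `binning` choice)

Evaluating the *continuous* truncated density pointwise at the grid is
inconsistent with frame-quantized data whenever a component's time constant
is comparable to `Δt`: for a 2 s exponential at 1 frame/s,
`Σᵢ f(tᵢ)Δt ≈ 1.27`, so no simplex-constrained pointwise mixture can match
a histogram that sums to one, and the resulting systematic residual biases
the slow components (in our experiments a generating 42 s mean was dragged
to ≈55 s) and pushes model selection toward spurious extra components. The
default fit (`binning="mass"`) therefore evaluates component `i` at grid
point `t` as the frame-bin probability mass
`[cdfᵢ(t+Δt/2) − cdfᵢ(t−Δt/2)]`, renormalized over the observation window
and divided by `Δt`. This is the same mixture model expressed for discrete
observation; it reduces to the pointwise form as `λΔt → 0` (for the 9 s and
42 s components the two differ by <0.1%). `binning="point"` retains the
literal pointwise evaluation for comparison.

### Optimization

Fractions are parameterized by their first `n−1` coordinates with the last
the complement, bounds `[0,1]` and the linear constraint `Σ ≤ 1`; rates are
bounded in `[1/(10·t_high), 10/t_low]` (Rayleigh scales in
`[t_low/20, 2·t_high]`). Each fit runs SLSQP from `n_starts` (default 50)
random starts — rates log-uniform over `[1/t_high, 2/t_low]`, fractions
Dirichlet(1) — with cost tolerance 1e-16 and at most 2000 iterations; the
lowest-cost start wins, ties resolved by start order, and everything is
deterministic given `(data, n, kind, n_starts, random_state)`. During model
selection each `n` additionally starts from the `(n−1)`-component optimum
with its heaviest component split, which makes `Λ*` non-increasing in `n`.

### Known limitation: BIC over-selection on fast-decaying data

The least-squares cost weights all bins equally, but multinomial sampling
variance is proportional to bin density, so for a monotone-decaying
histogram most of the noise budget sits in the first few bins. A spurious
fast component can cancel the particular noise realization of those bins
and reduce `Λ*` by more than the equal-variance BIC penalty — independent
of sample size. In practice: on data simulated from a *single* population,
BIC picks `n = 1` in only ~55–75% of seeds (the spurious extras carry a few
percent of weight and the dominant component is always recovered); on the
three-population reference data this does not occur, because a genuine fast
component already occupies the early bins, and BIC selects `n = 3`
reliably. Users fitting data suspected to be single-population should
inspect the component weights, not just the selected `n`.

## Track processing conventions

Coordinates are 0-based pixel positions (origin top-left, y downward);
frames are 0-based. The standard filter keeps tracks that start at frame
≥10, end at frame ≤ `n_frames−11`, stay ≥10 px from every movie edge at
every localization (the stricter reading of the edge rule), and persist ≥5
frames. Tracks with frame gaps are rejected at read time, so lifetime =
frame count × `Δt` is unambiguous. Density is the mean number of tracks
present per frame in a centered 100×100 px ROI over the 100 frames
centered on the movie midpoint. Organelle velocity profiling uses the
maximum frame-to-frame Euclidean displacement divided by `Δt`.

## Cohort profiles and phase segmentation

The cohort comprises tracks whose length is within ±3 frames of the
rounded mean track length. Each trajectory is normalized to unit peak (the
peak taken from a lightly smoothed copy so one noise spike cannot set the
scale). For the phase analysis the cohort trajectories are linearly
rescaled to the cohort mean length before averaging: phase boundaries are
defined as fractions of each track's own lifetime, so averaging in rescaled
time keeps the corners aligned, whereas pointwise start-aligned averaging
of unequal-length tracks blurs the fall corner and systematically shortens
the measured maturation plateau (by ~8 percentage points under the
reference conditions). For the departure assay the offsets must remain
real time relative to scission, so there the trajectories are end-aligned
and averaged pointwise without rescaling.

Smoothing is lowess (locally linear). The default span of 0.08 gives a
~3-point window at the typical 42-frame cohort length — the smallest window
a local-linear smoother supports. The constraint is that the window must
stay below roughly half the shortest phase: the maturation plateau spans
only ~7 frames, and a span of 0.3 (13-frame window) erases it entirely.
Cohort means over ≥100 tracks are already low-noise, so little smoothing
is needed.

Segmentation reads the central-difference slope of the smoothed profile.
With `s_max` the maximum (assembly) slope and `s_min` the minimum
(scission) slope, the assembly→maturation transition is the first point
after the slope maximum where the slope falls below `0.2·s_max`, and the
maturation→scission transition is the last point before the slope minimum
where the slope still exceeds `0.2·s_min`; both crossings are linearly
interpolated to sub-frame resolution. A single threshold placed at
`s_min + 0.2(s_max−s_min)` cannot produce two distinct transitions on a
rise–plateau–fall profile (the slope trace crosses such a value exactly
once), so the per-extreme form is used; it recovers noiseless
piecewise-linear breakpoints within one frame for any phase fractions, and
anchoring the scans at the slope extremes makes the estimate robust to
slope noise in the profile tails. Thresholds are relative to the slope
extremes, so segmentation is invariant to scaling and shifting the
intensities. Profiles without both a rising and a falling flank are
rejected as "phases not identifiable".

## Endosomal pick-up

Endosome trajectories are filtered to displacement >10 px, absent from the
first and last 10 movie frames. The mobile ROI is an axis-aligned square of
side 30 px (±15 px) centered on the endosome's per-frame position. An
endocytic track "ends in" an ROI if, at its final frame, its final position
lies inside the ROI of any endosome live at that frame; each track counts
at most once, and tracks whose final frame has no live endosome enter only
the denominator. Control trajectories are built per endosome by a rigid
50 px offset whose axis and sign depend on the quadrant of the first
coordinate (movie midlines; ties to the upper/left) and the parity of the
detection-order label: upper-left odd `x+50` / even `y+50`; upper-right odd
`x−50` / even `y+50`; bottom quadrants reverse these (lower-left odd
`x−50` / even `y−50`; lower-right odd `x+50` / even `y−50`). Offsets are
never clipped; ROI area leaving the frame simply catches nothing. Per-cell
endosome-vs-control percentages are compared with a paired two-sided
t test; identical pairs raise a degenerate-variance error rather than a
p-value.

## Synthetic data: what it does and does not emulate

The generators operate at track level, as the analyses do — no pixel-level
image synthesis, spot PSFs or camera noise, and no detection/linking
errors (no track fragmentation, fusion or localization bias).

* **Lifetimes** are drawn by inverse CDF from the mixture truncated to
  `[t_low − Δt/2, t_high + Δt/2)` and then rounded to the nearest frame:
  a camera observing a 4.6 s event reports 5 frames, so the half-frame
  extension is what acquisition does; truncating hard at `t_low` before
  rounding would leave the first histogram bin half-empty, an artifact
  comparable in size to the entire fast component. Component fractions are
  the *observed* (post-truncation) fractions. The reference observed
  percentages (6.31/50.6/43.9) sum to 100.81 as published and are
  renormalized onto the simplex before simulation.
* **Intensity trajectories** are trapezoids — linear rise over the assembly
  fraction of the lifetime, plateau, linear fall to zero — plus white
  Gaussian noise (default sd 10% of peak). Real CCP traces have curved
  shoulders and correlated noise; passing tests show the segmentation
  recovers trapezoid ground truth, not that real profiles are trapezoids.
* **Track tables** place tracks uniformly in space and time with 0.5 px
  positional jitter; tracks crossing the movie end are truncated there.
* **Endosome scenes** move endosomes on straight constant-velocity paths
  confined ≥60 px from the movie edge — this keeps the ±50 px control
  trajectories fully in frame, so under zero coupling the endosome and
  control ROIs are exchangeable and the null comparison is calibrated.
  Endocytic tracks are stationary; with the configured pick-up probability
  a track's endpoint is placed inside a randomly chosen endosome's ROI at
  a frame that endosome traverses, otherwise uniformly over the
  filter-compliant interior. Real endosomes meander and real pick-up is
  not spatially uniform within the ROI; the scene tests calibration and
  power of the statistic, not endosome biology.

## Reference experiment sizes

The recovery experiments run at the published scale where that is cheap:
149,162 lifetimes for the mixture (the full fit takes ~2 s; BIC selection
over n = 1…5 with 50 starts ~10 s), 200-track cohorts for the phase
analysis (averaged over 5 seeded replicates), 20 simulated cells for the
pick-up null calibration and 10 six-cell replicates for its power check.
The reduced model-selection experiment (20,000 lifetimes × 10 seeds) uses
15 optimizer starts per fit; selection outcomes are unchanged from 50
starts.
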