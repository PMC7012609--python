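# cmekinetics

Kinetic analysis of clathrin-mediated endocytosis (CME) from TIRF
microscopy particle tracks.

CME internalizes plasma-membrane cargo through clathrin-coated pits (CCPs)
that assemble, mature, and scission into vesicles. In TIRF time-lapse
movies each CCP appears as a fluorescent focus whose *track lifetime*
(frames persisted × frame interval) proxies the event duration — but most
clathrin visits to the membrane are transient and non-productive, so the
lifetime distribution is a mixture of short-lived and *bona fide* endocytic
populations. This package implements the downstream quantitative pipeline
for such data: it consumes track tables produced by standard
detection/tracking tools and answers, with tested code and synthetic
ground-truth generators, the questions a plant-endocytosis TIRF experiment
raises.

## What it computes

**Truncated lifetime mixtures.** Observed lifetimes are doubly truncated:
a 5-frame minimum track length imposes `t_low = 5Δt` and the movie duration
imposes `t_high`. The normalized lifetime histogram `h(t_i)` is fitted by
least squares with a mixture of exponential (or Rayleigh) densities
renormalized to the window,

```
ĥ(t) = Σᵢ μᵢ fᵢ(t),   fᵢ(t) = pdfᵢ(t) / (cdfᵢ(t_high) − cdfᵢ(t_low)),   Σᵢ μᵢ = 1,
```

minimized from many random starts; an *n*-component mixture has
`k = 2n − 1` free parameters and models are compared with
`AIC = 2k + N ln(Λ*/N)` and `BIC = k ln N + N ln(Λ*/N)` over the `N`
histogram grid points. Observed fractions are truncation-corrected through
the window masses `ωᵢ`: `μᵢ⁰ ∝ μᵢ/ωᵢ`. Because lifetimes are frame counts,
the default fit evaluates each component as the frame-bin cdf mass divided
by `Δt` (the quantization-aware form of the same model; see
`docs/methods.md`).

**Phase segmentation.** Cohort-averaged CCP intensity profiles (tracks
within ±3 frames of the mean lifetime, normalized and averaged) are
lowess-smoothed and segmented into assembly / maturation / scission at the
points where the profile slope crosses 20% of its extreme values.

**Departure assay.** Two-channel (master/slave) profiles aligned on the
master track's final frame, interpreting clathrin signal loss as vesicle
scission.

**Endosomal pick-up.** The percentage of endocytic tracks that terminate
inside a 30 px mobile ROI following a filtered endosome trajectory,
compared per cell against deterministically offset control trajectories
with a paired two-sided t test.

**Synthetic data.** Seeded generators for all of the above with known
ground truth: truncated-mixture lifetimes, three-phase trapezoid intensity
trajectories, full track tables, and coupled endosome/endocytosis scenes
with a tunable pick-up probability.

## Worked example

Simulate 30,000 lifetimes from a two-population truncated mixture
(9 s / 55% and 42 s / 45%, 1 frame/s, 601 frames) and decompose them:

```python
from cmekinetics import TruncatedLifetimeMixture
from cmekinetics.simulate import MixtureSpec, sample_mixture_lifetimes

spec = MixtureSpec(
    components=[("exponential", 9.0, 0.55), ("exponential", 42.0, 0.45)],
    frame_interval=1.0, n_frames=601,
)
lifetimes = sample_mixture_lifetimes(spec, 30000, seed=7)
model = TruncatedLifetimeMixture(n_components=2, n_starts=20, random_state=0)
model.fit(lifetimes)
for c in model.components_:
    print(f"mean {c.mean:5.2f} s   observed {100*c.mu:5.2f}%   "
          f"window mass {c.omega:.3f}   corrected {100*c.mu0:5.2f}%")
print(f"cost {model.cost_:.3e}   k {model.k_exp_}   "
      f"AIC {model.aic_:.1f}   BIC {model.bic_:.1f}")
```

```
mean  9.07 s   observed 54.79%   window mass 0.576   corrected 65.08%
mean 41.53 s   observed 45.21%   window mass 0.887   corrected 34.92%
cost 3.582e-05   k 3   AIC -9921.5   BIC -9908.3
```

Both component means and fractions are recovered to within a few percent.
The *observed* fractions describe the analyzed tracks; the *corrected*
fractions estimate the untruncated populations — the fast component is
under-observed because 42% of its mass falls below the 5-frame window
(`ω = 0.576`), so its corrected share is larger.

The same estimator composes with scikit-learn tooling
(`get_params`/`set_params`/`clone`), and `select_components` adds BIC model
selection over a range of component counts. The `cmekinetics` console
script exposes the full pipeline (`simulate`, `lifetimes`, `profile`,
`pickup`) over YAML configs; every report embeds the config hash and seed,
and reruns are byte-identical.

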