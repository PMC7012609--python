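"""Truncated lifetime-mixture decomposition with AIC/BIC model selection.

Track lifetimes observed by TIRF-M are doubly truncated: the five-frame
minimum track length imposes a lower bound ``t_low`` and the movie duration
an upper bound ``t_high``.  The observed lifetime histogram is modeled as a
mixture of ``n`` exponential (or Rayleigh) components, each renormalized to
the observation window,

    h_hat(t) = sum_i mu_i f_i(t),        sum_i mu_i = 1,

with f_i the truncated component density.  Parameters are estimated by
least squares on the normalized histogram,

    cost = sum_i ( h(t_i) - h_hat(t_i) )^2,

minimized from many random starts.  A mixture of n components has
``k = 2n - 1`` free parameters (n rates plus n-1 fractions), and models are
compared with AIC = 2k + N ln(cost/N) and BIC = k ln N + N ln(cost/N),
where N is the number of histogram grid points.

Because lifetimes are frame counts, the default fit evaluates each
component as the probability mass of the frame interval
``[t - dt/2, t + dt/2]`` divided by ``dt`` (renormalized over the window).
This is the same mixture model stated above, evaluated consistently with
frame-quantized data; it converges to the pointwise continuous density as
``rate * dt -> 0``, but avoids the large bias the pointwise evaluation
incurs for components whose time constant is comparable to the frame
interval (see docs/methods.md).  ``binning="point"`` selects the pointwise
evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .tracks import LifetimeDataset

_KINDS = ("exponential", "rayleigh")


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifetimeHistogram:
    """Normalized discrete lifetime density on a uniform grid.

    ``density[i]`` estimates the probability density (1/seconds) at grid
    point ``t[i]``; the grid runs from ``t_low`` to ``t_high`` inclusive with
    spacing equal to the frame interval, and ``sum(density) * dt == 1``.
    """

    t: np.ndarray
    density: np.ndarray
    frame_interval: float
    n_lifetimes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        dt = self.frame_interval
        if self.t.size != self.density.size:
            raise ValueError("grid and density must have equal length")
        if self.t.size < 2:
            raise ValueError("histogram needs at least two grid points")
        if np.abs(np.diff(self.t) - dt).max() > 1e-9:
            raise ValueError("grid spacing must equal the frame interval")
        if (self.density < 0).any():
            raise ValueError("densities must be non-negative")
        if abs(self.density.sum() * dt - 1.0) > 1e-9:
            raise ValueError("histogram is not normalized: sum h dt != 1")

    @property
    def n_bins(self) -> int:
        return int(self.t.size)

    @property
    def t_low(self) -> float:
        return float(self.t[0])

    @property
    def t_high(self) -> float:
        return float(self.t[-1])


def build_histogram(ds: LifetimeDataset) -> LifetimeHistogram:
    """Bin a lifetime dataset into a normalized density histogram.

    ``h(t_i) = count(lifetime == t_i) / (n_lifetimes * dt)`` on the uniform
    grid ``t_low .. t_high``.  A lifetime off the grid raises ValueError.
    """
    dt = ds.frame_interval
    n_bins = int(round((ds.t_high - ds.t_low) / dt)) + 1
    grid = ds.t_low + dt * np.arange(n_bins)
    idx = (ds.lifetimes - ds.t_low) / dt
    ridx = np.round(idx).astype(int)
    off = np.abs(idx - ridx) > 1e-6
    if off.any():
        raise ValueError(
            f"lifetime {ds.lifetimes[off][0]} is not on the grid (dt={dt})"
        )
    if ds.n_lifetimes == 0:
        raise ValueError("cannot build a histogram from zero lifetimes")
    counts = np.bincount(ridx, minlength=n_bins)
    h = counts / (ds.n_lifetimes * dt)
    return LifetimeHistogram(grid, h, dt, ds.n_lifetimes)


# ---------------------------------------------------------------------------
# component densities
# ---------------------------------------------------------------------------

def _cdf(kind: str, param: float, t):
    t = np.asarray(t, dtype=float)
    if kind == "exponential":
        return 1.0 - np.exp(-param * t)
    if kind == "rayleigh":
        return 1.0 - np.exp(-t * t / (2.0 * param * param))
    raise ValueError(f"unknown component kind {kind!r}")


def _pdf(kind: str, param: float, t):
    t = np.asarray(t, dtype=float)
    if kind == "exponential":
        return param * np.exp(-param * t)
    if kind == "rayleigh":
        s2 = param * param
        return (t / s2) * np.exp(-t * t / (2.0 * s2))
    raise ValueError(f"unknown component kind {kind!r}")


def component_mean(kind: str, param: float) -> float:
    """Untruncated mean lifetime: 1/rate (exponential) or sigma*sqrt(pi/2)."""
    if kind == "exponential":
        return 1.0 / param
    if kind == "rayleigh":
        return float(param * np.sqrt(np.pi / 2.0))
    raise ValueError(f"unknown component kind {kind!r}")


def window_mass(kind: str, param: float, t_low: float, t_high: float) -> float:
    """Probability mass of an untruncated component inside the window.

    ``omega = cdf(t_high) - cdf(t_low)``; for an exponential component this
    is ``exp(-rate*t_low) - exp(-rate*t_high)``, for a Rayleigh component
    ``exp(-t_low^2/(2 sigma^2)) - exp(-t_high^2/(2 sigma^2))``.
    """
    if param <= 0:
        raise ValueError("component parameter must be positive")
    if t_low >= t_high:
        raise ValueError("t_low must be smaller than t_high")
    return float(_cdf(kind, param, t_high) - _cdf(kind, param, t_low))


def truncated_density(
    kind: str, param: float, t, t_low: float, t_high: float
):
    """Density of a component truncated to ``[t_low, t_high]`` (pdf/omega)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < t_low) or np.any(t > t_high):
        raise ValueError("t outside the truncation window")
    omega = window_mass(kind, param, t_low, t_high)
    out = _pdf(kind, param, t) / omega
    return float(out) if out.ndim == 0 else out


def _bin_mass_density(
    kind: str, params: np.ndarray, grid: np.ndarray, dt: float
) -> np.ndarray:
    """Per-component frame-bin mass / dt, normalized over the window.

    Column j holds ``[cdf_j(t+dt/2) - cdf_j(t-dt/2)] / W_j / dt`` where
    ``W_j`` is the component mass of ``[t_low - dt/2, t_high + dt/2]``, so
    each column sums (times dt) to exactly 1 on the grid.
    """
    lo = np.stack([_cdf(kind, p, grid - dt / 2) for p in params], axis=1)
    hi = np.stack([_cdf(kind, p, grid + dt / 2) for p in params], axis=1)
    mass = hi - lo
    total = _cdf(kind, params, grid[-1] + dt / 2) - _cdf(kind, params, grid[0] - dt / 2)
    # guard against underflow for extreme rates explored by the optimizer
    total = np.where(total <= 0, np.finfo(float).tiny, total)
    return mass / total[None, :] / dt


def _pointwise_density(
    kind: str, params: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Per-component truncated density evaluated pointwise on the grid."""
    omega = _cdf(kind, params, grid[-1]) - _cdf(kind, params, grid[0])
    omega = np.where(omega <= 0, np.finfo(float).tiny, omega)
    f = np.stack([_pdf(kind, p, grid) for p in params], axis=1)
    return f / omega[None, :]


def correct_fractions(mu, omega) -> np.ndarray:
    """Truncation-correct observed mixture fractions.

    The observed fraction of component i relates to its true (untruncated)
    fraction through the window masses:
    ``mu_i = omega_i mu0_i / sum_j omega_j mu0_j``.  Inverting,
    ``mu0_i = (mu_i / omega_i) / sum_j (mu_j / omega_j)``.
    """
    mu = np.asarray(mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("component with zero mass in the window")
    raw = mu / omega
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureComponent:
    """One fitted mixture component.

    ``parameter`` is the rate (1/s) for an exponential component or the
    scale sigma (s) for a Rayleigh component; ``mean`` the untruncated mean
    lifetime; ``mu`` the observed fraction, ``omega`` the window mass and
    ``mu0`` the truncation-corrected fraction.
    """

    kind: str
    parameter: float
    mean: float
    mu: float
    omega: float
    mu0: float


@dataclass(frozen=True)
class MixtureFit:
    """Result of a truncated-mixture fit, components sorted by mean."""

    components: tuple[MixtureComponent, ...]
    cost: float
    k_exp: int
    aic: float
    bic: float
    n_bins: int
    t_low: float
    t_high: float
    n_starts: int
    seed: int | None

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    @property
    def corrected_fractions(self) -> np.ndarray:
        return np.array([c.mu0 for c in self.components])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["components"] = [asdict(c) for c in self.components]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TruncatedLifetimeMixture(BaseEstimator):
    """Truncated exponential/Rayleigh mixture fitted to lifetime data.

    Scikit-learn style estimator: hyperparameters in ``__init__``, data in
    :meth:`fit`, fitted results in trailing-underscore attributes.

    Parameters
    ----------
    n_components : int
        Number of mixture components.
    kind : {"exponential", "rayleigh"}
        Component family.  Exponential components are parameterized by
        their rate (1/s), Rayleigh components by their scale sigma (s).
    n_starts : int
        Number of random optimizer starts; the lowest-cost solution wins
        (ties broken by the earliest start).
    random_state : int or None
        Seed of the start-point stream; fits are deterministic given
        ``(data, n_components, kind, n_starts, random_state)``.
    binning : {"mass", "point"}
        Model evaluation on the histogram grid.  ``"mass"`` (default) uses
        the frame-bin cdf mass divided by dt; ``"point"`` evaluates the
        continuous truncated density at the grid points.
    warm_starts : sequence of (params, mu) or None
        Extra deterministic starts, e.g. the optimum of a smaller model
        padded with a new component (used by :func:`select_components`).

    Attributes
    ----------
    components_ : tuple of MixtureComponent, sorted by ascending mean
    rates_ or scales_ : component parameters in the same order
    means_, weights_, window_masses_, corrected_weights_ : per component
    cost_, k_exp_, aic_, bic_, n_bins_ : fit statistics
    histogram_ : the LifetimeHistogram that was fitted
    """

    def __init__(
        self,
        n_components: int = 3,
        kind: str = "exponential",
        n_starts: int = 50,
        random_state: int | None = None,
        binning: str = "mass",
        ftol: float = 1e-16,
        max_iter: int = 2000,
        warm_starts=None,
    ):
        self.n_components = n_components
        self.kind = kind
        self.n_starts = n_starts
        self.random_state = random_state
        self.binning = binning
        self.ftol = ftol
        self.max_iter = max_iter
        self.warm_starts = warm_starts

    # -- model evaluation ---------------------------------------------------

    def _component_matrix(self, params: np.ndarray, hist: LifetimeHistogram):
        if self.binning == "mass":
            return _bin_mass_density(self.kind, params, hist.t, hist.frame_interval)
        if self.binning == "point":
            return _pointwise_density(self.kind, params, hist.t)
        raise ValueError(f"unknown binning mode {self.binning!r}")

    def _unpack(self, x: np.ndarray):
        n = self.n_components
        params = x[:n]
        if n == 1:
            mu = np.ones(1)
        else:
            mu = np.empty(n)
            mu[: n - 1] = x[n:]
            mu[n - 1] = 1.0 - mu[: n - 1].sum()
        return params, mu

    def _param_bounds(self, t_low: float, t_high: float):
        if self.kind == "exponential":
            return 1.0 / (10.0 * t_high), 10.0 / t_low
        # Rayleigh scale sigma spans means ~ t_low/10 .. a few movie lengths
        return t_low / 20.0, 2.0 * t_high

    def _initial_params(self, rng, t_low: float, t_high: float):
        if self.kind == "exponential":
            lo, hi = np.log(1.0 / t_high), np.log(2.0 / t_low)
        else:
            lo, hi = np.log(t_low / 2.0), np.log(t_high)
        return np.exp(rng.uniform(lo, hi, self.n_components))

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the mixture to lifetimes.

        ``X`` may be a :class:`LifetimeDataset`, a
        :class:`LifetimeHistogram`, or a 1-d array of lifetimes in seconds
        together with a ``LifetimeDataset``-compatible window already built
        elsewhere (arrays are not accepted without window information).
        """
        if isinstance(X, LifetimeHistogram):
            hist = X
        elif isinstance(X, LifetimeDataset):
            hist = build_histogram(X)
        else:
            raise TypeError(
                "fit expects a LifetimeDataset or LifetimeHistogram; build one "
                "with lifetimes_from_tracks or build_histogram"
            )
        n = int(self.n_components)
        if n < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")

        h = hist.density
        t_low, t_high = hist.t_low, hist.t_high
        rng = np.random.default_rng(self.random_state)

        def cost(x):
            params, mu = self._unpack(x)
            resid = h - self._component_matrix(params, hist) @ mu
            return float(resid @ resid)

        p_lo, p_hi = self._param_bounds(t_low, t_high)
        bounds = [(p_lo, p_hi)] * n + [(0.0, 1.0)] * (n - 1)
        constraints = (
            [{"type": "ineq", "fun": lambda x: 1.0 - x[n:].sum()}] if n > 1 else []
        )

        starts = []
        for _ in range(self.n_starts):
            params0 = np.sort(self._initial_params(rng, t_low, t_high))
            mu0 = rng.dirichlet(np.ones(n))[: n - 1]
            starts.append(np.concatenate([params0, mu0]))
        for params0, mu0 in self.warm_starts or []:
            params0 = np.clip(np.asarray(params0, float), p_lo, p_hi)
            mu0 = np.asarray(mu0, float)
            starts.append(np.concatenate([params0, mu0[: n - 1]]))

        best = None
        diagnostics = []
        for x0 in starts:
            res = minimize(
                cost,
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=constraints,
                options={"maxiter": self.max_iter, "ftol": self.ftol},
            )
            diagnostics.append((res.status, res.message))
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                "optimizer failed on all starts: "
                + "; ".join(f"[{s}] {m}" for s, m in diagnostics)
            )

        params, mu = self._unpack(best.x)
        mu = np.clip(mu, 0.0, 1.0)
        mu = mu / mu.sum()
        order = np.argsort([component_mean(self.kind, p) for p in params])
        params, mu = params[order], mu[order]
        omega = np.array([window_mass(self.kind, p, t_low, t_high) for p in params])
        mu0 = correct_fractions(mu, omega)

        N = hist.n_bins
        k = 2 * n - 1
        self.components_ = tuple(
            MixtureComponent(
                kind=self.kind,
                parameter=float(p),
                mean=float(component_mean(self.kind, p)),
                mu=float(m),
                omega=float(w),
                mu0=float(m0),
            )
            for p, m, w, m0 in zip(params, mu, omega, mu0)
        )
        if self.kind == "exponential":
            self.rates_ = params.copy()
        else:
            self.scales_ = params.copy()
        self.means_ = np.array([c.mean for c in self.components_])
        self.weights_ = mu.copy()
        self.window_masses_ = omega.copy()
        self.corrected_weights_ = mu0.copy()
        self.cost_ = float(best.fun)
        self.k_exp_ = k
        self.n_bins_ = N
        self.aic_ = float(2 * k + N * np.log(self.cost_ / N))
        self.bic_ = float(k * np.log(N) + N * np.log(self.cost_ / N))
        self.histogram_ = hist
        return self

    # -- inspection ---------------------------------------------------------

    def predict_density(self, t) -> np.ndarray:
        """Evaluate the fitted mixture density pointwise at times ``t``."""
        check_is_fitted(self, "components_")
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for c in self.components_:
            out += c.mu * truncated_density(
                c.kind, c.parameter, t, self.histogram_.t_low, self.histogram_.t_high
            )
        return out

    def score(self, X=None, y=None) -> float:
        """Negative fitted cost (higher is better), sklearn convention."""
        check_is_fitted(self, "cost_")
        return -self.cost_

    def result_(self) -> MixtureFit:
        """Package the fitted state as an immutable :class:`MixtureFit`."""
        check_is_fitted(self, "components_")
        return MixtureFit(
            components=self.components_,
            cost=self.cost_,
            k_exp=self.k_exp_,
            aic=self.aic_,
            bic=self.bic_,
            n_bins=self.n_bins_,
            t_low=self.histogram_.t_low,
            t_high=self.histogram_.t_high,
            n_starts=self.n_starts,
            seed=self.random_state,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_mixture(
    hist: LifetimeHistogram | LifetimeDataset,
    n: int,
    kind: str = "exponential",
    n_starts: int = 50,
    seed: int | None = None,
    **kwargs,
) -> MixtureFit:
    """Fit an ``n``-component truncated mixture; see
    :class:`TruncatedLifetimeMixture`."""
    est = TruncatedLifetimeMixture(
        n_components=n, kind=kind, n_starts=n_starts, random_state=seed, **kwargs
    )
    return est.fit(hist).result_()


def select_components(
    hist: LifetimeHistogram | LifetimeDataset,
    n_range=range(1, 6),
    kind: str = "exponential",
    n_starts: int = 50,
    seed: int | None = None,
    **kwargs,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit every component count in ``n_range`` and select by minimum BIC.

    Besides the random starts, each model is additionally started from the
    previous (smaller) model's optimum with one duplicated component, which
    makes the minimized cost non-increasing in ``n``.

    Returns the best fit and a comparison table with columns
    ``n, cost, k_exp, aic, bic``.
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("n_range must be nonempty")
    rows = []
    fits: dict[int, MixtureFit] = {}
    prev: MixtureFit | None = None
    for n in sorted(n_range):
        warm = []
        if prev is not None and n == prev.n_components + 1:
            params = [c.parameter for c in prev.components]
            mu = [c.mu for c in prev.components]
            # split the heaviest component into two equal halves
            j = int(np.argmax(mu))
            params.append(params[j] * 1.05)
            mu[j] /= 2.0
            mu.append(mu[j])
            warm.append((np.array(params), np.array(mu)))
        fit = TruncatedLifetimeMixture(
            n_components=n,
            kind=kind,
            n_starts=n_starts,
            random_state=seed,
            warm_starts=warm,
            **kwargs,
        ).fit(hist).result_()
        fits[n] = fit
        prev = fit
        rows.append(
            {"n": n, "cost": fit.cost, "k_exp": fit.k_exp, "aic": fit.aic, "bic": fit.bic}
        )
    table = pd.DataFrame(rows)
    best_n = int(table.loc[table["bic"].idxmin(), "n"])
    return fits[best_n], table
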