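import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from sklearn.base import clone

from cmekinetics import (
    LifetimeDataset,
    LifetimeHistogram,
    TruncatedLifetimeMixture,
    build_histogram,
    window_mass,
    truncated_density,
    fit_mixture,
    select_components,
    correct_fractions,
)
from cmekinetics.mixture import _bin_mass_density, _pointwise_density
from cmekinetics.simulate import MixtureSpec, sample_mixture_lifetimes

T_LOW, T_HIGH = 5.0, 601.0


def analytic_histogram(rates, weights, t_low=T_LOW, t_high=T_HIGH, dt=1.0):
    """Noiseless histogram: the mixture's own frame-bin masses on the grid."""
    grid = np.arange(t_low, t_high + dt / 2, dt)
    comp = _bin_mass_density("exponential", np.asarray(rates, float), grid, dt)
    h = comp @ np.asarray(weights, float)
    h = h / (h.sum() * dt)
    return LifetimeHistogram(grid, h, dt, n_lifetimes=10**6)


class TestHistogram:
    def test_point_mass(self):
        ds = LifetimeDataset(np.full(100, 5.0), 1.0, 5.0, 601.0)
        hist = build_histogram(ds)
        assert hist.density[0] == pytest.approx(1.0)
        assert hist.density[1:].sum() == 0.0

    def test_uniform_support(self):
        ds = LifetimeDataset(np.arange(5.0, 15.0), 1.0, 5.0, 601.0)
        hist = build_histogram(ds)
        assert np.allclose(hist.density[:10], 0.1)

    def test_normalization_large_sample(self):
        # printed subpopulation percentages renormalized to sum exactly to 1
        w = np.array([0.0631, 0.506, 0.439])
        w = w / w.sum()
        spec = MixtureSpec(
            components=[("exponential", 2.0, w[0]),
                        ("exponential", 9.0, w[1]),
                        ("exponential", 42.0, w[2])],
        )
        ds = sample_mixture_lifetimes(spec, 149162, seed=0)
        hist = build_histogram(ds)
        assert abs(hist.density.sum() * hist.frame_interval - 1.0) < 1e-9

    def test_off_grid_lifetime_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            LifetimeDataset(np.array([5.0, 6.5]), 1.0, 5.0, 601.0)


class TestWindowMass:
    def test_exponential_closed_form_and_quadrature(self):
        lam = 1.0 / 42.0
        omega = window_mass("exponential", lam, T_LOW, T_HIGH)
        assert omega == pytest.approx(
            math.exp(-lam * T_LOW) - math.exp(-lam * T_HIGH), abs=1e-15
        )
        num, _ = quad(lambda t: lam * math.exp(-lam * t), T_LOW, T_HIGH)
        assert omega == pytest.approx(num, abs=1e-10)

    def test_full_support_is_one(self):
        assert window_mass("exponential", 0.3, 0.0, 1e9) == pytest.approx(1.0)

    def test_rayleigh_half_mass(self):
        sigma = 7.0
        t_half = sigma * math.sqrt(2 * math.log(2))
        assert window_mass("rayleigh", sigma, 0.0, t_half) == pytest.approx(0.5)

    def test_invalid_parameter(self):
        with pytest.raises(ValueError):
            window_mass("exponential", 0.0, T_LOW, T_HIGH)


class TestTruncatedDensity:
    @pytest.mark.parametrize("kind,param", [
        ("exponential", 0.5), ("exponential", 1 / 42), ("rayleigh", 20.0)])
    def test_integrates_to_one(self, kind, param):
        total, _ = quad(
            lambda t: truncated_density(kind, param, t, T_LOW, T_HIGH),
            T_LOW, T_HIGH, limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_fast_component_at_lower_edge(self):
        # upper-tail mass negligible: f(t_low) ~ rate
        f = truncated_density("exponential", 0.5, T_LOW, T_LOW, T_HIGH)
        assert f == pytest.approx(0.5, rel=1e-6)

    def test_outside_window_rejected(self):
        with pytest.raises(ValueError):
            truncated_density("exponential", 0.5, 4.0, T_LOW, T_HIGH)

    def test_two_rates_cross_once(self):
        f1 = lambda t: truncated_density("exponential", 0.2, t, T_LOW, T_HIGH)
        f2 = lambda t: truncated_density("exponential", 0.02, t, T_LOW, T_HIGH)
        root = brentq(lambda t: f1(t) - f2(t), T_LOW, T_HIGH)
        assert T_LOW < root < T_HIGH
        # strictly one sign change on a fine grid
        tt = np.linspace(T_LOW, T_HIGH, 5000)
        diff = np.sign([f1(t) - f2(t) for t in tt])
        assert np.sum(np.abs(np.diff(diff)) > 0) == 1


class TestFit:
    def test_noiseless_single_component_self_consistency(self):
        lam = 0.05
        hist = analytic_histogram([lam], [1.0])
        fit = fit_mixture(hist, n=1, n_starts=10, seed=0)
        assert fit.components[0].parameter == pytest.approx(lam, rel=1e-6)
        assert fit.cost < 1e-12

    def test_noiseless_pointwise_mode_self_consistency(self):
        lam = 0.05
        grid = np.arange(T_LOW, T_HIGH + 0.5, 1.0)
        f = _pointwise_density("exponential", np.array([lam]), grid)[:, 0]
        h = f / (f.sum() * 1.0)
        hist = LifetimeHistogram(grid, h, 1.0, 10**6)
        est = TruncatedLifetimeMixture(
            n_components=1, n_starts=10, random_state=0, binning="point"
        ).fit(hist)
        # pointwise density does not sum to 1 on a coarse grid, so the
        # renormalized target is a slightly scaled model curve; the rate
        # still identifies the shape up to a small discretization bias
        # (~lam*dt/2), which is why "mass" is the default evaluation
        assert est.rates_[0] == pytest.approx(lam, rel=0.05)

    def test_noiseless_two_components(self):
        hist = analytic_histogram([1 / 8, 1 / 40], [0.6, 0.4])
        fit = fit_mixture(hist, n=2, n_starts=30, seed=1)
        assert fit.means == pytest.approx([8.0, 40.0], rel=1e-4)
        assert fit.fractions == pytest.approx([0.6, 0.4], abs=1e-5)

    def test_k_exp_counts(self):
        hist = analytic_histogram([0.05], [1.0])
        assert fit_mixture(hist, 1, n_starts=3, seed=0).k_exp == 1
        assert fit_mixture(hist, 3, n_starts=3, seed=0).k_exp == 5

    def test_information_criteria_arithmetic(self):
        rng = np.random.default_rng(42)
        hist = analytic_histogram([0.05], [1.0])
        fit = fit_mixture(hist, 2, n_starts=5, seed=0)
        N, k, cost = fit.n_bins, fit.k_exp, fit.cost
        assert fit.aic == pytest.approx(2 * k + N * math.log(cost / N))
        assert fit.bic == pytest.approx(k * math.log(N) + N * math.log(cost / N))
        del rng

    def test_deterministic_given_seed(self):
        spec = MixtureSpec(components=[("exponential", 9.0, 0.5),
                                       ("exponential", 42.0, 0.5)])
        ds = sample_mixture_lifetimes(spec, 20000, seed=3)
        f1 = fit_mixture(ds, 2, n_starts=8, seed=9)
        f2 = fit_mixture(ds, 2, n_starts=8, seed=9)
        assert f1 == f2

    def test_more_starts_never_worse(self):
        spec = MixtureSpec(components=[("exponential", 4.0, 0.3),
                                       ("exponential", 30.0, 0.7)])
        ds = sample_mixture_lifetimes(spec, 20000, seed=5)
        hist = build_histogram(ds)
        costs = [
            fit_mixture(hist, 2, n_starts=k, seed=123).cost for k in (2, 5, 10)
        ]
        assert costs[1] <= costs[0] + 1e-15
        assert costs[2] <= costs[1] + 1e-15

    def test_sklearn_protocol(self):
        est = TruncatedLifetimeMixture(n_components=2, random_state=1)
        params = est.get_params()
        assert params["n_components"] == 2
        est2 = clone(est).set_params(n_components=3)
        assert est2.get_params()["n_components"] == 3
        hist = analytic_histogram([0.05], [1.0])
        est3 = TruncatedLifetimeMixture(n_components=1, n_starts=5,
                                        random_state=0).fit(hist)
        assert est3.score() == -est3.cost_
        dens = est3.predict_density([10.0, 50.0])
        assert (dens > 0).all()

    def test_rayleigh_fit_recovers_scale(self):
        spec = MixtureSpec(components=[("rayleigh", 20.0, 1.0)])
        ds = sample_mixture_lifetimes(spec, 50000, seed=2)
        fit = fit_mixture(ds, 1, kind="rayleigh", n_starts=10, seed=0)
        assert fit.components[0].parameter == pytest.approx(20.0, rel=0.05)


class TestSelection:
    def test_cost_non_increasing_in_n(self):
        spec = MixtureSpec(components=[("exponential", 9.0, 0.55),
                                       ("exponential", 42.0, 0.45)])
        ds = sample_mixture_lifetimes(spec, 30000, seed=8)
        _, table = select_components(ds, n_range=range(1, 5), n_starts=10, seed=0)
        assert (np.diff(table["cost"].to_numpy()) <= 1e-15).all()

    def test_single_component_data_dominant_recovery(self):
        # Model selection on truly single-population data.  The unweighted
        # least-squares cost concentrates the sampling noise in the
        # high-density early bins, which an occasional spurious fast
        # component can absorb, so BIC does not pick n=1 every time; what
        # holds is that n=1 wins in most seeds and that the true population
        # is always recovered as the dominant component, with any spurious
        # extras carrying only a few percent of the weight.
        scale = 42.0
        spec = MixtureSpec(components=[("exponential", scale, 1.0)])
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            ds = sample_mixture_lifetimes(spec, 20000, seed=100 + s)
            best, _ = select_components(ds, n_range=range(1, 4), n_starts=6,
                                        seed=s)
            hits += best.n_components == 1
            j = int(np.argmax(best.fractions))
            assert best.means[j] == pytest.approx(scale, rel=0.10)
            assert 1.0 - best.fractions[j] < 0.05
        assert hits >= 0.6 * n_seeds


class TestCorrectFractions:
    def test_equal_masses_identity(self):
        mu0 = correct_fractions([0.2, 0.3, 0.5], [0.7, 0.7, 0.7])
        assert mu0 == pytest.approx([0.2, 0.3, 0.5])

    def test_hand_solved_two_by_two(self):
        mu0 = correct_fractions([0.5, 0.5], [0.1, 0.9])
        assert mu0 == pytest.approx([0.9, 0.1])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        st.data(),
    )
    def test_forward_map_round_trip(self, raw_mu, data):
        mu = np.array(raw_mu) / np.sum(raw_mu)
        omega = np.array(
            data.draw(st.lists(st.floats(0.01, 1.0), min_size=len(mu),
                               max_size=len(mu)))
        )
        mu0 = correct_fractions(mu, omega)
        forward = omega * mu0 / np.sum(omega * mu0)
        assert np.abs(forward - mu).max() < 1e-12
        assert np.sum(mu0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="zero mass"):
            correct_fractions([0.5, 0.5], [0.0, 0.9])
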