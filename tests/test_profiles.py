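import numpy as np
import pandas as pd
import pytest

from cmekinetics import (
    MeanProfile,
    mean_cohort_profile,
    smooth_profile,
    segment_phases,
    departure_profile,
    PhaseSegmenter,
)
from cmekinetics.simulate import PhaseSpec, simulate_intensity_trajectory

from conftest import make_track


def trapezoid(L, a=0.4, m=0.2, peak=1.0):
    t = np.arange(L, dtype=float)
    return np.interp(t, [0, a * (L - 1), (a + m) * (L - 1), L - 1],
                     [0, peak, peak, 0])


def tracks_from_trajs(trajs, start=100):
    parts = []
    for tid, y in enumerate(trajs):
        parts.append(
            make_track(tid, np.arange(start, start + len(y)), 50.0, 50.0,
                       amplitude=y)
        )
    return pd.concat(parts, ignore_index=True)


class TestCohortProfile:
    def test_single_track_identity(self, movie):
        y = trapezoid(40)
        prof = mean_cohort_profile(tracks_from_trajs([y]), movie)
        assert prof.n_tracks == 1
        assert np.allclose(prof.sem, 0.0)
        assert np.allclose(prof.mean, y / y.max(), atol=1e-9)

    def test_identical_trapezoids(self, movie):
        trajs = [trapezoid(40, peak=7.0)] * 20
        prof = mean_cohort_profile(tracks_from_trajs(trajs), movie)
        assert np.allclose(prof.mean, trapezoid(40), atol=1e-9)
        assert np.allclose(prof.sem, 0.0, atol=1e-12)

    def test_sem_scales_with_noise_and_cohort_size(self, movie):
        rng = np.random.default_rng(0)
        peak, sd, m, L = 100.0, 10.0, 150, 40
        trajs = [trapezoid(L, peak=peak) + rng.normal(0, sd, L) for _ in range(m)]
        prof = mean_cohort_profile(tracks_from_trajs(trajs), movie)
        expected = sd / (peak * np.sqrt(m))
        mid = prof.sem[5:-5]
        assert np.median(mid) == pytest.approx(expected, rel=0.3)

    def test_permutation_invariant(self, movie):
        rng = np.random.default_rng(1)
        trajs = [trapezoid(L) for L in rng.integers(37, 44, 30)]
        df = tracks_from_trajs(trajs)
        p1 = mean_cohort_profile(df, movie)
        shuffled = tracks_from_trajs(trajs[::-1])
        p2 = mean_cohort_profile(shuffled, movie)
        assert np.allclose(p1.mean, p2.mean)

    def test_empty_cohort_reported(self, movie):
        trajs = [trapezoid(10)] * 5 + [trapezoid(30)] * 5  # mean 20, no member
        with pytest.raises(ValueError, match="empty cohort"):
            mean_cohort_profile(tracks_from_trajs(trajs), movie)


class TestSmooth:
    def _profile(self, y, dt=1.0):
        return MeanProfile(np.arange(len(y)) * dt, y, np.zeros(len(y)), 10,
                           (len(y), len(y)))

    def test_constant_unchanged(self):
        prof = self._profile(np.full(50, 3.0))
        assert np.allclose(smooth_profile(prof).mean, 3.0, atol=1e-10)

    def test_linear_unchanged_interior(self):
        y = np.linspace(0, 1, 60)
        sm = smooth_profile(self._profile(y), span=0.2).mean
        assert np.allclose(sm[5:-5], y[5:-5], atol=1e-8)

    def test_noise_reduced_on_trapezoid(self):
        rng = np.random.default_rng(2)
        clean = trapezoid(60)
        noisy = clean + rng.normal(0, 0.05, 60)
        sm = smooth_profile(self._profile(noisy), span=0.15).mean
        assert np.std(sm - clean) < np.std(noisy - clean)

    def test_bad_span_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self._profile(np.zeros(50)), span=0.0)


class TestSegmentation:
    def _profile(self, y, dt=1.0):
        return MeanProfile(np.arange(len(y)) * dt, y, np.zeros(len(y)), 10,
                           (len(y), len(y)))

    def test_trapezoid_breakpoints_recovered(self):
        seg = segment_phases(self._profile(trapezoid(100, 0.4, 0.2)))
        assert seg.fractions[0] == pytest.approx(0.4, abs=0.011)
        assert seg.fractions[1] == pytest.approx(0.2, abs=0.02)

    @pytest.mark.parametrize("a,m", [(0.15, 0.2), (0.3, 0.4), (0.42, 0.178),
                                     (0.6, 0.15), (0.2, 0.6)])
    def test_noiseless_recovery_within_one_frame(self, a, m):
        L = 200
        seg = segment_phases(self._profile(trapezoid(L, a, m)))
        assert abs(seg.assembly_end - a * (L - 1)) <= 1.0
        assert abs(seg.maturation_end - (a + m) * (L - 1)) <= 1.0

    def test_triangle_degenerate_plateau(self):
        L = 101
        y = np.interp(np.arange(L, dtype=float), [0, 50, 100], [0, 1, 0])
        seg = segment_phases(self._profile(y))
        assert seg.fractions[1] == pytest.approx(0.0, abs=1 / (L - 1))

    def test_scale_and_shift_invariance(self):
        y = trapezoid(80, 0.3, 0.3)
        s1 = segment_phases(self._profile(y))
        s2 = segment_phases(self._profile(5.0 * y + 11.0))
        assert s1.fractions == pytest.approx(s2.fractions, abs=1e-12)

    def test_fractions_sum_to_one(self):
        seg = segment_phases(self._profile(trapezoid(64, 0.25, 0.45)))
        assert sum(seg.fractions) == pytest.approx(1.0)

    def test_monotone_profile_rejected(self):
        y = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="not identifiable"):
            segment_phases(self._profile(y))

    def test_respects_frame_interval_units(self):
        y = trapezoid(100, 0.4, 0.2)
        seg = segment_phases(self._profile(y, dt=0.5))
        assert seg.assembly_end == pytest.approx(0.4 * 99 * 0.5, abs=0.5)

    def test_segmenter_estimator(self, movie):
        rng = np.random.default_rng(3)
        trajs = [
            simulate_intensity_trajectory(PhaseSpec(), 42, rng=rng)
            for _ in range(100)
        ]
        prof = mean_cohort_profile(tracks_from_trajs(trajs), movie)
        seg = PhaseSegmenter().fit(prof)
        assert 0.3 < seg.fractions_[0] < 0.55
        assert abs(sum(seg.fractions_) - 1.0) < 1e-9


class TestDeparture:
    def _two_channel(self, movie, slave_kind):
        rng = np.random.default_rng(4)
        masters, slaves = [], []
        for tid in range(25):
            L = int(rng.integers(38, 43))
            start = 100 + int(rng.integers(0, 30))
            ym = trapezoid(L, peak=50.0)
            if slave_kind == "constant":
                ys = np.full(L, 7.0)
            elif slave_kind == "master":
                ys = ym.copy()
            else:
                ys = np.linspace(0, 30.0, L)  # rises until departure
            masters.append(make_track(tid, np.arange(start, start + L),
                                      50.0, 50.0, amplitude=ym, channel="m"))
            slaves.append(make_track(tid, np.arange(start, start + L),
                                     50.0, 50.0, amplitude=ys, channel="s"))
        return (pd.concat(masters, ignore_index=True),
                pd.concat(slaves, ignore_index=True))

    def test_constant_slave_is_flat(self, movie):
        master, slave = self._two_channel(movie, "constant")
        _, sp = departure_profile(master, slave, movie)
        assert np.allclose(sp.mean, 1.0, atol=1e-9)

    def test_slave_equals_master(self, movie):
        master, slave = self._two_channel(movie, "master")
        mp, sp = departure_profile(master, slave, movie)
        assert np.allclose(mp.mean, sp.mean, atol=1e-9)

    def test_offsets_end_at_departure(self, movie):
        master, slave = self._two_channel(movie, "rising")
        mp, sp = departure_profile(master, slave, movie)
        assert mp.offsets[-1] == 0.0
        assert (np.diff(mp.offsets) > 0).all()
        # slave keeps rising right up to master departure
        assert sp.mean[-1] == pytest.approx(sp.mean.max(), rel=1e-6)

    def test_unmatched_ids_listed(self, movie):
        master, slave = self._two_channel(movie, "constant")
        slave = slave[slave.track_id != 3]
        with pytest.raises(ValueError, match=r"\b3\b"):
            departure_profile(master, slave, movie)
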