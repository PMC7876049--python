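import numpy as np
import pytest

from helixhop.mode_segmentation import (IMMOBILE, MOBILE, decode_modes,
                                        extract_mobile_segments,
                                        fit_two_state_hmm, immobile_fraction,
                                        windowed_displacements)
from helixhop.trajectory_io import CylTrajectory


def _traj(X, Y, dt=0.1):
    n = len(X)
    return CylTrajectory(np.arange(n) * dt, X, Y)


class TestWindowedDisplacements:
    def test_constant_trajectory(self):
        traj = _traj(np.zeros(50), np.zeros(50))
        series = windowed_displacements(traj, 0.3)
        assert np.all(series.s == 0)

    def test_pure_drift(self):
        t = np.arange(50) * 0.1
        series = windowed_displacements(_traj(0.3 * t, 0.1 * t), 0.3)
        # noiseless drift: zero variance displacements normalize to zero
        assert np.allclose(series.s, series.s[0])

    def test_length_bookkeeping(self):
        traj = _traj(np.random.default_rng(0).normal(size=60),
                     np.zeros(60))
        series = windowed_displacements(traj, 0.3)
        assert len(series) == 60 - 3

    def test_bad_windows(self):
        traj = _traj(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError):
            windowed_displacements(traj, 0.05)   # shorter than dt
        with pytest.raises(ValueError):
            windowed_displacements(traj, 10.0)   # longer than trajectory
        with pytest.raises(ValueError):
            windowed_displacements(traj, 0.25)   # not a multiple of dt


def _bimodal_series(seed=0, n=600, mean_lo=0.2, mean_hi=3.0, sd=0.3,
                    p_switch=0.05):
    """Two-state Markov sequence with Gaussian emissions; returns truth."""
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=int)
    states[0] = 1
    for i in range(1, n):
        states[i] = states[i - 1] if rng.random() > p_switch \
            else 1 - states[i - 1]
    s = np.where(states == 1, rng.normal(mean_hi, sd, n),
                 rng.normal(mean_lo, sd, n))
    from helixhop.mode_segmentation import WindowedDisplacementSeries
    series = WindowedDisplacementSeries(t=np.arange(n) * 0.1,
                                        s=np.abs(s), window=0.3,
                                        window_frames=3)
    return series, states


class TestHmmFit:
    def test_recovers_emission_means(self):
        series, _ = _bimodal_series(seed=1)
        fit = fit_two_state_hmm(series, seed=0)
        assert fit.means[IMMOBILE] == pytest.approx(0.2, abs=0.1)
        assert fit.means[MOBILE] == pytest.approx(3.0, abs=0.1)
        assert fit.converged
        assert np.allclose(fit.transition.sum(axis=1), 1.0)

    def test_degenerate_flagged(self):
        from helixhop.mode_segmentation import WindowedDisplacementSeries
        series = WindowedDisplacementSeries(np.arange(40) * 0.1,
                                            np.full(40, 1.7), 0.3, 3)
        fit = fit_two_state_hmm(series)
        assert fit.degenerate and not fit.converged

    def test_relabeling_is_deterministic(self):
        """Whatever the restart order, mobile is the larger-mean state."""
        series, _ = _bimodal_series(seed=2)
        fits = [fit_two_state_hmm(series, seed=s) for s in (0, 99)]
        for fit in fits:
            assert fit.means[MOBILE] > fit.means[IMMOBILE]
        assert fits[0].means == pytest.approx(fits[1].means, abs=0.05)

    def test_too_short_rejected(self):
        from helixhop.mode_segmentation import WindowedDisplacementSeries
        series = WindowedDisplacementSeries(np.arange(10) * 0.1,
                                            np.random.rand(10), 0.3, 3)
        with pytest.raises(ValueError):
            fit_two_state_hmm(series)


class TestDecode:
    def test_two_block_accuracy(self):
        series, states = _bimodal_series(seed=3, p_switch=0.01)
        fit = fit_two_state_hmm(series, seed=0)
        labels = decode_modes(fit)
        assert np.mean(labels == states) >= 0.95

    def test_all_mobile(self):
        rng = np.random.default_rng(4)
        from helixhop.mode_segmentation import WindowedDisplacementSeries
        series = WindowedDisplacementSeries(
            np.arange(200) * 0.1, np.abs(rng.normal(3.0, 0.3, 200)), 0.3, 3)
        fit = fit_two_state_hmm(series, seed=0)
        labels = decode_modes(fit)
        assert immobile_fraction(labels) <= 0.05


class TestSegments:
    def test_all_mobile_single_segment(self):
        traj = _traj(np.arange(30.0), np.zeros(30))
        labels = np.ones(25, dtype=int)
        segs = extract_mobile_segments(traj, labels)
        assert segs.segments == [(0, 24)]
        assert len(segs.virtual_dX) == 24

    def test_immobile_block_bookkeeping(self):
        """Displacement count = total - block - 1 boundary displacement."""
        traj = _traj(np.arange(30.0), np.zeros(30))
        labels = np.ones(30, dtype=int)
        labels[10:20] = IMMOBILE
        segs = extract_mobile_segments(traj, labels)
        assert segs.segments == [(0, 9), (20, 29)]
        total_disp = 29
        assert len(segs.virtual_dX) == total_disp - 10 - 1

    def test_short_segments_dropped(self):
        traj = _traj(np.arange(20.0), np.zeros(20))
        labels = np.tile([1, 0], 10)
        segs = extract_mobile_segments(traj, labels, min_len=5)
        assert segs.empty and len(segs.virtual_dX) == 0

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        X = np.cumsum(rng.normal(0.03, 0.01, 80))
        Y = np.cumsum(rng.normal(0.01, 0.01, 80))
        labels = (rng.random(75) > 0.2).astype(int)
        a = extract_mobile_segments(_traj(X, Y), labels)
        b = extract_mobile_segments(_traj(X + 5.0, Y - 3.0), labels)
        assert a.segments == b.segments
        assert np.allclose(a.virtual_dX, b.virtual_dX)


class TestImmobileFraction:
    def test_counts(self):
        labels = np.ones(100, dtype=int)
        labels[:5] = IMMOBILE
        assert immobile_fraction(labels) == 0.05
        assert immobile_fraction(np.ones(10, dtype=int)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            immobile_fraction(np.empty(0))

    def test_trapped_cohort_fraction(self, m2_like_cohort):
        """Pooled immobile fraction tracks the generator's 8% occupancy."""
        cfg, trajs, truths, _, _ = m2_like_cohort
        imm = tot = 0
        for i, traj in enumerate(trajs[:12]):
            series = windowed_displacements(traj, cfg.window_s)
            labels = decode_modes(fit_two_state_hmm(series, seed=50 + i))
            imm += int(np.sum(labels == IMMOBILE))
            tot += len(labels)
        assert 0.05 <= imm / tot <= 0.11
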