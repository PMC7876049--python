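import itertools
import math

import numpy as np
import pytest

from helixhop.macroscopic_estimators import (MsdCurve, average_msd, cve_params,
                                             fit_corkscrew_pitch,
                                             fit_msd_quadratic, msd_curve,
                                             segment_displacements)


def brute_force_cve(dx, dy, dt):
    """Independent plain-loop evaluation of the eight estimators.

    Mirrors the defining sums term by term with explicit Python loops over
    the adjacent displacement pairs of a single segment; kept free of any
    code shared with the vectorized implementation.
    """
    m = len(dx)
    vx = sum(dx) / m / dt
    vy = sum(dy) / m / dt
    u = [a - vx * dt for a in dx]
    w = [a - vy * dt for a in dy]
    ks = range(m - 1)  # adjacent-pair positions

    def mean(fn):
        return sum(fn(k) for k in ks) / len(ks)

    twoDx = (mean(lambda k: u[k] ** 2) + 2 * mean(lambda k: u[k + 1] * u[k])) / dt
    twoDy = (mean(lambda k: w[k] ** 2) + 2 * mean(lambda k: w[k + 1] * w[k])) / dt
    A = (mean(lambda k: u[k] * w[k]) + mean(lambda k: u[k + 1] * w[k])
         + mean(lambda k: u[k] * w[k + 1])) / dt
    B = sum(mean(lambda k, a=a, b=b, g=g: u[k + a] * u[k + b] * w[k + g])
            for a, b, g in itertools.product((0, 1), repeat=3)
            if (a, b, g) != (1, 1, 1)) / dt
    C = sum(mean(lambda k, a=a, b=b, g=g: u[k + a] * w[k + b] * w[k + g])
            for a, b, g in itertools.product((0, 1), repeat=3)
            if (a, b, g) != (1, 1, 1)) / dt

    def f(i, j, p, q):
        return (mean(lambda k: u[k + i] * u[k + j] * w[k + p] * w[k + q])
                - mean(lambda k: u[k + i] * u[k + j]) * mean(lambda k: w[k + p] * w[k + q])
                - mean(lambda k: u[k + i] * w[k + p]) * mean(lambda k: u[k + j] * w[k + q])
                - mean(lambda k: u[k + i] * w[k + q]) * mean(lambda k: u[k + j] * w[k + p]))

    E = sum(f(a, b, g, lam)
            for a, b, g, lam in itertools.product((0, 1), repeat=4)
            if (a, b, g, lam) != (1, 1, 1, 1)) / dt
    return np.array([vx, vy, twoDx, twoDy, A, B, C, E])


class TestCve:
    def test_pure_drift_all_zero(self):
        dx = np.full(20, 0.03)
        dy = np.full(20, 0.01)
        p = cve_params([(dx, dy)], 0.1)
        assert p.v_x == pytest.approx(0.3)
        assert p.v_y == pytest.approx(0.1)
        for val in (p.twoD_x, p.twoD_y, p.A, p.B, p.C, p.E):
            assert val == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_toy_displacements(self):
        """Every output equals an independent loop evaluation of the sums."""
        rng = np.random.default_rng(7)
        dx = rng.normal(0.02, 0.05, 15)
        dy = rng.normal(0.0, 0.04, 15)
        p = cve_params([(dx, dy)], 0.1)
        expected = brute_force_cve(list(dx), list(dy), 0.1)
        assert p.as_vector() == pytest.approx(expected, rel=1e-10)

    def test_offset_and_time_origin_invariance(self):
        """CVE works on displacements: absolute offsets never enter."""
        rng = np.random.default_rng(8)
        X = np.cumsum(rng.normal(0.02, 0.05, 60))
        Y = np.cumsum(rng.normal(0.0, 0.04, 60))
        segs = [(0, 29), (31, 59)]
        a = cve_params(segment_displacements(X, Y, segs), 0.1)
        b = cve_params(segment_displacements(X + 7.3, Y - 2.2, segs), 0.1)
        assert a.as_vector() == pytest.approx(b.as_vector(), rel=1e-12)

    def test_noise_cancellation(self):
        """CVE cancels localization noise; the naive variance does not."""
        rng = np.random.default_rng(42)
        dt, D, v, sig = 0.1, 2e-4, 0.3, 3e-3
        segs, naive = [], []
        for _ in range(50):
            steps = rng.normal(v * dt, math.sqrt(2 * D * dt), 1000)
            x = np.concatenate([[0.0], np.cumsum(steps)])
            x = x + rng.normal(0, sig, len(x))
            dx = np.diff(x)
            segs.append((dx, rng.normal(0, 1e-3, len(dx))))
            naive.append(np.var(dx - dx.mean()) / (2 * dt))
        est = cve_params(segs, dt).twoD_x / 2
        assert est == pytest.approx(D, rel=0.05)
        assert np.mean(naive) - D == pytest.approx(sig ** 2 / dt, rel=0.10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cve_params([(np.ones(5), np.ones(5))], 0.1)


class TestMsd:
    def test_pure_drift_exact(self):
        x = 0.3 * np.arange(50) * 0.1
        curve = msd_curve([x], dt=0.1)
        assert curve.msd == pytest.approx((0.3 * curve.tau) ** 2)

    def test_pair_counting_segment_of_11(self):
        x = np.arange(11.0)
        curve = msd_curve([x], dt=0.1, tau_max=1.0)
        # lag 10 (tau=1.0) has exactly one pair in an 11-point segment
        assert curve.tau[-1] == pytest.approx(1.0)
        assert curve.msd[-1] == pytest.approx(100.0)

    def test_diffusion_slope(self):
        rng = np.random.default_rng(11)
        D, dt = 0.01, 0.1
        curves = []
        for _ in range(40):
            x = np.cumsum(rng.normal(0, math.sqrt(2 * D * dt), 500))
            curves.append(msd_curve([x], dt=dt))
        avg = average_msd(curves)
        fit = fit_msd_quadratic(avg)
        assert fit["D"] == pytest.approx(D, abs=3 * max(fit["se_D"], 1e-4))

    def test_cross_segment_pairs_excluded(self):
        a, b = np.arange(8.0), np.arange(100.0, 106.0)
        curve = msd_curve([a, b], dt=0.1, tau_max=0.5)
        # a jump between segments would inflate MSD by ~1e4
        assert curve.msd.max() < 30

    def test_no_long_segment_rejected(self):
        with pytest.raises(ValueError):
            msd_curve([np.arange(4.0)], dt=0.1, tau_max=1.0)


class TestMsdFit:
    def test_exact_recovery(self):
        tau = np.arange(1, 11) * 0.1
        se = np.full(10, 0.01)
        exact = 0.001 + 2 * 0.005 * tau + 0.2 ** 2 * tau ** 2
        fit = fit_msd_quadratic(MsdCurve(tau, exact, se, 1))
        assert fit["y0"] == pytest.approx(0.001, abs=1e-6)
        assert fit["v"] == pytest.approx(0.2, abs=1e-6)
        assert fit["D"] == pytest.approx(0.005, abs=1e-6)
        assert not fit["clamped"]

    def test_drift_only(self):
        tau = np.arange(1, 11) * 0.1
        fit = fit_msd_quadratic(MsdCurve(tau, (0.3 * tau) ** 2,
                                         np.full(10, 0.01), 1))
        assert fit["v"] == pytest.approx(0.3, abs=1e-8)
        assert fit["D"] == pytest.approx(0.0, abs=1e-8)

    def test_negative_D_clamped(self):
        tau = np.arange(1, 11) * 0.1
        msd = 0.01 - 2 * 0.003 * tau + 0.3 ** 2 * tau ** 2
        fit = fit_msd_quadratic(MsdCurve(tau, msd, np.full(10, 0.01), 1))
        assert fit["D"] == 0.0 and fit["clamped"]


class TestCorkscrewPitch:
    def test_noise_free(self):
        x = np.linspace(0, 3, 300)
        y = 0.05 * np.sin(2 * np.pi * x / 1.0 + 0.5) + 0.01
        pitch, amp = fit_corkscrew_pitch(x, y)
        assert pitch == pytest.approx(1.0, rel=1e-6)
        assert amp == pytest.approx(0.05, rel=1e-6)

    def test_noisy_within_two_percent(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0, 4, 400)
        y = 0.05 * np.sin(2 * np.pi * x / 1.3) + rng.normal(0, 0.0025, 400)
        pitch, _ = fit_corkscrew_pitch(x, y)
        assert pitch == pytest.approx(1.3, rel=0.02)

    def test_flat_rejected(self):
        x = np.linspace(0, 3, 100)
        with pytest.raises(ValueError):
            fit_corkscrew_pitch(x, np.full_like(x, 0.2))


def test_cve_and_msd_agree_on_clean_drift_diffusion():
    """Without noise the two estimation routes give the same v and D."""
    rng = np.random.default_rng(21)
    dt, D, v = 0.1, 0.005, 0.25
    segs, curves = [], []
    for _ in range(30):
        steps = rng.normal(v * dt, math.sqrt(2 * D * dt), 800)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        segs.append((np.diff(x), rng.normal(0, 1e-4, 800)))
        curves.append(msd_curve([x], dt=dt))
    cve = cve_params(segs, dt)
    fit = fit_msd_quadratic(average_msd(curves))
    assert cve.v_x == pytest.approx(v, abs=0.01)
    assert fit["v"] == pytest.approx(cve.v_x, abs=0.02)
    assert fit["D"] == pytest.approx(cve.twoD_x / 2, abs=5e-4)
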