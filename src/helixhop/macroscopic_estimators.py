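"""Per-trajectory macroscopic motion parameters.

Two routes from a (mobile-segment) trajectory to velocity and diffusion:

* MSD: mean square displacement over intervals 0.1–1.0 s, fitted with the
  quadratic MSD(τ) = y0 + 2Dτ + v²τ² (inverse-variance weights, parameters
  bounded below by 0).
* Covariance-based estimators (CVE): drift-adjusted displacement moments
  combining the per-frame variance with the covariance of *adjacent*
  displacements, which cancels the (independent, additive) localization
  noise.  Extended here to the higher-order coefficients A, B, C, E — the
  per-time rates of the joint cumulants κ11, κ21, κ12, κ22 of the 2D
  displacement — which carry the directional information that velocity and
  diffusion alone cannot resolve.

With per-frame displacements u_k = ΔZ_k (drift-adjusted, Z = X − v_x t)
and w_k = ΔW_k the estimators are (all divided by Δt)::

    2D_x = <u_k²> + 2<u_{k+1} u_k>
    2D_y = <w_k²> + 2<w_{k+1} w_k>
    A    = <u_k w_k> + <u_{k+1} w_k> + <u_k w_{k+1}>
    B    = Σ_{(α,β,γ)≠(1,1,1)} <u_{k+α} u_{k+β} w_{k+γ}>
    C    = Σ_{(α,β,γ)≠(1,1,1)} <u_{k+α} w_{k+β} w_{k+γ}>
    E    = Σ_{(α,β,γ,λ)≠(1,1,1,1)} f(u_{k+α}, u_{k+β}, w_{k+γ}, w_{k+λ})

with f(x,y,z,w) = <xyzw> − <xy><zw> − <xz><yw> − <xw><yz> and α,β,γ,λ ∈
{0,1}.  Expectations are sample means over all adjacent-index pairs that
lie within a single mobile segment, pooled across segments (weighted by
pair count); products never span a segment boundary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .mode_segmentation import MobileSegments

__all__ = [
    "MsdCurve",
    "MacroscopicParams",
    "segment_displacements",
    "msd_curve",
    "average_msd",
    "fit_msd_quadratic",
    "cve_params",
    "fit_corkscrew_pitch",
]


@dataclass
class MsdCurve:
    """MSD versus interval, mean ± SE (across trajectories if averaged)."""

    tau: np.ndarray
    msd: np.ndarray
    se: np.ndarray
    n: int  # trajectories (1 for a per-trajectory curve)


@dataclass
class MacroscopicParams:
    """The 8 macroscopic parameters of one trajectory.

    Units are (length unit)/s etc. of the input coordinates: lattice sites
    when the trajectory was mapped onto the lattice, physical units
    otherwise.  Variance-like entries may be negative by sampling noise and
    are reported as estimated; positivity is enforced only in the Bayesian
    inversion downstream.
    """

    v_x: float
    v_y: float
    twoD_x: float
    twoD_y: float
    A: float
    B: float
    C: float
    E: float
    n_frames: int
    coords: str = "physical"

    def as_vector(self) -> np.ndarray:
        return np.array([self.v_x, self.v_y, self.twoD_x, self.twoD_y,
                         self.A, self.B, self.C, self.E])


def segment_displacements(X, Y, segments) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-segment lag-1 displacement arrays for (start, end) point ranges."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    return [(np.diff(X[a:b + 1]), np.diff(Y[a:b + 1])) for a, b in segments]


def msd_curve(segments: list[np.ndarray], dt: float, tau_max: float = 1.0,
              tau_min: float | None = None) -> MsdCurve:
    """Per-trajectory MSD over a τ grid for 1D positions split by segment.

    ``segments``: position arrays, one per mobile segment; all overlapping
    pairs within a segment contribute, pairs across segments never do.
    The default grid is Δt…1.0 s (0.1–1.0 s at 0.1 s sampling).
    """
    if tau_min is None:
        tau_min = dt
    lags = np.arange(max(1, int(round(tau_min / dt))),
                     int(round(tau_max / dt)) + 1)
    if len(lags) == 0:
        raise ValueError("empty tau grid")
    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    for seg in segments:
        seg = np.asarray(seg, float)
        for i, L in enumerate(lags):
            if len(seg) > L:
                d = seg[L:] - seg[:-L]
                sums[i] += np.sum(d * d)
                counts[i] += len(d)
    if counts[0] == 0 or np.any(counts == 0):
        raise ValueError("no segment long enough for the requested tau grid")
    msd = sums / counts
    return MsdCurve(tau=lags * dt, msd=msd, se=np.full(len(lags), np.nan), n=1)


def average_msd(curves: list[MsdCurve]) -> MsdCurve:
    """Average per-trajectory MSD curves: mean ± SE across trajectories."""
    if not curves:
        raise ValueError("no curves to average")
    tau = curves[0].tau
    stack = np.vstack([c.msd for c in curves])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / math.sqrt(len(curves)) if len(curves) > 1 \
        else np.full_like(mean, np.nan)
    return MsdCurve(tau=tau, msd=mean, se=se, n=len(curves))


def fit_msd_quadratic(curve: MsdCurve):
    """Fit MSD(τ) = y0 + 2Dτ + v²τ² with inverse-variance weights.

    The model is linear in (y0, 2D, v²); the bounded fit (all three ≥ 0)
    is solved exactly by non-negative least squares on the weighted design.
    Returns a dict with y0, v, D, their standard errors, and ``clamped``
    (True when a lower bound is active).
    """
    tau, msd, se = curve.tau, curve.msd, curve.se
    if len(tau) < 3:
        raise ValueError("need at least 3 tau points")
    w = np.ones_like(tau) if np.any(~np.isfinite(se)) or np.any(se <= 0) \
        else 1.0 / se
    design = np.column_stack([np.ones_like(tau), tau, tau ** 2])
    Aw = design * w[:, None]
    bw = msd * w
    if np.linalg.matrix_rank(Aw) < 3:
        raise ValueError("singular design matrix")
    coef, _ = optimize.nnls(Aw, bw)
    free = np.linalg.lstsq(Aw, bw, rcond=None)[0]
    clamped = bool(np.any((free < 0) & (coef <= 1e-300)))
    y0, c1, c2 = coef
    v, D = math.sqrt(c2), c1 / 2.0
    # covariance of the weighted linear fit, delta method for v
    dof = max(len(tau) - 3, 1)
    resid = bw - Aw @ coef
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(Aw.T @ Aw)
        se_y0 = math.sqrt(max(cov[0, 0], 0.0))
        se_D = math.sqrt(max(cov[1, 1], 0.0)) / 2.0
        se_v = math.sqrt(max(cov[2, 2], 0.0)) / (2.0 * v) if v > 0 else math.inf
    except np.linalg.LinAlgError:
        se_y0 = se_D = se_v = math.nan
    return {"y0": y0, "v": v, "D": D, "se_y0": se_y0, "se_v": se_v,
            "se_D": se_D, "clamped": clamped}


def _pooled_pairs(disp_segments):
    """Stack (u_k, u_{k+1}, w_k, w_{k+1}) over all within-segment pairs."""
    u0, u1, w0, w1 = [], [], [], []
    for dx, dy in disp_segments:
        if len(dx) >= 2:
            u0.append(dx[:-1]); u1.append(dx[1:])
            w0.append(dy[:-1]); w1.append(dy[1:])
    if not u0:
        return None
    return tuple(np.concatenate(a) for a in (u0, u1, w0, w1))


def cve_params(disp_segments: list[tuple[np.ndarray, np.ndarray]] | MobileSegments,
               dt: float, coords: str = "physical") -> MacroscopicParams:
    """Covariance-based estimators of the 8 macroscopic parameters.

    ``disp_segments``: per-segment (ΔX, ΔY) per-frame displacement arrays
    (or a :class:`MobileSegments`, whose per-segment displacements are
    reconstructed; note adjacent-displacement products never cross a
    segment boundary).  Velocities come from the pooled mean displacement;
    the remaining six estimators use drift-adjusted displacements.
    """
    if isinstance(disp_segments, MobileSegments):
        raise TypeError(
            "pass per-segment displacement arrays (see segment_displacements); "
            "MobileSegments alone does not preserve segment boundaries")
    segs = [(np.asarray(dx, float), np.asarray(dy, float))
            for dx, dy in disp_segments if len(dx)]
    n_disp = sum(len(dx) for dx, _ in segs)
    all_dx = np.concatenate([dx for dx, _ in segs]) if segs else np.empty(0)
    all_dy = np.concatenate([dy for _, dy in segs]) if segs else np.empty(0)
    v_x = float(all_dx.mean()) / dt if n_disp else math.nan
    v_y = float(all_dy.mean()) / dt if n_disp else math.nan
    # drift-adjusted displacements: Z = X - v_x t  =>  dZ_k = dX_k - v_x dt
    adj = [(dx - v_x * dt, dy - v_y * dt) for dx, dy in segs]
    pooled = _pooled_pairs(adj)
    if pooled is None or len(pooled[0]) < 10:
        raise ValueError("need at least 10 within-segment displacement pairs")
    u0, u1, w0, w1 = pooled

    def m(*arrs):
        return float(np.mean(np.prod(arrs, axis=0)))

    twoD_x = (m(u0, u0) + 2.0 * m(u1, u0)) / dt
    twoD_y = (m(w0, w0) + 2.0 * m(w1, w0)) / dt
    A = (m(u0, w0) + m(u1, w0) + m(u0, w1)) / dt

    U = (u0, u1)
    W = (w0, w1)
    B = sum(m(U[a], U[b], W[g])
            for a, b, g in itertools.product((0, 1), repeat=3)
            if not (a == b == g == 1)) / dt
    C = sum(m(U[a], W[b], W[g])
            for a, b, g in itertools.product((0, 1), repeat=3)
            if not (a == b == g == 1)) / dt

    def f(x, y, z, w):
        return (m(x, y, z, w) - m(x, y) * m(z, w)
                - m(x, z) * m(y, w) - m(x, w) * m(y, z))

    E = sum(f(U[a], U[b], W[g], W[lam])
            for a, b, g, lam in itertools.product((0, 1), repeat=4)
            if not (a == b == g == lam == 1)) / dt

    return MacroscopicParams(v_x=v_x, v_y=v_y, twoD_x=twoD_x, twoD_y=twoD_y,
                             A=A, B=B, C=C, E=E, n_frames=n_disp, coords=coords)


def fit_corkscrew_pitch(x, y):
    """Fit the lateral wobble of a gliding-assay probe with a sine in x.

    Model: y = a·sin(2πx/pitch + φ) + c.  Returns (pitch, amplitude).
    Requires at least one full period in the x span; a flat trace or a
    non-converging fit raises with a residual report.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 8:
        raise ValueError("too few points for a sine fit")
    yc = y - y.mean()
    if yc.std() < 1e-12:
        raise ValueError("flat trace: no oscillation to fit")
    # initial pitch from the dominant frequency on a uniform resampling
    order = np.argsort(x)
    xs, ys = x[order], yc[order]
    grid = np.linspace(xs[0], xs[-1], max(256, len(x)))
    yg = np.interp(grid, xs, ys)
    freqs = np.fft.rfftfreq(len(grid), d=grid[1] - grid[0])
    power = np.abs(np.fft.rfft(yg - yg.mean()))
    k = int(np.argmax(power[1:]) + 1)
    pitch0 = 1.0 / freqs[k]
    span = xs[-1] - xs[0]
    if span < pitch0 * 0.99:
        raise ValueError("less than one full period present")

    def model(xv, a, pitch, phi, c):
        return a * np.sin(2 * np.pi * xv / pitch + phi) + c

    p0 = [math.sqrt(2) * yc.std(), pitch0, 0.0, y.mean()]
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"sine fit did not converge: {exc}") from exc
    a, pitch, _, _ = popt
    resid = y - model(x, *popt)
    if resid.std() > 0.9 * y.std(ddof=0) and abs(a) < 0.1 * y.std():
        raise ValueError(
            f"sine fit rejected: residual SD {resid.std():.3g} "
            f"comparable to data SD {y.std():.3g}")
    return abs(float(pitch)), abs(float(a))
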