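"""Mobile/immobile segmentation of trajectories with a two-state HMM.

A motor-coated bead alternates between a *mobile* mode (fluctuating helical
drift over the lattice) and an *immobile* mode (transient entrapment at a
lattice site, where apparent motion is only localization noise and tether
fluctuation).  Each time point is classified by a two-state hidden Markov
model on the windowed, normalized displacement magnitude

    s_i = || (dX_i / sd(dX), dY_i / sd(dY)) ||,   dX_i = X[i+w] - X[i]

where the look-ahead window ``w`` frames is chosen per construct as the
expected time to travel ~0.1 µm along the axis.  Emissions are Gaussian per
state; the fit is maximum likelihood by expectation-maximization with
multiple seeded restarts (the state posterior used for decoding comes from
the forward-backward recursion).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .trajectory_io import CylTrajectory

__all__ = [
    "WindowedDisplacementSeries",
    "HmmFit",
    "MobileSegments",
    "windowed_displacements",
    "fit_two_state_hmm",
    "decode_modes",
    "extract_mobile_segments",
    "immobile_fraction",
]

IMMOBILE, MOBILE = 0, 1


@dataclass
class WindowedDisplacementSeries:
    """Dimensionless displacement magnitude per time point."""

    t: np.ndarray
    s: np.ndarray
    window: float  # seconds
    window_frames: int

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class HmmFit:
    """Two-state Gaussian HMM fit; state 0 = immobile, state 1 = mobile."""

    means: np.ndarray          # (2,) emission means, immobile first
    sds: np.ndarray            # (2,) emission SDs
    transition: np.ndarray     # (2, 2), rows sum to 1
    startprob: np.ndarray      # (2,)
    posterior_immobile: np.ndarray  # per time point
    log_likelihood: float
    converged: bool
    degenerate: bool = False


@dataclass
class MobileSegments:
    """Mobile index ranges and the reassembled virtual trajectory."""

    segments: list[tuple[int, int]]  # inclusive (start, end) point ranges
    virtual_dX: np.ndarray           # within-segment lag-1 displacements
    virtual_dY: np.ndarray
    dt: float
    empty: bool = False


def windowed_displacements(traj: CylTrajectory, window: float
                           ) -> WindowedDisplacementSeries:
    """Sliding normalized displacement magnitudes over a fixed window.

    The window must be an integer multiple of the sampling interval; the
    series is shorter than the trajectory by window/dt points.  The X and Y
    displacement components are normalized by their whole-trajectory
    standard deviations at this window before taking the Euclidean norm.
    """
    dt = traj.dt
    w = int(round(window / dt))
    if w < 1:
        raise ValueError(f"window {window} s shorter than sampling interval {dt} s")
    if abs(w * dt - window) > 0.05 * dt:
        raise ValueError(f"window {window} s is not a multiple of dt {dt} s")
    if w >= len(traj):
        raise ValueError("window longer than trajectory")
    dx = traj.X[w:] - traj.X[:-w]
    dy = traj.Y[w:] - traj.Y[:-w]
    sx, sy = dx.std(), dy.std()
    nx = dx / sx if sx > 0 else np.zeros_like(dx)
    ny = dy / sy if sy > 0 else np.zeros_like(dy)
    return WindowedDisplacementSeries(
        t=traj.t[:-w], s=np.hypot(nx, ny), window=window, window_frames=w)


def fit_two_state_hmm(series: WindowedDisplacementSeries, seed: int = 0,
                      n_restarts: int = 5, n_iter: int = 500,
                      tol: float = 1e-8) -> HmmFit:
    """Fit the two-state Gaussian HMM by EM with seeded random restarts.

    States are relabeled so state 1 (mobile) has the larger emission mean.
    Degenerate input (zero variance) yields a flagged single-mode result.
    """
    s = np.asarray(series.s, dtype=float)
    if len(s) < 30:
        raise ValueError("need at least 30 points to fit the HMM")
    if s.std() < 1e-12:
        # all mass in one mode; report everything mobile, flag degenerate
        return HmmFit(
            means=np.array([s.mean(), s.mean()]),
            sds=np.array([0.0, 0.0]),
            transition=np.eye(2),
            startprob=np.array([0.0, 1.0]),
            posterior_immobile=np.zeros_like(s),
            log_likelihood=np.nan, converged=False, degenerate=True)

    obs = s.reshape(-1, 1)
    best = None
    rng = np.random.default_rng(seed)
    var = s.var()
    for r in range(max(1, n_restarts)):
        sub = int(rng.integers(0, 2**31 - 1))
        model = GaussianHMM(n_components=2, covariance_type="diag",
                            n_iter=n_iter, tol=tol, random_state=sub,
                            min_covar=1e-10, init_params="",
                            # MAP-EM: anchor the immobile emission mean near
                            # zero (its apparent motion is noise only);
                            # without this the skewed mobile bulk is
                            # occasionally split into two states instead
                            means_prior=np.array([[0.0], [np.median(s)]]),
                            means_weight=np.array([[30.0], [1e-6]]))
        # seed EM with one state near the lower tail and jitter restarts
        q_lo = float(np.quantile(s, rng.uniform(0.01, 0.10)))
        q_hi = float(np.quantile(s, rng.uniform(0.45, 0.75)))
        model.startprob_ = np.array([0.1, 0.9])
        model.transmat_ = np.array([[0.9, 0.1], [0.05, 0.95]])
        model.means_ = np.array([[q_lo], [q_hi]])
        model.covars_ = np.array([[max(0.05 * var, 1e-6)], [var]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(obs)
                ll = model.score(obs)
            except Exception:
                continue
        if best is None or ll > best[0]:
            best = (ll, model)
    if best is None:
        raise RuntimeError("HMM fit failed in all restarts")
    ll, model = best

    means = model.means_.ravel().copy()
    sds = np.sqrt(model.covars_.ravel())
    trans = model.transmat_.copy()
    start = model.startprob_.copy()
    order = np.argsort(means)  # immobile (smaller mean) first
    means, sds, start = means[order], sds[order], start[order]
    trans = trans[np.ix_(order, order)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = model.predict_proba(obs)[:, order]
    return HmmFit(means=means, sds=sds, transition=trans, startprob=start,
                  posterior_immobile=post[:, IMMOBILE], log_likelihood=float(ll),
                  converged=bool(model.monitor_.converged))


def decode_modes(fit: HmmFit, series: WindowedDisplacementSeries | None = None
                 ) -> np.ndarray:
    """Per-timepoint labels: 0 = immobile, 1 = mobile.

    A point is immobile iff its forward-backward posterior probability of
    the immobile state exceeds 0.5.
    """
    return np.where(fit.posterior_immobile > 0.5, IMMOBILE, MOBILE)


def extract_mobile_segments(traj: CylTrajectory, labels: np.ndarray,
                            min_len: int = 5) -> MobileSegments:
    """Extract mobile runs and reassemble a virtual trajectory.

    ``labels`` (one per time point, typically shorter than the trajectory
    by the HMM window) select mobile points; maximal mobile runs shorter
    than ``min_len`` points are dropped.  The virtual trajectory is the
    concatenation of lag-1 displacements strictly inside each kept run —
    displacements spanning a removed gap are excluded.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n > len(traj):
        raise ValueError("labels longer than trajectory")
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if labels[i] == MOBILE:
            j = i
            while j + 1 < n and labels[j + 1] == MOBILE:
                j += 1
            if j - i + 1 >= min_len:
                segments.append((i, j))
            i = j + 1
        else:
            i += 1
    dxs, dys = [], []
    for a, b in segments:
        dxs.append(np.diff(traj.X[a:b + 1]))
        dys.append(np.diff(traj.Y[a:b + 1]))
    vdx = np.concatenate(dxs) if dxs else np.empty(0)
    vdy = np.concatenate(dys) if dys else np.empty(0)
    return MobileSegments(segments=segments, virtual_dX=vdx, virtual_dY=vdy,
                          dt=traj.dt, empty=not segments)


def immobile_fraction(labels: np.ndarray) -> float:
    """Fraction of time points labeled immobile."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label array")
    return float(np.mean(labels == IMMOBILE))
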