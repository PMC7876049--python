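"""Microscopic hopping rates from macroscopic trajectory moments.

A bead hops on the lattice to one of the 8 neighboring sites at rates
k_1…k_8 (direction indexing below).  For such a Markov jump process, the
increment over time t is compound-Poisson, so every joint cumulant of
(Δz, Δw) grows linearly in t with rate Σ_i k_i · dz_i^a · dw_i^b.  The 8
macroscopic parameters — velocities v_x, v_y, diffusion 2D_x, 2D_y and the
higher-order covariance coefficients A, B, C, E — are exactly these
cumulant rates for the moment orders (1,0), (0,1), (2,0), (0,2), (1,1),
(2,1), (1,2), (2,2), giving a linear, invertible 8×8 map between rates and
macroscopic parameters.

Direction indexing (dz: forward along the protofilament, dw: leftward):

    1 = (+1, +1) forward-left    2 = (+1, 0) forward   3 = (+1, −1) forward-right
    4 = ( 0, +1) left            5 = ( 0, −1) right
    6 = (−1, +1) backward-left   7 = (−1, 0) backward  8 = (−1, −1) backward-right

Directly solving the linear system can produce negative rates on noisy
data (higher-order covariances are sensitive to extremes), so inference is
Bayesian: each trajectory's observed macroscopic vector is modeled as
Gaussian around the theoretical one, with constraints k_i ≥ 0 built into
the parametrization.  Results are reported as the total rate k = Σ k_i and
the preference simplex p_i = k_i / k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DIRECTIONS",
    "HoppingModel",
    "HoppingPosterior",
    "forward_map",
    "invert_exact",
    "infer_hopping",
    "summarize_posterior",
    "mirror_macroscopic",
    "MIRROR_PERMUTATION",
]

#: (dz, dw) for hop directions 1..8 (row order of the moment matrix input).
DIRECTIONS = np.array([
    (+1, +1), (+1, 0), (+1, -1),
    (0, +1), (0, -1),
    (-1, +1), (-1, 0), (-1, -1),
])

#: moment orders (a, b) of the 8 macroscopic parameters, in output order
#: v_x, v_y, 2D_x, 2D_y, A, B, C, E
MOMENT_ORDERS = [(1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 1), (1, 2), (2, 2)]

MACRO_NAMES = ["v_x", "v_y", "2D_x", "2D_y", "A", "B", "C", "E"]

#: preference-index permutation under the lattice mirror w -> -w
#: (1<->3, 4<->5, 6<->8, 0-based)
MIRROR_PERMUTATION = np.array([2, 1, 0, 4, 3, 7, 6, 5])

#: sign of each macroscopic parameter under w -> -w (odd in dw flips)
MIRROR_SIGNS = np.array([(-1.0) ** b for _, b in MOMENT_ORDERS])


def _moment_matrix() -> np.ndarray:
    dz, dw = DIRECTIONS[:, 0].astype(float), DIRECTIONS[:, 1].astype(float)
    return np.array([dz ** a * dw ** b for a, b in MOMENT_ORDERS])


@dataclass(frozen=True)
class HoppingModel:
    """The 8-direction nearest-neighbor hopping model and its moment map."""

    directions: np.ndarray = field(default_factory=lambda: DIRECTIONS.copy())
    moment_matrix: np.ndarray = field(default_factory=_moment_matrix)


def forward_map(k: np.ndarray, model: HoppingModel | None = None) -> np.ndarray:
    """Map hopping rates k_1..k_8 (s⁻¹) to the 8 macroscopic parameters."""
    k = np.asarray(k, dtype=float)
    if k.shape[-1] != 8:
        raise ValueError("k must have 8 components")
    if np.any(k < 0):
        raise ValueError("hopping rates must be non-negative")
    M = (model or HoppingModel()).moment_matrix
    return k @ M.T


def invert_exact(macro: np.ndarray, model: HoppingModel | None = None):
    """Exact linear solve for rates; negative entries are flagged.

    Diagnostic use only — on noisy data the solution may leave the
    physical (non-negative) domain.  Returns (k, has_negative).
    """
    macro = np.asarray(macro, dtype=float)
    M = (model or HoppingModel()).moment_matrix
    k = np.linalg.solve(M, macro)
    return k, bool(np.any(k < -1e-12))


def mirror_macroscopic(macro: np.ndarray) -> np.ndarray:
    """Transform a macroscopic 8-vector under the lattice mirror w → −w."""
    return np.asarray(macro, float) * MIRROR_SIGNS


@dataclass
class HoppingPosterior:
    """Posterior draws for the total rate and preference simplex.

    ``k`` has shape (chains, draws); ``p`` (chains, draws, 8); ``sigma``
    (chains, draws, 8) holds the per-macroscopic-parameter noise scales.
    """

    k: np.ndarray
    p: np.ndarray
    sigma: np.ndarray
    rhat: dict
    converged: bool
    warning: str | None = None

    @property
    def k_mean(self) -> float:
        return float(self.k.mean())

    @property
    def k_sd(self) -> float:
        return float(self.k.std(ddof=1))

    @property
    def p_mean(self) -> np.ndarray:
        return self.p.reshape(-1, 8).mean(axis=0)

    @property
    def p_sd(self) -> np.ndarray:
        return self.p.reshape(-1, 8).std(axis=0, ddof=1)

    def p_interval(self, prob: float = 0.95) -> np.ndarray:
        """Central credible interval per preference, shape (8, 2)."""
        lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
        flat = self.p.reshape(-1, 8)
        return np.quantile(flat, [lo, hi], axis=0).T


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ of Gelman et al. for an array shaped (chains, draws)."""
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return math.nan
    sub = chains[:, : 2 * half].reshape(c * 2, half)
    means = sub.mean(axis=1)
    W = sub.var(axis=1, ddof=1).mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(math.sqrt(var_hat / W))


def infer_hopping(macro_table: np.ndarray, model: HoppingModel | None = None,
                  seed: int = 0, n_chains: int = 4, n_steps: int = 2000,
                  n_walkers: int = 48, k_max: float = 200.0,
                  sigma_scale_factor: float = 2.0) -> HoppingPosterior:
    """Bayesian inference of hopping rates from per-trajectory moments.

    Parameters
    ----------
    macro_table
        (n_trajectories, 8) observed macroscopic parameters in lattice
        units (sites/s … sites⁴/s), one row per trajectory, column order
        v_x, v_y, 2D_x, 2D_y, A, B, C, E.
    seed
        Seeds everything (chain initializations and proposals).
    n_chains, n_steps
        Independent ensembles and steps each (first half discarded as
        warmup).  Split-R̂ across chains is reported for k and p_1..p_8;
        the posterior carries a warning when any R̂ ≥ 1.01.
    k_max
        Upper limit of the flat prior support per rate, s⁻¹ (roughly an
        order of magnitude above motor ATPase turnover; a prior support
        statement, not a physical claim).

    Model: observed_jm ~ Normal(theoretical_m(k), σ_m) independently per
    trajectory j and macroscopic parameter m; flat priors on each rate
    over [0, k_max]; half-normal priors on the σ_m scaled to the empirical
    cross-trajectory spread (per-parameter sampling noise differs by
    orders of magnitude across moment orders).
    """
    import emcee

    macro_table = np.atleast_2d(np.asarray(macro_table, dtype=float))
    n_traj = macro_table.shape[0]
    if n_traj < 5:
        raise ValueError("need at least 5 trajectories for inference")
    if macro_table.shape[1] != 8:
        raise ValueError("macro_table must have 8 columns")
    model = model or HoppingModel()
    M = model.moment_matrix

    obs_mean = macro_table.mean(axis=0)
    obs_sd = macro_table.std(axis=0, ddof=1)
    # half-normal scale per macroscopic parameter, floored to avoid
    # degenerate likelihoods when a column happens to have zero spread
    sigma_scale = sigma_scale_factor * np.maximum(obs_sd,
                                                  1e-3 * np.abs(obs_mean) + 1e-9)

    ndim = 16  # 8 rates + 8 noise scales

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        k = theta[:, :8]
        sig = theta[:, 8:]
        bad = (np.any(k < 0, axis=1) | np.any(k > k_max, axis=1)
               | np.any(sig <= 0, axis=1))
        theo = k @ M.T  # (nw, 8)
        resid = macro_table[None, :, :] - theo[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = -0.5 * np.sum(resid ** 2 / sig[:, None, :] ** 2, axis=(1, 2)) \
                - n_traj * np.sum(np.log(sig), axis=1)
            lp = -0.5 * np.sum((sig / sigma_scale) ** 2, axis=1)
        out = ll + lp
        out[bad] = -np.inf
        return out

    # initialization near the exact linear solution, clipped to the domain
    k0, _ = invert_exact(obs_mean, model)
    k0 = np.clip(k0, 0.05, k_max * 0.5)

    k_list, sig_list = [], []
    master = np.random.SeedSequence(seed)
    for c, ss in enumerate(master.spawn(n_chains)):
        rng = np.random.default_rng(ss)
        p0 = np.empty((n_walkers, ndim))
        p0[:, :8] = np.abs(k0[None, :] * (1 + 0.3 * rng.standard_normal((n_walkers, 8)))
                           + 0.05 * rng.random((n_walkers, 8)))
        p0[:, :8] = np.clip(p0[:, :8], 1e-3, k_max - 1e-3)
        p0[:, 8:] = sigma_scale[None, :] * (0.5 + rng.random((n_walkers, 8)))
        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(
            int(ss.generate_state(1)[0] % (2 ** 31))).get_state()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler.run_mcmc(p0, n_steps, progress=False)
        # (kept_steps, walkers, ndim) -> time-ordered flat draws, thinned
        arr = sampler.get_chain(discard=n_steps // 2, thin=5)
        flat = arr.reshape(-1, ndim)
        k_list.append(flat[:, :8])
        sig_list.append(flat[:, 8:])

    chains_k = np.stack(k_list)       # (chains, draws, 8)
    chains_sig = np.stack(sig_list)

    k_total = chains_k.sum(axis=2)
    with np.errstate(invalid="ignore"):
        p = chains_k / k_total[:, :, None]

    rhat = {"k": _split_rhat(k_total)}
    for i in range(8):
        rhat[f"p{i + 1}"] = _split_rhat(p[:, :, i])
    worst = max(v for v in rhat.values() if np.isfinite(v))
    converged = worst < 1.01
    warning = None if converged else (
        f"max split-R-hat {worst:.3f} >= 1.01; increase n_steps")
    if warning:
        warnings.warn(warning)
    return HoppingPosterior(k=k_total, p=p, sigma=chains_sig, rhat=rhat,
                            converged=converged, warning=warning)


#: 3x3 compass grid (row, col) for preference index 1..8; center empty.
_GRID_POSITIONS = {1: (0, 0), 2: (0, 1), 3: (0, 2),
                   4: (1, 0), 5: (1, 2),
                   6: (2, 0), 7: (2, 1), 8: (2, 2)}


def summarize_posterior(post: HoppingPosterior):
    """Posterior mean ± SD table and the 3×3 preference grid.

    The grid places forward on the top row and leftward in the left
    column (direction 1 = forward-left at top-left); the center cell is
    NaN.  Returns a dict with ``table`` (pandas DataFrame) and grids
    ``grid_mean``, ``grid_sd``.
    """
    import pandas as pd

    rows = [{"parameter": "k", "mean": post.k_mean, "sd": post.k_sd,
             "rhat": post.rhat.get("k", math.nan)}]
    for i in range(8):
        rows.append({"parameter": f"p{i + 1}", "mean": post.p_mean[i],
                     "sd": post.p_sd[i], "rhat": post.rhat.get(f"p{i + 1}",
                                                               math.nan)})
    grid_mean = np.full((3, 3), np.nan)
    grid_sd = np.full((3, 3), np.nan)
    for i in range(8):
        r, c = _GRID_POSITIONS[i + 1]
        grid_mean[r, c] = post.p_mean[i]
        grid_sd[r, c] = post.p_sd[i]
    return {"table": pd.DataFrame(rows), "grid_mean": grid_mean,
            "grid_sd": grid_sd}
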