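"""Synthetic trajectories with the statistical structure the analysis assumes.

A bead is simulated as a continuous-time Markov jump process on the
microtubule surface lattice: exponential waiting times at total rate
Σ k_i, hop direction drawn proportional to k_i, with an independent
two-state mobile/trapped switching process that suppresses hopping while
trapped.  The lattice path is sampled on the observation grid (0.10028 s
cycle), mapped to measured coordinates (X µm, Y revolutions) through the
lattice geometry, and corrupted with independent Gaussian localization
noise (3 nm longitudinal, ~6° rotational by default, within the measured
5–7.5° precision).  Ground truth (jump times and directions, trapped
intervals, true macroscopic parameters) is retained for every track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .hopping_inference import forward_map
from .lattice_geometry import LatticeGeometry, lattice_to_measured
from .trajectory_io import BeadTrack3D, CylTrajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_lattice_walk",
    "render_observation",
    "make_cohort",
    "load_preset",
    "solve_preset_rates",
    "PRESETS",
]

PRESETS = ("M2", "M2C2", "M1")

#: rotation radius for the optional 3D embedding: microtubule + bead radii, µm
EMBED_RADIUS_UM = 0.1225


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one cohort."""

    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)
    rates: tuple = (0.0,) * 8          # k_1..k_8, s^-1
    trap_on_rate: float = 0.0          # mobile -> trapped, s^-1
    trap_off_rate: float = 1.0         # trapped -> mobile, s^-1
    noise_long_nm: float = 3.0
    noise_rot_deg: float = 6.0
    dt: float = 0.10028
    duration: float = 30.0
    n_tracks: int = 1
    seed: int = 0
    construct: str = "custom"
    window_s: float | None = None      # suggested HMM window for this cohort

    def __post_init__(self) -> None:
        if len(self.rates) != 8 or any(r < 0 for r in self.rates):
            raise ValueError("rates must be 8 non-negative values")
        if self.trap_on_rate < 0 or self.trap_off_rate < 0:
            raise ValueError("trap rates must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must be at least 10 sampling intervals")

    @property
    def k_total(self) -> float:
        return float(sum(self.rates))

    @property
    def trap_occupancy(self) -> float:
        denom = self.trap_on_rate + self.trap_off_rate
        return self.trap_on_rate / denom if denom > 0 else 0.0


@dataclass
class GroundTruth:
    """Everything the generator knew: the noise-free path and its labels."""

    t: np.ndarray                  # frame times, s
    z: np.ndarray                  # lattice path at frame times, sites
    w: np.ndarray
    trapped: np.ndarray            # bool per frame
    jump_times: np.ndarray
    jump_dirs: np.ndarray          # 0-based direction indices
    trapped_intervals: list[tuple[float, float]]
    true_macro: np.ndarray         # forward_map(rates), lattice units


def _trap_intervals(cfg: SimConfig, rng) -> list[tuple[float, float]]:
    """Alternating-renewal trapped intervals over [0, duration]."""
    if cfg.trap_on_rate <= 0:
        return []
    occ = cfg.trap_occupancy
    trapped = bool(rng.random() < occ)
    t, out = 0.0, []
    while t < cfg.duration:
        rate = cfg.trap_off_rate if trapped else cfg.trap_on_rate
        dwell = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if trapped:
            out.append((t, min(t + dwell, cfg.duration)))
        t += dwell
        trapped = not trapped
    return out


def simulate_lattice_walk(cfg: SimConfig, rng=None) -> GroundTruth:
    """Gillespie simulation of the biased 8-neighbor walk with trapping.

    Deterministic given the generator state; the path is reported at the
    frame times n·dt together with the full jump record.
    """
    from .hopping_inference import DIRECTIONS

    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    k = np.asarray(cfg.rates, dtype=float)
    k_tot = k.sum()
    intervals = _trap_intervals(cfg, rng)

    # mobile windows = complement of trapped intervals in [0, duration]
    mobile: list[tuple[float, float]] = []
    cursor = 0.0
    for a, b in intervals:
        if a > cursor:
            mobile.append((cursor, a))
        cursor = b
    if cursor < cfg.duration:
        mobile.append((cursor, cfg.duration))

    jump_times: list[np.ndarray] = []
    if k_tot > 0:
        for a, b in mobile:
            t = a
            chunk = max(16, int(1.5 * k_tot * (b - a)) + 1)
            times = []
            while t < b:
                waits = rng.exponential(1.0 / k_tot, size=chunk)
                cand = t + np.cumsum(waits)
                inside = cand[cand < b]
                times.append(inside)
                t = cand[-1]
            if times:
                jump_times.append(np.concatenate(times))
    jt = np.concatenate(jump_times) if jump_times else np.empty(0)
    jd = rng.choice(8, size=len(jt), p=k / k_tot) if (k_tot > 0 and len(jt)) \
        else np.empty(0, dtype=int)

    n_frames = int(math.floor(cfg.duration / cfg.dt)) + 1
    t_frames = np.arange(n_frames) * cfg.dt
    dz = np.concatenate([[0], np.cumsum(DIRECTIONS[jd, 0])]) if len(jd) \
        else np.zeros(1)
    dw = np.concatenate([[0], np.cumsum(DIRECTIONS[jd, 1])]) if len(jd) \
        else np.zeros(1)
    idx = np.searchsorted(jt, t_frames, side="right")
    z = dz[idx].astype(float)
    w = dw[idx].astype(float)
    trapped = np.zeros(n_frames, dtype=bool)
    for a, b in intervals:
        trapped |= (t_frames >= a) & (t_frames < b)
    return GroundTruth(t=t_frames, z=z, w=w, trapped=trapped,
                       jump_times=jt, jump_dirs=jd,
                       trapped_intervals=intervals,
                       true_macro=forward_map(k))


def render_observation(truth: GroundTruth, cfg: SimConfig, rng=None,
                       as_3d: bool = False):
    """Emit the observed trajectory: geometry transform + localization noise.

    Returns a :class:`CylTrajectory`; with ``as_3d=True`` additionally a
    :class:`BeadTrack3D` embedding on a cylinder of radius 0.1225 µm
    (microtubule + bead radii) for exercising the unwrapping step.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    X, Y = lattice_to_measured(cfg.geometry, truth.z, truth.w)
    X = X + rng.normal(0.0, cfg.noise_long_nm / 1000.0, size=len(X))
    Y = Y + rng.normal(0.0, cfg.noise_rot_deg / 360.0, size=len(Y))
    meta = {"construct": cfg.construct, "dt": cfg.dt}
    traj = CylTrajectory(truth.t, X, Y, meta=meta)
    if not as_3d:
        return traj
    phi = 2 * np.pi * Y
    track = BeadTrack3D(truth.t, X,
                        EMBED_RADIUS_UM * np.cos(phi),
                        EMBED_RADIUS_UM * np.sin(phi),
                        meta=dict(meta))
    return traj, track


def solve_preset_rates(k_total: float, v_long_um_s: float, v_rot_rev_s: float,
                       geom: LatticeGeometry, corner_preference: float,
                       lateral_preference_total: float) -> np.ndarray:
    """Solve a preference vector reproducing target cohort-mean velocities.

    Under the symmetric background (p1=p3=p6=p8 fixed, p4+p5 fixed), the
    noise-free expectations reduce to p2−p7 = v_z/k and p4−p5 = v_w/k with
    v_z = v_long/d sites/s and v_w = v_rot·n sites/s, which pin down the
    remaining entries in closed form.
    """
    c = corner_preference
    s = lateral_preference_total
    v_z = v_long_um_s * 1000.0 / geom.dimer_spacing_d
    v_w = v_rot_rev_s * geom.n_protofilaments
    a = v_z / k_total
    b = v_w / k_total
    q = 1.0 - 4.0 * c - s
    p = np.array([c, (q + a) / 2, c, (s + b) / 2, (s - b) / 2,
                  c, (q - a) / 2, c])
    if np.any(p < 0) or q < a or s < b:
        raise ValueError("preset targets infeasible with the given background "
                         f"allocations (p={p})")
    return k_total * p


def load_preset(name: str, seed: int = 0, geometry: LatticeGeometry | None = None,
                **overrides) -> SimConfig:
    """Load a construct preset (M2, M2C2, or M1) as a :class:`SimConfig`."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    with resources.files("helixhop.presets").joinpath(f"{name}.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    geom = geometry or LatticeGeometry.for_protofilaments(13)
    rates = solve_preset_rates(cfg["k_total"], cfg["v_long_um_s"],
                               cfg["v_rot_rev_s"], geom,
                               cfg["corner_preference"],
                               cfg["lateral_preference_total"])
    base = dict(
        geometry=geom,
        rates=tuple(rates),
        trap_on_rate=cfg["trap_on_rate"],
        trap_off_rate=cfg["trap_off_rate"],
        duration=cfg["duration_s"],
        n_tracks=cfg["n_tracks"],
        construct=cfg["construct"],
        window_s=cfg["window_s"],
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def make_cohort(preset: str | SimConfig, seed: int | None = None,
                as_3d: bool = False, **overrides):
    """Generate a cohort of trajectories with ground truth.

    ``preset`` is "M2", "M2C2", "M1", or a custom :class:`SimConfig`
    (passed through unchanged apart from ``seed``/overrides).  Returns
    (trajectories, truths); fully deterministic for a given seed+config.
    """
    if isinstance(preset, str):
        cfg = load_preset(preset, seed=0 if seed is None else seed, **overrides)
    else:
        cfg = preset
        if seed is not None or overrides:
            cfg = replace(cfg, **({"seed": seed} if seed is not None else {}),
                          **overrides)
    master = np.random.SeedSequence(cfg.seed)
    trajs, truths = [], []
    for i, ss in enumerate(master.spawn(cfg.n_tracks)):
        rng = np.random.default_rng(ss)
        truth = simulate_lattice_walk(cfg, rng)
        out = render_observation(truth, cfg, rng, as_3d=as_3d)
        traj = out[0] if as_3d else out
        traj.meta["track_id"] = i
        trajs.append(out if as_3d else traj)
        truths.append(truth)
    return trajs, truths
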