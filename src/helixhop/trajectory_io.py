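"""Trajectory tables, cylindrical unwrapping, and quality-control filters.

Raw input is a time-stamped 3D bead track (t, x, y, z) sampled at ~0.1 s,
with x along the microtubule axis.  The track is unwrapped into cylindrical
coordinates: longitudinal position X (µm) and cumulative revolutions Y
around the axis, left-handed rotation positive (counterclockwise when
viewed toward the microtubule plus end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeadTrack3D",
    "CylTrajectory",
    "read_tracks",
    "read_trajectory",
    "write_trajectory",
    "cylindrical_unwrap",
    "qc_filter",
    "yz_histogram",
    "fit_linear_velocity",
]


@dataclass
class BeadTrack3D:
    """3D bead positions in the microscope frame (µm), t in seconds."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t, self.x, self.y, self.z = (
            np.asarray(a, dtype=float) for a in (self.t, self.x, self.y, self.z)
        )
        n = len(self.t)
        if not all(len(a) == n for a in (self.x, self.y, self.z)):
            raise ValueError("t, x, y, z must have equal length")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise ValueError(f"time not strictly increasing at row {bad[0] + 1}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CylTrajectory:
    """Cylindrical trajectory: X longitudinal (µm), Y cumulative revolutions."""

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    radius: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)
        if not (len(self.t) == len(self.X) == len(self.Y)):
            raise ValueError("t, X, Y must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time not strictly increasing")
            self.meta.setdefault("dt", float(np.median(dt)))

    @property
    def dt(self) -> float:
        return float(self.meta["dt"])

    def __len__(self) -> int:
        return len(self.t)

    def net_run(self) -> float:
        """Net longitudinal displacement, µm."""
        return float(abs(self.X[-1] - self.X[0]))


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # malformed rows
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    df.columns = [c.strip() for c in df.columns]
    return df


def read_tracks(path: str | Path) -> list[BeadTrack3D]:
    """Read one or more 3D bead tracks.

    ``path`` may be a single CSV/TSV file with header ``t,x,y,z`` (one
    track) or a directory of such files (one file per tracked bead).
    Units: t in s, positions in µm.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".csv", ".tsv", ".tab"))
        return [t for f in files for t in read_tracks(f)]
    df = _read_table(path)
    required = ["t", "x", "y", "z"]
    if not all(c in df.columns for c in required):
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    bad = np.flatnonzero(np.diff(df["t"].to_numpy(dtype=float)) <= 0)
    if bad.size:
        # diff index i -> data row i+1 violates; +1 header, +1 one-based
        raise ValueError(f"{path}: time not strictly increasing at line {bad[0] + 3}")
    return [BeadTrack3D(df["t"], df["x"], df["y"], df["z"],
                        meta={"source": str(path)})]


def read_trajectory(path: str | Path) -> CylTrajectory:
    """Read a cylindrical trajectory file with header ``t,X,Y_rev``."""
    path = Path(path)
    df = _read_table(path)
    if not all(c in df.columns for c in ("t", "X", "Y_rev")):
        raise ValueError(f"{path}: expected columns t, X, Y_rev")
    radius = df["radius"].to_numpy(float) if "radius" in df.columns else None
    return CylTrajectory(df["t"], df["X"], df["Y_rev"], radius=radius,
                         meta={"source": str(path)})


def write_trajectory(traj: CylTrajectory, path: str | Path) -> None:
    """Write a cylindrical trajectory as CSV with unit-annotated header."""
    path = Path(path)
    cols = {"t": traj.t, "X": traj.X, "Y_rev": traj.Y}
    if traj.radius is not None:
        cols["radius"] = traj.radius
    with open(path, "w") as fh:
        fh.write("# units: t [s], X [um, longitudinal], "
                 "Y_rev [revolutions, left-handed positive], radius [um]\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.9g")


def _circle_center(y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Least-squares (Kåsa) circle center of the (y, z) cloud.

    Exact for noise-free arcs of any angular extent (the plain centroid is
    badly biased on partial arcs); falls back to the centroid when the
    points do not constrain a circle.
    """
    A = np.column_stack([y, z, np.ones_like(y)])
    b = y * y + z * z
    try:
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        rank = 0
    if rank < 3:
        return float(y.mean()), float(z.mean())
    return float(sol[0] / 2), float(sol[1] / 2)


def cylindrical_unwrap(track: BeadTrack3D, axis: str | np.ndarray = "fit"
                       ) -> CylTrajectory:
    """Unwrap a 3D track into (X, Y revolutions) around the microtubule axis.

    The per-frame angle is the atan2 of the centered (y, z) position and the
    cumulative revolution count Y is built with smallest-angle increments
    (valid: the fastest observed rotation moves well under half a turn per
    frame).  When ``axis="fit"`` the axis direction is the principal
    direction of the point cloud and the (y, z) circle center is the mean;
    a straight suspended microtubule is assumed.
    """
    if len(track) < 10:
        raise ValueError("need at least 10 frames to unwrap")
    pts = np.column_stack([track.x, track.y, track.z])
    if isinstance(axis, str):
        if axis != "fit":
            raise ValueError(f"unknown axis mode {axis!r}")
        centered = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        # orient along +x so longitudinal sign follows the microscope frame
        if direction[0] < 0:
            direction = -direction
    else:
        direction = np.asarray(axis, dtype=float)
        direction = direction / np.linalg.norm(direction)

    X = pts @ direction
    X = X - X[0]
    yc, zc = _circle_center(track.y, track.z)
    ry, rz = track.y - yc, track.z - zc
    radius = np.hypot(ry, rz)
    if np.all(radius < 1e-12):
        raise ValueError("degenerate track: all points on the axis")
    theta = np.arctan2(rz, ry)
    # smallest-angle increments -> cumulative revolutions
    y_rev = np.concatenate([[0.0], np.cumsum(
        (np.diff(theta) + np.pi) % (2 * np.pi) - np.pi)]) / (2 * np.pi)
    meta = dict(track.meta)
    return CylTrajectory(track.t, X, y_rev, radius=radius, meta=meta)


# reason codes for qc_filter rejections
REASON_SHORT_RUN = "run<min_run"
REASON_LARGE_RADIUS = "radius>max_radius"


def qc_filter(trajs: Sequence[CylTrajectory], min_run: float = 1.0,
              max_radius: float = 0.25
              ) -> tuple[list[CylTrajectory], list[tuple[CylTrajectory, str]]]:
    """Keep trajectories with a stable run and a plausible helix radius.

    Keeps trajectories whose net longitudinal displacement exceeds
    ``min_run`` (µm) and whose median per-frame radius is at most
    ``max_radius`` (µm; 250 nm is roughly twice the microtubule + bead
    radius).  Returns (kept, rejected) where each rejection carries a
    machine-readable reason code.
    """
    kept: list[CylTrajectory] = []
    rejected: list[tuple[CylTrajectory, str]] = []
    for traj in trajs:
        if traj.net_run() <= min_run:
            rejected.append((traj, REASON_SHORT_RUN))
        elif traj.radius is not None and float(np.median(traj.radius)) > max_radius:
            rejected.append((traj, REASON_LARGE_RADIUS))
        else:
            kept.append(traj)
    return kept, rejected


def yz_histogram(track: BeadTrack3D, bin_nm: float = 25.0):
    """Normalized 2D occupancy histogram of the (y, z) bead position.

    Bin edges are aligned to multiples of the bin size (nm); the matrix
    sums to 1.  Returns (H, y_edges_um, z_edges_um).
    """
    if bin_nm <= 0:
        raise ValueError("bin size must be > 0")
    if len(track) < 1:
        raise ValueError("empty track")
    b = bin_nm / 1000.0  # µm
    def edges(v):
        lo = math.floor(v.min() / b) * b
        hi = math.ceil(v.max() / b) * b
        if hi <= lo + b / 2:
            hi = lo + b
        return np.arange(lo, hi + b / 2, b)
    ye, ze = edges(track.y), edges(track.z)
    H, _, _ = np.histogram2d(track.y, track.z, bins=(ye, ze))
    return H / H.sum(), ye, ze


def fit_linear_velocity(traj: CylTrajectory):
    """Least-squares longitudinal and rotational velocities and inverse pitch.

    Fits t-X and t-Y with straight lines for the velocities (µm/s, rev/s)
    and X-Y for the inverse pitch (rev/µm).  ``pitch`` is 1/inverse_pitch,
    or NaN (flagged) for a non-rotating trajectory.
    Returns a dict with keys v_long, v_rot, inverse_pitch, pitch, flagged.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames for a linear fit")
    v_long = np.polyfit(traj.t, traj.X, 1)[0]
    v_rot = np.polyfit(traj.t, traj.Y, 1)[0]
    x_span = np.ptp(traj.X)
    if x_span < 1e-12:
        inverse_pitch = math.nan
    else:
        inverse_pitch = np.polyfit(traj.X, traj.Y, 1)[0]
    flagged = not np.isfinite(inverse_pitch) or abs(inverse_pitch) < 1e-12
    pitch = math.nan if flagged else 1.0 / inverse_pitch
    return {
        "v_long": float(v_long),
        "v_rot": float(v_rot),
        "inverse_pitch": float(inverse_pitch),
        "pitch": float(pitch),
        "flagged": bool(flagged),
    }
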