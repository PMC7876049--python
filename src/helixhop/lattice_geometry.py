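"""Microtubule surface-lattice geometry and coordinate conversions.

The microtubule wall is a skewed 2D lattice of tubulin dimers: ``n``
protofilaments (13 or 14) run along the axis with an 8 nm dimer spacing
``d`` and a small axial offset ("rise", ``r`` ~0.82 nm) between laterally
adjacent dimers.  For 14 protofilaments the lattice closure forces a slow
left-handed supertwist of the protofilaments around the axis (pitch
``P_MT`` ~8 µm); for 13 the protofilaments are parallel to the axis.

A bead position measured as (X: longitudinal distance, Y: cumulative
revolutions, left-handed positive) maps linearly to a lattice position
(z: dimer sites along a protofilament, w: protofilament sites sideways)::

    X_nm  = z*d + w*r
    Y_rev = w/n + X_nm/P_MT      (second term absent for 13 protofilaments)

The seam (the one lateral contact with mismatched alpha/beta registry) is
ignored; lattice coordinates are real-valued (no snapping to sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LatticeGeometry",
    "lattice_to_measured",
    "measured_to_lattice",
    "correct_pitch_for_supertwist",
    "steps_per_switch",
]

#: Axial length in nm closing the 13-protofilament lattice seam
#: (1.5 x 8 nm = 12 nm).  Informational: the per-contact rise used in the
#: coordinate transform is ``rise_r`` = 0.82 nm, and 13 x 0.82 != 12; the
#: two printed constants are not mutually consistent and both are kept.
SEAM_CLOSURE_NM = 12.0


@dataclass(frozen=True)
class LatticeGeometry:
    """Geometry of a 13- or 14-protofilament microtubule surface lattice.

    Parameters
    ----------
    n_protofilaments
        13 (no supertwist) or 14 (left-handed supertwist).
    dimer_spacing_d
        Tubulin dimer spacing along a protofilament, nm.
    rise_r
        Axial offset between laterally adjacent dimers, nm.
    supertwist_pitch_P_MT
        Supertwist pitch in nm, signed (+ = left-handed); ``inf`` means no
        supertwist (the 13-protofilament default).
    supertwist_angle_theta
        Protofilament tilt against the axis, degrees.  Stored constant
        only; the transform is parametrized by pitch.
    mixture_fraction_alpha
        Proportion of 13-protofilament microtubules in the preparation.
    """

    n_protofilaments: int = 13
    dimer_spacing_d: float = 8.0
    rise_r: float = 0.82
    supertwist_pitch_P_MT: float = math.inf
    supertwist_angle_theta: float = 0.0
    mixture_fraction_alpha: float = 5.0 / 8.0

    def __post_init__(self) -> None:
        if self.n_protofilaments not in (13, 14):
            raise ValueError(
                f"n_protofilaments must be 13 or 14, got {self.n_protofilaments}"
            )
        if not self.dimer_spacing_d > 0:
            raise ValueError("dimer_spacing_d must be > 0")
        if self.rise_r < 0:
            raise ValueError("rise_r must be >= 0")
        if not 0.0 <= self.mixture_fraction_alpha <= 1.0:
            raise ValueError("mixture_fraction_alpha must be in [0, 1]")

    @classmethod
    def for_protofilaments(cls, n: int) -> "LatticeGeometry":
        """Default geometry for a given protofilament count."""
        if n == 13:
            return cls(n_protofilaments=13, supertwist_pitch_P_MT=math.inf,
                       supertwist_angle_theta=0.0)
        if n == 14:
            return cls(n_protofilaments=14, supertwist_pitch_P_MT=8000.0,
                       supertwist_angle_theta=0.73)
        raise ValueError(f"unsupported protofilament count {n}")

    @classmethod
    def from_config(cls, path: str | Path) -> "LatticeGeometry":
        """Load geometry from a plain key-value (YAML) config file.

        Recognized keys: ``n_protofilaments``, ``dimer_spacing_nm``,
        ``rise_nm``, ``supertwist_pitch_nm`` (absent/null/"inf" = none),
        ``alpha``.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        n = int(cfg.get("n_protofilaments", 13))
        base = cls.for_protofilaments(n)
        pitch = cfg.get("supertwist_pitch_nm", base.supertwist_pitch_P_MT)
        if pitch is None or (isinstance(pitch, str) and pitch.lower() == "inf"):
            pitch = math.inf
        return cls(
            n_protofilaments=n,
            dimer_spacing_d=float(cfg.get("dimer_spacing_nm", base.dimer_spacing_d)),
            rise_r=float(cfg.get("rise_nm", base.rise_r)),
            supertwist_pitch_P_MT=float(pitch),
            supertwist_angle_theta=base.supertwist_angle_theta,
            mixture_fraction_alpha=float(cfg.get("alpha", base.mixture_fraction_alpha)),
        )


def _as_2d(z, w):
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if z.shape != w.shape:
        raise ValueError("z and w must have the same shape")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite lattice coordinates")
    return z, w


def lattice_to_measured(geom: LatticeGeometry, z, w):
    """Map lattice positions (z, w) to measured (X in µm, Y in revolutions).

    ``z``: dimer sites along the protofilament; ``w``: protofilament sites
    sideways (cumulative, not wrapped).  Left-handed rotation is positive Y.
    """
    z, w = _as_2d(z, w)
    x_nm = z * geom.dimer_spacing_d + w * geom.rise_r
    y_rev = w / geom.n_protofilaments
    if math.isfinite(geom.supertwist_pitch_P_MT):
        y_rev = y_rev + x_nm / geom.supertwist_pitch_P_MT
    return x_nm / 1000.0, y_rev


def measured_to_lattice(geom: LatticeGeometry, x_um, y_rev):
    """Exact inverse of :func:`lattice_to_measured`."""
    x_um = np.asarray(x_um, dtype=float)
    y_rev = np.asarray(y_rev, dtype=float)
    if not (np.all(np.isfinite(x_um)) and np.all(np.isfinite(y_rev))):
        raise ValueError("non-finite measured coordinates")
    if geom.dimer_spacing_d == 0:
        raise ValueError("singular geometry: dimer_spacing_d = 0")
    x_nm = x_um * 1000.0
    if math.isfinite(geom.supertwist_pitch_P_MT):
        w = geom.n_protofilaments * (y_rev - x_nm / geom.supertwist_pitch_P_MT)
    else:
        w = geom.n_protofilaments * y_rev
    z = (x_nm - w * geom.rise_r) / geom.dimer_spacing_d
    return z, w


def correct_pitch_for_supertwist(p_obs: float, alpha: float, p_mt: float) -> float:
    """Correct an observed helical pitch for the supertwist contribution.

    The observed pitch on a 14-protofilament microtubule combines the motor's
    own helical pitch ``P_motor`` with the supertwist pitch ``P_MT`` as
    1/P_obs = 1/P_motor + 1/P_MT; a fraction ``alpha`` of the microtubules
    (13-protofilament) have no supertwist.  The mixture-averaged observed
    pitch then satisfies

        alpha*P_motor + (1-alpha)*P_motor*P_MT/(P_motor+P_MT) = P_obs

    whose positive root is returned (all pitches in the same unit, µm here).
    """
    if not p_obs > 0:
        raise ValueError("p_obs must be > 0")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if not p_mt > 0:
        raise ValueError("p_mt must be > 0")
    diff = p_obs - p_mt
    return (diff + math.sqrt(diff * diff + 4.0 * alpha * p_obs * p_mt)) / (2.0 * alpha)


def steps_per_switch(pitch: float, geom: LatticeGeometry) -> float:
    """Mean number of forward dimer steps per single protofilament switch
    implied by a helical pitch: (pitch / d) / n."""
    if not pitch > 0:
        raise ValueError("pitch must be > 0")
    pitch_nm = pitch * 1000.0
    return (pitch_nm / geom.dimer_spacing_d) / geom.n_protofilaments
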