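"""Helical filament reconstruction and screw-parameter analysis.

A head-to-tail enzyme polymer is generated by one rigid transform T that
maps each repeating unit onto the next.  Iterating T replicates the
cryo-EM asymmetric unit into a filament; decomposing T as a screw motion
(rotation by a twist angle about an axis, plus a rise along it) yields the
helical parameters, e.g. a 40° twist means the filament closes a full turn
every nine units.  The kink angle between the principal axes of adjacent
units measures how strongly the cross-linker bends the polymer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import (
    DegenerateGeometryError,
    RigidTransform,
    Structure,
    StructIOError,
    ca_array,
    extract_ca,
    superpose,
)

__all__ = [
    "ScrewParameters",
    "FilamentModel",
    "unit_transform",
    "screw_decompose",
    "replicate_filament",
    "kink_angle",
]

MIN_TWIST_DEG = 0.1  # below this the screw axis is numerically ill-defined


@dataclass
class ScrewParameters:
    """Screw decomposition of a rigid motion.

    ``twist_deg`` is the rotation magnitude in (0, 180]; ``axis`` is the unit
    rotation axis oriented so the rise is non-negative; ``handedness`` is +1
    for a right-handed screw (rotation right-handed about the direction of
    advance) and −1 for left-handed.
    """

    twist_deg: float
    axis: np.ndarray          # unit 3-vector
    axis_point: np.ndarray    # a point on the screw axis
    rise: float               # Å per repeat along the axis
    handedness: int

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        self.axis_point = np.asarray(self.axis_point, dtype=float).reshape(3)

    @property
    def repeats_per_turn(self) -> float:
        return 360.0 / self.twist_deg

    def to_transform(self) -> RigidTransform:
        """Recompose the rigid motion from the screw parameters."""
        signed = math.radians(self.twist_deg) * self.handedness
        rot = Rotation.from_rotvec(signed * self.axis).as_matrix()
        # x ↦ R (x − p) + p + rise·axis
        trans = self.axis_point - rot @ self.axis_point + self.rise * self.axis
        return RigidTransform(rot, trans)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "twist_deg": self.twist_deg,
            "rise_A": self.rise,
            "repeats_per_turn": self.repeats_per_turn,
            "axis": self.axis.tolist(),
            "axis_point": self.axis_point.tolist(),
            "handedness": "right" if self.handedness > 0 else "left",
        }, indent=2))


def screw_decompose(t: RigidTransform) -> ScrewParameters:
    """Decompose a proper rigid motion into screw parameters.

    The twist comes from the rotation angle, the axis from the rotation's
    invariant direction, the rise from the translation component along the
    axis, and the axis point from solving the in-plane fixed-point equation
    (I − R) p = d_perp.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if math.degrees(angle) < MIN_TWIST_DEG:
        raise DegenerateGeometryError(
            f"rotation angle {math.degrees(angle):.3g}° < {MIN_TWIST_DEG}°: "
            "near-pure translation, screw axis ill-defined")
    axis = rotvec / angle
    rise = float(t.translation @ axis)
    # orient the axis so that the rise is non-negative; the rotation sense
    # about the re-oriented axis defines handedness
    sign = 1
    if rise < 0:
        axis, rise, sign = -axis, -rise, -1
    handedness = sign  # rotation is +angle about original axis

    d_perp = t.translation - (t.translation @ axis) * axis
    # Solve (I − R) p = d_perp for p in the plane normal to the axis.
    a_mat = np.eye(3) - t.rotation
    p, *_ = np.linalg.lstsq(a_mat, d_perp, rcond=None)
    p = p - (p @ axis) * axis  # canonical representative: closest to origin

    twist_deg = math.degrees(angle)
    if twist_deg > 180.0:
        twist_deg = 360.0 - twist_deg
        handedness = -handedness
    return ScrewParameters(twist_deg, axis, p, rise, handedness)


def unit_transform(octamer: Structure,
                   sel_t1: Sequence[str],
                   sel_t2: Sequence[str],
                   chain_pairing: dict[str, str] | None = None
                   ) -> tuple[RigidTransform, float]:
    """Rigid transform mapping repeating-unit selection 1 onto selection 2.

    This is the filament propagation step: superposing the Cα trace of one
    tetramer of the asymmetric unit onto the equivalent, adjacent tetramer.
    Chains are paired in the order given (or via *chain_pairing*); each
    paired chain must contribute the same number of Cα atoms.
    """
    sel_t1, sel_t2 = list(sel_t1), list(sel_t2)
    if chain_pairing is None:
        if len(sel_t1) != len(sel_t2):
            raise StructIOError("chain selections differ in length; provide chain_pairing")
        chain_pairing = dict(zip(sel_t1, sel_t2))
    mob, ref, mismatched = [], [], []
    for c1 in sel_t1:
        c2 = chain_pairing[c1]
        t1 = extract_ca(octamer, [c1])
        t2 = extract_ca(octamer, [c2])
        if len(t1) != len(t2):
            mismatched.append((c1, len(t1), c2, len(t2)))
            continue
        mob.append(ca_array(t1))
        ref.append(ca_array(t2))
    if mismatched:
        raise StructIOError(f"unequal residue pairing for chains: {mismatched}")
    if sel_t1 == sel_t2:
        return RigidTransform.identity(), 0.0
    return superpose(np.vstack(mob), np.vstack(ref))


@dataclass
class FilamentModel:
    """A reconstructed filament: n transformed copies of a repeating unit."""

    unit: Structure
    transform: RigidTransform
    copies: list[Structure]

    @property
    def n_units(self) -> int:
        return len(self.copies)

    def min_intercopy_ca_distance(self) -> float:
        """Steric sanity check: minimum Cα–Cα distance between distinct copies."""
        from scipy.spatial import cKDTree
        coords = [ca_array(extract_ca(c)) for c in self.copies]
        best = math.inf
        for i in range(len(coords)):
            tree = cKDTree(coords[i])
            for j in range(i + 1, len(coords)):
                d = tree.query(coords[j], k=1)[0].min()
                best = min(best, float(d))
        return best


def replicate_filament(unit: Structure, t: RigidTransform, n: int) -> FilamentModel:
    """Build a filament of *n* copies; copy k is t^k applied to the unit."""
    if n < 1:
        raise ValueError("need at least one copy")
    copies = []
    current = RigidTransform.identity()
    for _k in range(n):
        copies.append(unit.transformed(current))
        current = t.compose(current)
    return FilamentModel(unit, t, copies)


def _principal_axis(coords: np.ndarray, which: str = "smallest") -> np.ndarray:
    """Principal inertia axis of a point cloud (unit masses).

    ``which='smallest'`` returns the axis of smallest moment of inertia —
    the long axis of an elongated body.
    """
    x = coords - coords.mean(axis=0)
    inertia = np.trace(x.T @ x) * np.eye(3) - x.T @ x
    w, v = np.linalg.eigh(inertia)
    rel_spread = (w[1] - w[0]) / max(w[-1], 1e-12)
    if which == "smallest":
        if rel_spread < 1e-6:
            raise DegenerateGeometryError("inertia tensor nearly spherical; axis undefined")
        return v[:, 0]
    return v[:, 2]


def _interface_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Normal of the best-fit plane through a point cloud (smallest-variance
    direction of the centered coordinates)."""
    x = coords - coords.mean(axis=0)
    _u, _s, vt = np.linalg.svd(x, full_matrices=False)
    return vt[2]


def kink_angle(octamer: Structure,
               sel_t1: Sequence[str],
               sel_t2: Sequence[str],
               axis_rule: str = "inertia") -> float:
    """Angle (degrees, in [0, 90]) between the molecular axes of two units.

    ``axis_rule='inertia'`` uses each unit's principal inertia axis of
    smallest moment; ``axis_rule='plane'`` uses the normal of the best-fit
    plane through each unit's Cα cloud.
    """
    c1 = ca_array(extract_ca(octamer, list(sel_t1)))
    c2 = ca_array(extract_ca(octamer, list(sel_t2)))
    if axis_rule == "inertia":
        a1, a2 = _principal_axis(c1), _principal_axis(c2)
    elif axis_rule == "plane":
        a1, a2 = _interface_plane_normal(c1), _interface_plane_normal(c2)
    else:
        raise ValueError(f"unknown axis_rule {axis_rule!r}")
    cosang = abs(float(a1 @ a2)) / (np.linalg.norm(a1) * np.linalg.norm(a2))
    return math.degrees(math.acos(min(1.0, cosang)))
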