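"""Gō-model coarse-grained discrete molecular dynamics (DMD) and the
pocket-deformation statistic d_rms.

Model
-----
Each residue is a single Cα bead of unit mass.  Consecutive beads on a
chain are joined by hard bond windows around the native bond length.
Residue pairs forming a native contact (Cα–Cα distance ≤ 7.5 Å in the
native structure) interact through an attractive square well centred on the
native distance d0: an infinite wall at ``well_lo·d0``, well depth ε out to
``well_hi·d0`` and zero beyond.  All remaining pairs feel only a hardcore
repulsion.  Units are reduced: ε = 1, m = 1, k_B = 1.

Dynamics
--------
DMD is event-driven: beads fly ballistically between events, and at each
event (hardcore collision, well-boundary crossing, bond-window wall) the
two velocities are updated analytically from energy and momentum
conservation.  An Andersen-style thermostat resamples single-bead
velocities from the Maxwell–Boltzmann distribution at Poisson times.  A
"step" is one processed event.  Runs are bit-reproducible for a fixed seed.

Deformation statistic
---------------------
For a residue set of size n (e.g. the active-site pocket),

    d_rms = sqrt( (1/N) Σ_{i<j} (d_ij − d0_ij)² ),   N = n(n−1)/2,

over **all** pairs within the set, where d0 are native-state distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist

from .selection import ContactList

__all__ = [
    "GoParams",
    "GoModel",
    "Trajectory",
    "DrmsSummary",
    "build_go_model",
    "run_dmd",
    "compute_drms",
    "drms_profile",
]

_INF = 1.0e300

# pair interaction classes
_REPULSIVE = 0
_BOND = 1
_CONTACT = 2

# wall codes
_INNER = 0
_OUTER = 1


class DMDError(Exception):
    pass


@dataclass(frozen=True)
class GoParams:
    """Gō-potential parameters (reduced units; lengths in Å)."""

    epsilon: float = 1.0        # native-contact well depth
    well_lo: float = 0.85       # well inner wall, fraction of d0
    well_hi: float = 1.15       # well outer wall, fraction of d0
    hardcore: float = 3.6       # Å, non-native hard-sphere diameter
    bond_lo: float = 0.98       # bond window, fraction of native bond length
    bond_hi: float = 1.02
    mass: float = 1.0


@dataclass
class GoModel:
    """A Cα Gō model: native geometry plus the pair-interaction partition."""

    native: np.ndarray            # (N, 3) native bead coordinates, Å
    chain_index: np.ndarray       # (N,) chain id per bead
    bonds: np.ndarray             # (B, 2) bonded neighbour pairs
    bond_lengths: np.ndarray      # (B,) native bond lengths
    contacts: ContactList
    params: GoParams = field(default_factory=GoParams)

    @property
    def n_beads(self) -> int:
        return len(self.native)

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (N, N) interaction tables: pair type, inner-wall² and
        outer-wall² distances.  Every pair falls in exactly one class."""
        n = self.n_beads
        p = self.params
        ptype = np.full((n, n), _REPULSIVE, dtype=np.int8)
        rin2 = np.full((n, n), p.hardcore ** 2, dtype=np.float64)
        rout2 = np.full((n, n), _INF, dtype=np.float64)
        for (i, j), d0 in zip(self.contacts.pairs, self.contacts.distances):
            ptype[i, j] = ptype[j, i] = _CONTACT
            rin2[i, j] = rin2[j, i] = (p.well_lo * d0) ** 2
            rout2[i, j] = rout2[j, i] = (p.well_hi * d0) ** 2
        for (i, j), b0 in zip(self.bonds, self.bond_lengths):
            ptype[i, j] = ptype[j, i] = _BOND
            rin2[i, j] = rin2[j, i] = (p.bond_lo * b0) ** 2
            rout2[i, j] = rout2[j, i] = (p.bond_hi * b0) ** 2
        return ptype, rin2, rout2


def build_go_model(ca_coords: np.ndarray,
                   contacts: ContactList,
                   chain_index: np.ndarray | None = None,
                   params: GoParams = GoParams()) -> GoModel:
    """Assemble a Gō model from native Cα coordinates and their contact list.

    Bonds connect consecutive beads of each chain at their native length;
    native-contact pairs get square wells centred on their native distances;
    every other pair is hardcore-repulsive.
    """
    native = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    n = len(native)
    if chain_index is None:
        chain_index = np.zeros(n, dtype=np.int64)
    chain_index = np.asarray(chain_index, dtype=np.int64)

    bonds, lengths = [], []
    for i in range(n - 1):
        if chain_index[i] == chain_index[i + 1]:
            bonds.append((i, i + 1))
            lengths.append(float(np.linalg.norm(native[i + 1] - native[i])))
    bonds_arr = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    lengths_arr = np.array(lengths, dtype=float)

    bond_set = {(i, j) for i, j in bonds}
    contact_set = contacts.as_set()
    overlap = bond_set & contact_set
    if overlap:
        raise DMDError(f"bonded pairs present in contact list: {sorted(overlap)[:5]}")
    too_close = contacts.distances < params.hardcore
    if np.any(too_close):
        bad = contacts.pairs[too_close][:5]
        raise DMDError(f"native contact distance below hardcore diameter for pairs {bad.tolist()}")
    return GoModel(native, chain_index, bonds_arr, lengths_arr, contacts, params)


# ---------------------------------------------------------------------------
# Event-driven kernel (numba)
# ---------------------------------------------------------------------------

@njit(inline="always")
def _predict(i, j, pos, vel, ptype, rin2, rout2, bound, t_now):
    """Earliest future event time for pair (i, j); returns (t_abs, wall)."""
    rx = pos[i, 0] - pos[j, 0]
    ry = pos[i, 1] - pos[j, 1]
    rz = pos[i, 2] - pos[j, 2]
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    r2 = rx * rx + ry * ry + rz * rz
    v2 = vx * vx + vy * vy + vz * vz
    b = rx * vx + ry * vy + rz * vz
    if v2 <= 0.0:
        return _INF, _INNER
    kind = ptype[i, j]
    ri2 = rin2[i, j]
    ro2 = rout2[i, j]
    inside = kind == _BOND or (kind == _CONTACT and bound[i, j] == 1)

    t_best = _INF
    wall = _INNER
    if inside or kind == _REPULSIVE:
        # inner hard wall, reachable only while approaching
        if b < 0.0:
            disc = b * b - v2 * (r2 - ri2)
            if disc > 0.0:
                t = (-b - math.sqrt(disc)) / v2
                if t < t_best:
                    t_best = t
                    wall = _INNER
    if inside and ro2 < _INF:
        # outward crossing of the outer wall is always reachable from inside
        disc = b * b - v2 * (r2 - ro2)
        if disc < 0.0:
            disc = 0.0
        t = (-b + math.sqrt(disc)) / v2
        if t < t_best:
            t_best = t
            wall = _OUTER
    if (not inside) and kind == _CONTACT:
        # approaching the well from outside
        if b < 0.0:
            disc = b * b - v2 * (r2 - ro2)
            if disc > 0.0:
                t = (-b - math.sqrt(disc)) / v2
                if t < t_best:
                    t_best = t
                    wall = _OUTER
    if t_best < 0.0:
        t_best = 0.0
    if t_best >= _INF:
        return _INF, _INNER
    return t_now + t_best, wall


@njit(inline="always")
def _update_row(i, pos, vel, ptype, rin2, rout2, bound, t_now,
                nxt_t, nxt_j, nxt_w):
    """Recompute bead i's earliest pair event; push earlier events onto
    partners' rows so no collision is missed."""
    n = pos.shape[0]
    best_t = _INF
    best_j = -1
    best_w = _INNER
    for j in range(n):
        if j == i:
            continue
        t, w = _predict(i, j, pos, vel, ptype, rin2, rout2, bound, t_now)
        if t < best_t:
            best_t = t
            best_j = j
            best_w = w
        if t < nxt_t[j]:
            nxt_t[j] = t
            nxt_j[j] = i
            nxt_w[j] = w
    nxt_t[i] = best_t
    nxt_j[i] = best_j
    nxt_w[i] = best_w


@njit
def _run_kernel(pos, vel, ptype, rin2, rout2, bound,
                eps, mass, n_steps, snapshot_every, temperature,
                thermo_rate, seed,
                snapshots, snap_steps, energies, record_energy):
    """Main DMD loop.  Returns (status, n_snapshots): status 0 = ok,
    1 = event starvation (no future events)."""
    n = pos.shape[0]
    np.random.seed(seed)
    mu = 0.5 * mass  # reduced mass of a pair
    sqrt_t = math.sqrt(temperature / mass)

    nxt_t = np.full(n, _INF)
    nxt_j = np.full(n, -1, dtype=np.int64)
    nxt_w = np.zeros(n, dtype=np.int8)
    t_now = 0.0
    for i in range(n):
        _update_row(i, pos, vel, ptype, rin2, rout2, bound, t_now,
                    nxt_t, nxt_j, nxt_w)

    th_t = np.full(n, _INF)
    if thermo_rate > 0.0:
        for i in range(n):
            th_t[i] = t_now + np.random.exponential(1.0 / thermo_rate)

    # potential energy bookkeeping: −eps per bound contact pair
    n_bound = 0
    for i in range(n):
        for j in range(i + 1, n):
            if ptype[i, j] == _CONTACT and bound[i, j] == 1:
                n_bound += 1

    n_snap = 0
    for step in range(n_steps):
        # next pair event
        tp = _INF
        ip = -1
        for i in range(n):
            if nxt_t[i] < tp:
                tp = nxt_t[i]
                ip = i
        # next thermostat event
        tt = _INF
        it = -1
        for i in range(n):
            if th_t[i] < tt:
                tt = th_t[i]
                it = i
        if tp >= _INF and tt >= _INF:
            return 1, n_snap

        if tt < tp:
            # Andersen thermostat: resample one bead from Maxwell-Boltzmann
            dt = tt - t_now
            for i in range(n):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
            t_now = tt
            vel[it, 0] = sqrt_t * np.random.normal(0.0, 1.0)
            vel[it, 1] = sqrt_t * np.random.normal(0.0, 1.0)
            vel[it, 2] = sqrt_t * np.random.normal(0.0, 1.0)
            th_t[it] = t_now + np.random.exponential(1.0 / thermo_rate)
            # invalidate rows pointing at the resampled bead, then its own row
            for k in range(n):
                if nxt_j[k] == it:
                    _update_row(k, pos, vel, ptype, rin2, rout2, bound, t_now,
                                nxt_t, nxt_j, nxt_w)
            _update_row(it, pos, vel, ptype, rin2, rout2, bound, t_now,
                        nxt_t, nxt_j, nxt_w)
        else:
            i = ip
            j = nxt_j[i]
            wall = nxt_w[i]
            dt = tp - t_now
            for k in range(n):
                pos[k, 0] += vel[k, 0] * dt
                pos[k, 1] += vel[k, 1] * dt
                pos[k, 2] += vel[k, 2] * dt
            t_now = tp

            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            r = math.sqrt(r2)
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            a = (rx * vx + ry * vy + rz * vz) / r  # radial relative speed

            kind = ptype[i, j]
            if wall == _INNER or kind == _BOND:
                a_new = -a                        # hard reflection
            else:
                # outer wall of a native-contact square well
                if bound[i, j] == 1:
                    if a > 0.0 and mu * a * a > 2.0 * eps:
                        a_new = math.sqrt(a * a - 2.0 * eps / mu)   # escape
                        bound[i, j] = 0
                        bound[j, i] = 0
                        n_bound -= 1
                    else:
                        a_new = -a                                   # bounce back in
                else:
                    a_new = -math.sqrt(a * a + 2.0 * eps / mu)       # capture
                    bound[i, j] = 1
                    bound[j, i] = 1
                    n_bound += 1
            da = 0.5 * (a_new - a)
            nx = rx / r
            ny = ry / r
            nz = rz / r
            vel[i, 0] += da * nx
            vel[i, 1] += da * ny
            vel[i, 2] += da * nz
            vel[j, 0] -= da * nx
            vel[j, 1] -= da * ny
            vel[j, 2] -= da * nz

            for k in range(n):
                if k != i and k != j and (nxt_j[k] == i or nxt_j[k] == j):
                    _update_row(k, pos, vel, ptype, rin2, rout2, bound, t_now,
                                nxt_t, nxt_j, nxt_w)
            _update_row(i, pos, vel, ptype, rin2, rout2, bound, t_now,
                        nxt_t, nxt_j, nxt_w)
            _update_row(j, pos, vel, ptype, rin2, rout2, bound, t_now,
                        nxt_t, nxt_j, nxt_w)

        if record_energy:
            ke = 0.0
            for k in range(n):
                ke += vel[k, 0] ** 2 + vel[k, 1] ** 2 + vel[k, 2] ** 2
            ke *= 0.5 * mass
            energies[step, 0] = ke
            energies[step, 1] = -eps * n_bound
            energies[step, 2] = t_now
        if (step + 1) % snapshot_every == 0:
            for k in range(n):
                snapshots[n_snap, k, 0] = pos[k, 0]
                snapshots[n_snap, k, 1] = pos[k, 1]
                snapshots[n_snap, k, 2] = pos[k, 2]
            snap_steps[n_snap] = step + 1
            n_snap += 1
    return 0, n_snap


@dataclass
class Trajectory:
    """Snapshots of a DMD run (bead coordinates at regular event counts)."""

    steps: np.ndarray             # (F,) event index of each frame
    frames: np.ndarray            # (F, N, 3) coordinates, Å
    seed: int
    temperature: float
    n_steps: int
    snapshot_every: int
    energies: np.ndarray | None = None   # (n_steps, 3): kinetic, potential, time

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    def kinetic_temperature(self, n_beads: int | None = None) -> np.ndarray:
        """Instantaneous kinetic temperature per recorded event, T = 2·KE/(3N)."""
        if self.energies is None:
            raise DMDError("run with record_energy=True to get temperatures")
        n = self.frames.shape[1] if n_beads is None else n_beads
        return 2.0 * self.energies[:, 0] / (3.0 * n)

    def mean_kinetic_temperature(self, burn_in_fraction: float = 1.0 / 3.0
                                 ) -> float:
        """Time-weighted mean kinetic temperature after burn-in.

        Event-weighted averages are biased upward (events cluster when the
        system is transiently hot), so each recorded KE is weighted by the
        length of the inter-event interval it spans.
        """
        t_kin = self.kinetic_temperature()
        times = self.energies[:, 2]
        start = int(burn_in_fraction * len(t_kin))
        dt = np.diff(times[start:])
        if dt.sum() <= 0:
            raise DMDError("no elapsed time in averaging window")
        return float(np.sum(t_kin[start:-1] * dt) / dt.sum())


def run_dmd(model: GoModel,
            n_steps: int,
            temperature: float = 0.5,
            seed: int = 0,
            snapshot_every: int = 1000,
            thermostat_rate: float = 0.1,
            record_energy: bool = False,
            start_coords: np.ndarray | None = None,
            start_velocities: np.ndarray | None = None) -> Trajectory:
    """Run event-driven DMD; a step is one processed event.

    Velocities are initialised from the Maxwell–Boltzmann distribution at
    the target temperature with the net momentum removed.  Setting
    ``thermostat_rate=0`` disables the Andersen thermostat (microcanonical
    run; total energy is then conserved exactly up to round-off).
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p = model.params
    pos = np.array(model.native if start_coords is None else start_coords,
                   dtype=np.float64).reshape(-1, 3).copy()
    if pos.shape != model.native.shape:
        raise DMDError("start coordinates shape mismatch")
    ptype, rin2, rout2 = model.pair_tables()

    # initial-state sanity: no pair may start inside its inner wall
    d2 = np.square(pos[:, None, :] - pos[None, :, :]).sum(axis=2)
    np.fill_diagonal(d2, _INF)
    if np.any(d2 < rin2 * (1.0 - 1e-9)):
        raise DMDError("bead overlap in initial state (pair inside its hard wall)")

    bound = np.zeros_like(ptype, dtype=np.int8)
    contact_mask = ptype == _CONTACT
    bound[contact_mask & (d2 <= rout2)] = 1

    if start_velocities is not None:
        vel = np.array(start_velocities, dtype=np.float64).reshape(pos.shape).copy()
    else:
        rng = np.random.default_rng(seed)
        vel = rng.normal(0.0, math.sqrt(temperature / p.mass), size=pos.shape)
        vel -= vel.mean(axis=0)

    n_snap_max = n_steps // snapshot_every
    snapshots = np.zeros((max(n_snap_max, 1), pos.shape[0], 3))
    snap_steps = np.zeros(max(n_snap_max, 1), dtype=np.int64)
    energies = np.zeros((n_steps if record_energy else 1, 3))

    kernel_seed = int((seed + 987654321) % 2147483647)
    status, n_snap = _run_kernel(pos, vel, ptype, rin2, rout2, bound,
                                 p.epsilon, p.mass, n_steps, snapshot_every,
                                 temperature, thermostat_rate, kernel_seed,
                                 snapshots, snap_steps, energies,
                                 record_energy)
    if status == 1:
        raise DMDError("event queue starved: no future events (all beads at rest?)")
    return Trajectory(snap_steps[:n_snap].copy(), snapshots[:n_snap].copy(),
                      seed, temperature, n_steps, snapshot_every,
                      energies if record_energy else None)


# ---------------------------------------------------------------------------
# d_rms
# ---------------------------------------------------------------------------

def compute_drms(frame_coords: np.ndarray,
                 native_coords: np.ndarray,
                 indices: Sequence[int]) -> float:
    """Pocket/interface deformation d_rms (Å) of one frame.

    All n(n−1)/2 distinct pairs within the residue set contribute, whether
    or not they are native contacts.
    """
    idx = np.asarray(sorted(indices), dtype=np.int64)
    if len(idx) < 2:
        raise ValueError("need at least 2 residues for d_rms")
    d = pdist(np.asarray(frame_coords, dtype=float)[idx])
    d0 = pdist(np.asarray(native_coords, dtype=float)[idx])
    return float(np.sqrt(np.mean((d - d0) ** 2)))


@dataclass
class DrmsSummary:
    """Pooled per-frame d_rms distribution over one or more replicas."""

    values: np.ndarray
    mean: float
    sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @classmethod
    def from_values(cls, values: np.ndarray, bins: int = 50) -> "DrmsSummary":
        values = np.asarray(values, dtype=float)
        counts, edges = np.histogram(values, bins=bins)
        return cls(values, float(values.mean()), float(values.std(ddof=0)),
                   counts, edges)


def drms_profile(trajectories: Sequence[Trajectory],
                 model: GoModel,
                 indices: Sequence[int],
                 burn_in_fraction: float = 2.0 / 6.0,
                 bins: int = 50) -> DrmsSummary:
    """d_rms of every retained frame, pooled across replicas.

    Frames within the first ``burn_in_fraction`` of each run are discarded
    (the production convention: analyse only the final part of each
    trajectory).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    values = []
    for traj in trajectories:
        cut = burn_in_fraction * traj.n_steps
        if cut >= traj.n_steps:
            raise ValueError("burn-in covers the entire trajectory")
        for step, frame in zip(traj.steps, traj.frames):
            if step > cut:
                values.append(compute_drms(frame, model.native, indices))
    return DrmsSummary.from_values(np.array(values), bins=bins)
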