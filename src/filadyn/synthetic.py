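"""Synthetic structure generator with planted ground truth.

Every analysis stage of the package can be exercised without any external
structure files: this module builds compact Cα chains, tetramer and
octamer-with-linkers assemblies (a stand-in for an enzyme tetramer and for
two tetramers cross-linked by small dimeric partners at a filament
junction), and helical stacks generated by exact screw transforms.  All
fixtures are synthetic surrogates — random compact bead chains, not real
protein geometry — and each generator returns the planted ground truth
(pocket membership, junction patches, screw parameters) computed here by
direct brute-force scans, independently of the analysis modules under test.

The octamer analog plants the allosteric signature of filament junctions by
construction.  The junction-facing pocket segment of each tetramer is
pulled towards the junction (stripping most of its packing against its own
chain), two linker chains bridge the two segments, and the junction
pseudo-ligands are re-planted in the junction cleft so those pockets
straddle the hinge between the tetramers.  The hinge is always among the
softest modes of the assembly and carries opposite phases on its two
sides, so low-frequency modes deform the junction pockets (low C_pocket),
and the loosely tethered junction cluster enlarges their d_rms in the Gō
dynamics, while the free tetramer's compact single-chain pockets ride
rigidly.  A small deterministic jitter breaks the exact D2 symmetry of the
tetramer so its spectrum has no artificially degenerate mode pairs.  This
is a planted surrogate of the biological effect, not a biological claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structio import Atom, Chain, Residue, ResidueId, RigidTransform, Structure

__all__ = [
    "GenerationError",
    "make_compact_chain",
    "make_tetramer_analog",
    "make_octamer_analog",
    "make_helical_fixture",
    "TetramerTruth",
    "OctamerTruth",
    "HelixTruth",
]

BOND_LENGTH = 3.8      # Å, virtual Cα–Cα bond
MIN_SEPARATION = 4.0   # Å, excluded-volume floor between non-bonded beads
POCKET_RADIUS = 6.0    # Å, planted pockets are defined with this expansion
CONTACT_RANGE = (4.3, 7.0)   # Å, acceptable chain–chain touching distance


class GenerationError(Exception):
    pass


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _chain_from_coords(coords: np.ndarray, chain_id: str,
                       resname: str = "GLY") -> Chain:
    residues = [Residue(i + 1, resname,
                        [Atom("CA", "C", coords[i])], "", False)
                for i in range(len(coords))]
    return Chain(chain_id, residues)


def _ligand_chain(positions: np.ndarray, chain_id: str = "Z") -> Chain:
    residues = [Residue(i + 1, "LIG", [Atom("P1", "P", positions[i])], "", True)
                for i in range(len(positions))]
    return Chain(chain_id, residues)


def _chain_coords(structure: Structure, chain_id: str) -> np.ndarray:
    return np.array([r.atoms[0].pos for r in structure.chain(chain_id).residues
                     if not r.hetero])


# ---------------------------------------------------------------------------
# Compact chain
# ---------------------------------------------------------------------------

def make_compact_chain(n: int, seed: int,
                       bond: float = BOND_LENGTH,
                       min_sep: float = MIN_SEPARATION,
                       radius_factor: float = 3.0,
                       max_restarts: int = 200) -> Structure:
    """Self-avoiding compact Cα chain of *n* residues.

    Beads are grown with fixed virtual bonds inside a sphere of radius
    ``radius_factor · n^(1/3)`` Å (protein-like density), keeping every
    non-bonded pair at least *min_sep* Å apart so the hardcore diameter of
    the Gō model is respected.  Deterministic for a fixed seed.
    """
    if n < 4:
        raise GenerationError("need at least 4 residues")
    radius = radius_factor * n ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    for _restart in range(max_restarts):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _try in range(120):
                v = rng.normal(size=3)
                v *= bond / np.linalg.norm(v)
                cand = coords[i - 1] + v
                if np.linalg.norm(cand) > radius:
                    continue
                if i >= 2:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            coords -= coords.mean(axis=0)
            return Structure([_chain_from_coords(coords, "A")], name=f"chain{n}")
    raise GenerationError(f"failed to place a {n}-residue compact chain "
                          f"after {max_restarts} restarts")


# ---------------------------------------------------------------------------
# Brute-force ground-truth scans (independent of the selection module)
# ---------------------------------------------------------------------------

def _brute_pocket(structure: Structure, ligand_pos: np.ndarray,
                  cutoff: float = POCKET_RADIUS) -> list[ResidueId]:
    """Residues with any atom within cutoff of any ligand atom (double loop)."""
    ligand_pos = np.asarray(ligand_pos, dtype=float).reshape(-1, 3)
    hits = []
    for cid, res in structure.iter_residues():
        if res.hetero:
            continue
        found = False
        for a in res.atoms:
            for lp in ligand_pos:
                if np.linalg.norm(a.pos - lp) <= cutoff:
                    found = True
                    break
            if found:
                break
        if found:
            hits.append((cid, res.number, res.icode))
    return hits


def _brute_interface(structure: Structure, chains_a: list[str],
                     chains_b: list[str], cutoff: float) -> list[ResidueId]:
    coords_b = np.vstack([_chain_coords(structure, c) for c in chains_b])
    hits = []
    for cid in chains_a:
        for res in structure.chain(cid).residues:
            if res.hetero:
                continue
            d = np.linalg.norm(coords_b - res.atoms[0].pos, axis=1)
            if d.min() <= cutoff:
                hits.append((cid, res.number, res.icode))
    return hits


def _min_interchain_dist(coords_sets: list[np.ndarray]) -> float:
    best = math.inf
    for i in range(len(coords_sets)):
        for j in range(i + 1, len(coords_sets)):
            d = np.linalg.norm(coords_sets[i][:, None, :]
                               - coords_sets[j][None, :, :], axis=2).min()
            best = min(best, float(d))
    return best


# ---------------------------------------------------------------------------
# Tetramer analog
# ---------------------------------------------------------------------------

@dataclass
class TetramerTruth:
    """Planted ground truth for a tetramer analog."""

    pockets: dict[str, list[ResidueId]]          # pocket label → member residues
    ligand_sites: dict[str, np.ndarray]          # pocket label → pseudo-atom position
    chains: list[str] = field(default_factory=lambda: ["A", "B", "C", "D"])


def _dock_d2(monomer: np.ndarray, target_touch: float = 4.8) -> list[np.ndarray]:
    """Place four copies of a monomer as a D2 dimer-of-dimers.

    A tight dimer (A with its Rx(180°) mate C) is docked first by scanning
    the y offset until the two chains just touch; the dimer is then docked
    against its Rz(180°) copy (chains B, D) along x the same way.  The
    result is closed under the D2 operations, with A–C and B–D the tight
    dimer interfaces (where the pockets are planted) and a weaker
    dimer–dimer interface holding the tetramer together.
    """
    rz = _rotation([0, 0, 1], 180.0)
    rx = _rotation([1, 0, 0], 180.0)

    def bisect(fn, lo: float, hi: float) -> float:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if fn(mid) < target_touch:
                lo = mid
            else:
                hi = mid
        return hi

    def dimer(t: float) -> tuple[np.ndarray, np.ndarray]:
        a = monomer + np.array([0.0, t, 0.0])
        return a, a @ rx.T

    t = bisect(lambda t: _min_interchain_dist(list(dimer(t))), 0.0, 80.0)
    a0, c0 = dimer(t)

    def tetra(u: float) -> list[np.ndarray]:
        a = a0 + np.array([-u, 0.0, 0.0])
        c = c0 + np.array([-u, 0.0, 0.0])
        return [a, a @ rz.T, c, c @ rz.T]  # A, B, C, D

    u = bisect(lambda u: _min_interchain_dist([np.vstack(tetra(u)[::2]),
                                               np.vstack(tetra(u)[1::2])]),
               0.0, 80.0)
    chains = tetra(u)
    d_dimer = _min_interchain_dist([chains[0], chains[2]])
    d_cross = _min_interchain_dist([np.vstack([chains[0], chains[2]]),
                                    np.vstack([chains[1], chains[3]])])
    if not (CONTACT_RANGE[0] <= d_dimer <= CONTACT_RANGE[1]
            and CONTACT_RANGE[0] <= d_cross <= CONTACT_RANGE[1]):
        raise GenerationError(
            f"docking failed: dimer gap {d_dimer:.2f} Å, cross gap {d_cross:.2f} Å")
    return chains


def _closest_pair(ca: np.ndarray, cb: np.ndarray) -> tuple[int, int, float]:
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return int(i), int(j), float(d[i, j])


def _pocket_anchor(chain: np.ndarray, min_neighbors: int = 6) -> int:
    """Index of the pocket anchor residue: the most +x-exposed residue that
    is still well embedded (≥ *min_neighbors* residues within 6.5 Å), so the
    planted pocket is a dimple cluster rather than a floppy protrusion."""
    d = np.linalg.norm(chain[:, None] - chain[None], axis=2)
    n_nbr = (d <= 6.5).sum(axis=1) - 1
    ok = np.where(n_nbr >= min_neighbors)[0]
    if len(ok) == 0:
        ok = np.arange(len(chain))
    return int(ok[np.argmax(chain[ok, 0])])


def _pocket_sites(chains: dict[str, np.ndarray], istar: int,
                  offset: float = 1.5) -> dict[str, np.ndarray]:
    """One pseudo-ligand site per chain: a fixed surface residue (index
    *istar*, the same residue on every symmetry copy) displaced *offset* Å
    outward from the assembly centre, so the planted pocket is a compact
    surface cluster of that chain."""
    center = np.vstack(list(chains.values())).mean(axis=0)
    sites = {}
    for cid, c in chains.items():
        out = c[istar] - center
        out = out / np.linalg.norm(out)
        sites[cid] = c[istar] + offset * out
    return sites


def make_tetramer_analog(chain_length: int = 40, seed: int = 0,
                         radius_factor: float = 2.7,
                         target_touch: float = 4.8,
                         jitter: float = 0.35
                         ) -> tuple[Structure, TetramerTruth]:
    """Four copies of a compact chain in a D2 dimer-of-dimers arrangement
    with four planted active-site pockets, one per chain.

    Each pocket is defined by a pseudo-ligand placed just outside a fixed
    surface residue of its chain — the residue that, on chain B, faces the
    +x side where a filament junction would attach.  Ground-truth pocket
    membership is computed by brute-force scan.
    """
    mono = _chain_coords(make_compact_chain(chain_length, seed,
                                             radius_factor=radius_factor), "A")
    placed = _dock_d2(mono, target_touch)
    ids = ["A", "B", "C", "D"]

    # break the exact D2 symmetry with a small deterministic jitter so the
    # network spectrum has no artificially degenerate mode pairs (whose
    # arbitrary eigenvector mixtures would contaminate sign correlations)
    rng = np.random.default_rng(seed + 424242)
    amp = jitter
    for _ in range(6):
        trial = [c + rng.normal(0.0, amp, size=c.shape) for c in placed]
        flat = np.vstack(trial)
        d = np.linalg.norm(flat[:, None] - flat[None], axis=2)
        np.fill_diagonal(d, np.inf)
        for k in range(len(flat) - 1):  # bonded neighbours may sit closer
            if (k + 1) % len(placed[0]) != 0:
                d[k, k + 1] = d[k + 1, k] = np.inf
        if amp == 0.0 or d.min() >= MIN_SEPARATION - 0.25:
            placed = trial
            break
        amp = 0.0 if amp < 0.1 else amp / 2.0
    chains = {cid: c for cid, c in zip(ids, placed)}

    # the pocket anchor: a well-embedded residue on chain B's +x face
    istar = _pocket_anchor(chains["B"])
    sites = _pocket_sites(chains, istar)

    lig_pos = np.array([sites[c] for c in ids])
    structure = Structure([_chain_from_coords(chains[c], c) for c in ids]
                          + [_ligand_chain(lig_pos)], name="tetramer_analog")
    pockets = {cid: _brute_pocket(structure, sites[cid][None, :]) for cid in ids}
    return structure, TetramerTruth(pockets, sites)


# ---------------------------------------------------------------------------
# Octamer analog (two tetramers + two junction linkers)
# ---------------------------------------------------------------------------

@dataclass
class OctamerTruth:
    """Planted ground truth for an octamer-plus-linkers analog."""

    pockets: dict[str, list[ResidueId]]
    ligand_sites: dict[str, np.ndarray]
    interface_patches: dict[str, list[ResidueId]]   # per tetramer, junction residues
    tetramer1_chains: list[str]
    tetramer2_chains: list[str]
    linker_chains: list[str]
    junction_pull: float


def _steer_linker(lk: np.ndarray, primary: np.ndarray, secondary: np.ndarray,
                  d_primary: float, d_secondary: float,
                  obstacle: np.ndarray | None = None,
                  avoid: np.ndarray | None = None,
                  n_iter: int = 80) -> np.ndarray:
    """Iteratively translate a rigid linker blob until its minimum distance
    to *primary* is ~d_primary and to *secondary* ~d_secondary, while
    staying clear of an optional *obstacle* point cloud and keeping a hard
    floor against the *avoid* cloud."""

    def pull(lk: np.ndarray, coords: np.ndarray, target: float,
             gain: float) -> np.ndarray:
        dmat = np.linalg.norm(coords[:, None] - lk[None], axis=2)
        bi, li = np.unravel_index(np.argmin(dmat), dmat.shape)
        d = float(dmat[bi, li])
        direction = coords[bi] - lk[li]
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            return lk
        step = min(1.0, max(-1.0, gain * (d - target)))
        return lk + step * direction / nrm

    for _ in range(n_iter):
        lk = pull(lk, primary, d_primary, 0.6)
        lk = pull(lk, secondary, d_secondary, 0.4)
        if obstacle is not None:
            d_obs = np.linalg.norm(obstacle[:, None] - lk[None], axis=2).min()
            if d_obs < MIN_SEPARATION + 1.5:
                lk = pull(lk, obstacle, MIN_SEPARATION + 1.5, 0.8)
        if avoid is not None:
            d_av = np.linalg.norm(avoid[:, None] - lk[None], axis=2).min()
            if d_av < MIN_SEPARATION:
                lk = pull(lk, avoid, MIN_SEPARATION, 1.0)
        d1 = np.linalg.norm(primary[:, None] - lk[None], axis=2).min()
        d2 = np.linalg.norm(secondary[:, None] - lk[None], axis=2).min()
        if abs(d1 - d_primary) < 0.2 and abs(d2 - d_secondary) < 0.3:
            break
    return lk


def make_octamer_analog(chain_length: int = 40, seed: int = 0,
                        linker_length: int = 14,
                        gap: float = 10.0,
                        junction_pull: float = 4.5,
                        interface_cutoff: float = 7.5,
                        radius_factor: float = 2.7,
                        target_touch: float = 4.8
                        ) -> tuple[Structure, OctamerTruth]:
    """Two tetramer analogs joined head-to-tail by two small linker chains,
    with the junction planted to deform the junction-facing pockets.

    Tetramer 2 (chains E-H) is tetramer 1 (A-D) flipped about y and
    translated along +x, so chain F (the copy of B) directly faces chain B
    across the gap.  The pocket segment of each junction chain (the pocket
    residues of B, and of F by symmetry) is pulled up to *junction_pull* Å
    towards the junction before native contacts are defined — far enough to
    strip most of its packing against its own chain while keeping every
    backbone virtual bond inside the elastic-network cutoff.  Two linker
    chains (S, T — standing in for the cross-linking dimers) then bridge
    the two pulled segments directly, and the junction pseudo-ligands are
    re-planted inside this segment–linker cluster.  The junction pockets
    therefore contain beads of both linkers, whose in-phase/anti-phase pair
    of soft modes guarantees low-frequency pocket deformation, while the
    loosely tethered cluster enlarges the pocket d_rms in the dynamics —
    the planted allosteric signature.  Ground truth (pocket membership on
    the final geometry, junction interface patches) is computed by brute
    force.
    """
    tet, _tet_truth = make_tetramer_analog(chain_length, seed,
                                           radius_factor, target_touch)
    coords = {cid: _chain_coords(tet, cid) for cid in "ABCD"}
    istar = _pocket_anchor(coords["B"])
    x_dir = np.array([1.0, 0.0, 0.0])

    # pull the junction-facing pocket segment of chain B towards +x, capped
    # so every backbone bond stays within the 7.5 Å network cutoff
    sites0 = _pocket_sites(coords, istar)
    seg = np.linalg.norm(coords["B"] - sites0["B"], axis=1) <= POCKET_RADIUS
    rest = np.vstack([coords[c] for c in "ACD"])
    pull = junction_pull
    while pull > 0.5:
        b_mod = coords["B"].copy()
        b_mod[seg] += pull * x_dir
        bond_len = np.linalg.norm(np.diff(b_mod, axis=0), axis=1)
        moved = b_mod[seg]
        d_other = min(
            _min_interchain_dist([moved, b_mod[~seg]]),
            _min_interchain_dist([moved, rest]))
        if bond_len.max() <= 7.3 and d_other >= 3.7:
            break
        pull -= 0.25
    pulled = dict(coords)
    pulled["B"] = b_mod

    extent = max(c[:, 0].max() for c in pulled.values())
    offset = 2.0 * extent + gap

    # tetramer 2: copy flipped about y so chain F (copy of B) faces chain B
    flip = _rotation([0, 1, 0], 180.0)

    def build_t2(off: float) -> dict[str, np.ndarray]:
        return {dst: (pulled[src] @ flip.T) + off * x_dir
                for dst, src in zip("EFGH", "ABCD")}

    chains1 = {cid: pulled[cid] for cid in "ABCD"}
    t2 = build_t2(offset)
    # close the junction until the two pulled segments approach to ≤9.5 Å,
    # so the junction pseudo-ligand reaches residues of both tetramers
    d_seg = _min_interchain_dist([chains1["B"][seg], t2["F"][seg]])
    if d_seg > 9.5:
        for shift in np.arange(0.5, d_seg - 9.5 + 0.51, 0.5):
            cand = build_t2(offset - shift)
            if _min_interchain_dist(
                    [np.vstack(list(chains1.values())),
                     np.vstack(list(cand.values()))]) < MIN_SEPARATION + 0.3:
                break
            t2 = cand
            if _min_interchain_dist([chains1["B"][seg], t2["F"][seg]]) <= 9.5:
                break
    all_prot = {**chains1, **t2}

    # linkers: S and T both bridge the pulled segments of B and F, one
    # above and one below the junction midline
    seg_b = chains1["B"][seg]
    seg_f = t2["F"][seg]
    protein = np.vstack(list(all_prot.values()))
    linkers: dict[str, np.ndarray] = {}
    for attempt, z0 in enumerate((8.0, 11.0, 8.0, 11.0, 14.0, 14.0)):
        trial: dict[str, np.ndarray] = {}
        for lid, grab, lean, zsign in (("S", seg_b, seg_f, +1.0),
                                       ("T", seg_f, seg_b, -1.0)):
            base = _chain_coords(
                make_compact_chain(linker_length,
                                   seed + ord(lid) + 37 * attempt), "A")
            start = 0.5 * (seg_b.mean(axis=0) + seg_f.mean(axis=0))
            start[2] += zsign * z0
            lk = base - base.mean(axis=0) + start
            lk = _steer_linker(lk, grab, lean, 4.5, 5.0,
                               obstacle=trial.get("S"), avoid=protein)
            d1 = np.linalg.norm(grab[:, None] - lk[None], axis=2).min()
            d2 = np.linalg.norm(lean[:, None] - lk[None], axis=2).min()
            if (CONTACT_RANGE[0] - 0.5 <= d1 <= CONTACT_RANGE[1] + 0.5
                    and CONTACT_RANGE[0] - 0.5 <= d2 <= CONTACT_RANGE[1] + 0.5):
                trial[lid] = lk
        if len(trial) != 2:
            continue
        # hard floor against every protein bead (the Gō hardcore is 3.6 Å)
        # and mutual linker separation
        floor = min(_min_interchain_dist([trial["S"], protein]),
                    _min_interchain_dist([trial["T"], protein]))
        if (floor >= 3.7 and _min_interchain_dist(
                [trial["S"], trial["T"]]) >= MIN_SEPARATION):
            linkers = trial
            break
    if not linkers:
        raise GenerationError("linker placement failed after bounded retries")

    # pocket pseudo-ligands: the junction pockets (B, F) are re-planted in
    # the junction cleft itself, so they straddle the hinge between the two
    # tetramers (segments of B and F plus linker beads); the other pockets
    # stay at their chain's anchor
    ib, jf, _d = _closest_pair(seg_b, seg_f)
    junction_site = 0.5 * (seg_b[ib] + seg_f[jf])
    sites1 = dict(sites0)
    sites1["B"] = junction_site - 0.8 * x_dir
    sites = dict(sites1)
    for dst, src in zip("EFGH", "ABCD"):
        sites[dst] = (sites1[src] @ flip.T) + offset * x_dir

    chain_order = list("ABCDEFGH")
    all_chains = [_chain_from_coords(all_prot[c], c) for c in chain_order]
    all_chains += [_chain_from_coords(linkers[c], c) for c in "ST"]
    lig_pos = np.array([sites[c] for c in chain_order])
    structure = Structure(all_chains + [_ligand_chain(lig_pos)],
                          name="octamer_analog")

    pockets = {cid: _brute_pocket(structure, sites[cid][None, :])
               for cid in chain_order}
    patches = {
        "tetramer1": sorted(set(
            _brute_interface(structure, list("ABCD"), list("ST"), interface_cutoff)
            + _brute_interface(structure, list("ABCD"), list("EFGH"), interface_cutoff))),
        "tetramer2": sorted(set(
            _brute_interface(structure, list("EFGH"), list("ST"), interface_cutoff)
            + _brute_interface(structure, list("EFGH"), list("ABCD"), interface_cutoff))),
    }
    truth = OctamerTruth(pockets, sites, patches,
                         list("ABCD"), list("EFGH"), list("ST"), pull)
    return structure, truth


# ---------------------------------------------------------------------------
# Helical fixtures
# ---------------------------------------------------------------------------

@dataclass
class HelixTruth:
    twist_deg: float
    rise: float
    kink_deg: float
    n_units: int
    transform: RigidTransform
    unit_chain_sets: list[list[str]]


def make_helical_fixture(unit: Structure | None = None,
                         twist: float = 40.0,
                         rise: float = 50.0,
                         kink: float = 0.0,
                         n: int = 9,
                         seed: int = 0) -> tuple[Structure, HelixTruth]:
    """Stack of *n* unit copies generated by an exact screw transform about
    the z axis (twist in degrees, rise in Å), optionally composed with a
    *kink* rotation about y.

    If no unit is given, a z-elongated two-chain unit is generated, so the
    angle between the principal axes of the first two copies equals the
    planted kink exactly.
    """
    if not 0.0 < twist <= 180.0:
        raise GenerationError("twist must be in (0, 180] degrees")
    if unit is None:
        chain = _chain_coords(make_compact_chain(30, seed), "A")
        stretched = chain * np.array([0.6, 0.6, 2.2])  # elongate along z
        # align the principal inertia axis (smallest moment) exactly with z,
        # so the kink between consecutive copies is the planted angle
        x = stretched - stretched.mean(axis=0)
        inertia = np.trace(x.T @ x) * np.eye(3) - x.T @ x
        _w, v = np.linalg.eigh(inertia)
        if np.linalg.det(v) < 0:
            v = -v
        aligned = x @ v[:, [1, 2, 0]]  # smallest-moment axis -> z
        unit = Structure([
            _chain_from_coords(aligned + np.array([12.0, 0.0, 0.0]), "A"),
            _chain_from_coords(aligned + np.array([18.5, 0.0, 0.0]), "B"),
        ], name="helix_unit")

    rot = _rotation([0, 0, 1], twist)
    if kink != 0.0:
        rot = rot @ _rotation([0, 1, 0], kink)
    t = RigidTransform(rot, np.array([0.0, 0.0, rise]))

    copies = []
    chain_sets = []
    current = RigidTransform.identity()
    for k in range(n):
        moved = unit.transformed(current)
        renamed = []
        names = []
        for c in moved.chains:
            cid = f"{c.id}{k}" if n > 1 else c.id
            renamed.append(Chain(cid, c.residues))
            names.append(cid)
        copies.extend(renamed)
        chain_sets.append(names)
        current = t.compose(current)
    structure = Structure(copies, name="helical_fixture")
    return structure, HelixTruth(twist, rise, kink, n, t, chain_sets)
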