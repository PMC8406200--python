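"""Residue selections: native contacts, active-site pockets, junction interfaces.

The three distance-based selections share the conventions used throughout the
package: Euclidean distances in Å with inclusive (≤) cutoffs.  Native
contacts use a 7.5 Å Cα–Cα cutoff; pockets are a 6 Å all-atom expansion
around bound ligand atoms; junction interfaces collect residues within
7.5 Å (0.75 nm) of a partner chain group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import (
    ResidueId,
    RigidTransform,
    SelectionError,
    Structure,
    extract_ca,
)

__all__ = [
    "ContactList",
    "ResidueSet",
    "native_contacts",
    "pocket_residues",
    "interface_residues",
    "junction_interface_residues",
    "map_residue_set",
]

#: Defaults shared with the dynamics/network modules.
CONTACT_CUTOFF = 7.5      # Å, Cα–Cα native-contact cutoff
POCKET_EXPANSION = 6.0    # Å, around active-site ligand atoms
INTERFACE_CUTOFF = 7.5    # Å (= 0.75 nm), junction interface definition
MIN_SEQ_SEP = 2           # exclude i,i+1 (bonds) from intra-chain contacts


@dataclass
class ContactList:
    """Native-contact pairs ``(i, j, d0_ij)`` over a bead indexing, i < j."""

    pairs: np.ndarray          # (M, 2) int
    distances: np.ndarray      # (M,) Å, native reference distances
    cutoff: float
    min_seq_sep: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}


@dataclass
class ResidueSet:
    """An ordered, duplicate-free selection of residues."""

    ids: list[ResidueId]
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise SelectionError("duplicate residue ids in set")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in set(self.ids)

    def union(self, other: "ResidueSet", label: str | None = None) -> "ResidueSet":
        ids = list(self.ids) + [r for r in other.ids if r not in set(self.ids)]
        return ResidueSet(ids, label or self.label)

    def indices_in(self, trace: Sequence[tuple[ResidueId, np.ndarray]]) -> np.ndarray:
        """Bead indices of this set within a Cα trace (order of the trace)."""
        lookup = {rid: i for i, (rid, _p) in enumerate(trace)}
        missing = [r for r in self.ids if r not in lookup]
        if missing:
            raise SelectionError(f"residues not in trace: {missing[:5]}"
                                 + ("..." if len(missing) > 5 else ""))
        return np.array(sorted(lookup[r] for r in self.ids), dtype=np.int64)

    def to_tsv(self, path: str | Path, structure: Structure | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresnum\ticode\tresname\tlabel\n")
            for cid, num, icode in self.ids:
                name = ""
                if structure is not None:
                    name = structure.residue((cid, num, icode)).name
                fh.write(f"{cid}\t{num}\t{icode}\t{name}\t{self.label}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueSet":
        ids: list[ResidueId] = []
        label = "custom"
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chain\t"):
                raise SelectionError(f"{path}: not a residue-set TSV")
            for line in fh:
                if not line.strip():
                    continue
                cid, num, icode, _name, label = line.rstrip("\n").split("\t")
                ids.append((cid, int(num), icode))
        return cls(ids, label)


def _atoms_by_residue(structure: Structure, chains: Sequence[str] | None = None
                      ) -> tuple[np.ndarray, np.ndarray, list[ResidueId]]:
    coords: list[np.ndarray] = []
    owner: list[int] = []
    rids: list[ResidueId] = []
    for cid, res in structure.iter_residues(chains):
        if res.hetero:
            continue
        rids.append((cid, res.number, res.icode))
        for a in res.atoms:
            coords.append(a.pos)
            owner.append(len(rids) - 1)
    return (np.array(coords, dtype=float).reshape(-1, 3),
            np.array(owner, dtype=np.int64), rids)


# ---------------------------------------------------------------------------
# Native contacts
# ---------------------------------------------------------------------------

def native_contacts(ca_coords: np.ndarray,
                    cutoff: float = CONTACT_CUTOFF,
                    min_seq_sep: int = MIN_SEQ_SEP,
                    chain_index: np.ndarray | None = None) -> ContactList:
    """All bead pairs within *cutoff* Å, excluding near neighbours in sequence.

    Pairs on the same chain must be separated by at least *min_seq_sep* in
    index; pairs on different chains (per *chain_index*) are kept at any
    separation.  Reference distances are stored for the Gō potentials and
    for d_rms.
    """
    ca_coords = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    n = len(ca_coords)
    if n < 2:
        raise SelectionError("need at least 2 beads")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if chain_index is None:
        chain_index = np.zeros(n, dtype=np.int64)
    chain_index = np.asarray(chain_index)
    if chain_index.shape != (n,):
        raise ValueError("chain_index length mismatch")

    tree = cKDTree(ca_coords)
    raw = tree.query_pairs(cutoff, output_type="ndarray")  # i < j, strict <? (<=)
    # cKDTree.query_pairs uses strict < r by default in older versions; be
    # explicit about the inclusive boundary by re-checking distances.
    if len(raw) == 0:
        raw = raw.reshape(0, 2)
    d = np.linalg.norm(ca_coords[raw[:, 0]] - ca_coords[raw[:, 1]], axis=1)
    # add any pairs exactly at the cutoff that a strict query might drop
    keep = d <= cutoff + 1e-12
    raw, d = raw[keep], d[keep]
    same = chain_index[raw[:, 0]] == chain_index[raw[:, 1]]
    sep_ok = (raw[:, 1] - raw[:, 0]) >= min_seq_sep
    mask = ~same | sep_ok
    pairs, dist = raw[mask], d[mask]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return ContactList(pairs[order], dist[order], cutoff, min_seq_sep)


# ---------------------------------------------------------------------------
# Pocket selection
# ---------------------------------------------------------------------------

def pocket_residues(structure: Structure,
                    ligand_atoms: Sequence,
                    expansion: float = POCKET_EXPANSION,
                    chains: Sequence[str] | None = None,
                    label: str = "pocket") -> ResidueSet:
    """Residues with ≥ 1 atom within *expansion* Å of ≥ 1 ligand atom.

    *ligand_atoms* may be Atom objects or raw coordinates.  On Cα-only
    models this naturally degenerates to a Cα–ligand distance criterion with
    the same cutoff.
    """
    if len(ligand_atoms) == 0:
        raise ValueError("empty ligand atom list")
    if expansion <= 0:
        raise ValueError("expansion must be positive")
    lig = np.array([a.pos if hasattr(a, "pos") else np.asarray(a, dtype=float)
                    for a in ligand_atoms], dtype=float).reshape(-1, 3)
    coords, owner, rids = _atoms_by_residue(structure, chains)
    if len(coords) == 0:
        return ResidueSet([], label)
    tree = cKDTree(lig)
    dmin, _ = tree.query(coords, k=1)
    hit = np.zeros(len(rids), dtype=bool)
    np.logical_or.at(hit, owner[dmin <= expansion + 1e-12], True)
    ids = [rid for rid, h in zip(rids, hit) if h]
    return ResidueSet(ids, label)


# ---------------------------------------------------------------------------
# Interface selection
# ---------------------------------------------------------------------------

def interface_residues(structure: Structure,
                       group_a: Sequence[str],
                       group_b: Sequence[str],
                       cutoff: float = INTERFACE_CUTOFF,
                       label: str = "interface") -> ResidueSet:
    """Residues of *group_a* with ≥ 1 atom within *cutoff* Å of any *group_b* atom."""
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise SelectionError("chain groups must be non-empty")
    if ga & gb:
        raise SelectionError(f"chain groups overlap: {sorted(ga & gb)}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords_a, owner_a, rids_a = _atoms_by_residue(structure, sorted(ga))
    coords_b, _owner_b, _rids_b = _atoms_by_residue(structure, sorted(gb))
    if len(coords_a) == 0 or len(coords_b) == 0:
        return ResidueSet([], label)
    tree = cKDTree(coords_b)
    dmin, _ = tree.query(coords_a, k=1)
    hit = np.zeros(len(rids_a), dtype=bool)
    np.logical_or.at(hit, owner_a[dmin <= cutoff + 1e-12], True)
    ids = [rid for rid, h in zip(rids_a, hit) if h]
    return ResidueSet(ids, label)


def junction_interface_residues(structure: Structure,
                                mat_chains: Sequence[str],
                                linker_chains: Sequence[str],
                                partner_mat_chains: Sequence[str],
                                cutoff: float = INTERFACE_CUTOFF) -> ResidueSet:
    """The junction interface set used for dynamics: residues of one enzyme
    tetramer contacting the cross-linker chains, united with its residues
    contacting the adjacent tetramer.
    """
    vs_linker = interface_residues(structure, mat_chains, linker_chains, cutoff)
    vs_partner = interface_residues(structure, mat_chains, partner_mat_chains, cutoff)
    return vs_linker.union(vs_partner, label="interface")


# ---------------------------------------------------------------------------
# Mapping selections between structures
# ---------------------------------------------------------------------------

def map_residue_set(residue_set: ResidueSet,
                    source: Structure,
                    target: Structure,
                    pairing: RigidTransform | Mapping[ResidueId, ResidueId]
                    | Callable[[ResidueId], ResidueId],
                    max_dist: float = 3.0) -> ResidueSet:
    """Transfer a residue selection from *source* onto *target*.

    *pairing* is either an explicit residue-id map (dict or callable), or a
    RigidTransform superposing source onto target, in which case each
    selected source Cα is matched to the nearest target Cα (must fall within
    *max_dist* Å).
    """
    if isinstance(pairing, RigidTransform):
        trace_t = extract_ca(target)
        if not trace_t:
            raise SelectionError("target has no Cα atoms")
        coords_t = np.array([p for _r, p in trace_t])
        tree = cKDTree(coords_t)
        ids: list[ResidueId] = []
        unmapped: list[ResidueId] = []
        for rid in residue_set:
            ca = source.residue(rid).atom("CA")
            if ca is None:
                unmapped.append(rid)
                continue
            d, i = tree.query(pairing.apply(ca.pos))
            if d > max_dist:
                unmapped.append(rid)
            else:
                ids.append(trace_t[int(i)][0])
        if unmapped:
            raise SelectionError(f"unmapped residues: {unmapped}")
        return ResidueSet(ids, residue_set.label)

    mapper = pairing if callable(pairing) else pairing.__getitem__
    ids, unmapped = [], []
    for rid in residue_set:
        try:
            tgt = mapper(rid)
            target.residue(tgt)  # must resolve
            ids.append(tgt)
        except (KeyError, SelectionError):
            unmapped.append(rid)
    if unmapped:
        raise SelectionError(f"unmapped residues: {unmapped}")
    return ResidueSet(ids, residue_set.label)
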