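"""Atomic structure I/O, Cα extraction and rigid-body superposition.

Structures are held in a small chain → residue → atom hierarchy that keeps
author residue numbering (with insertion codes) from the input file, since
the literature on the SAMase–MAT system refers to residues such as Asp132 in
author numbering.  Parsing and writing of PDB / mmCIF files is delegated to
gemmi; everything downstream works on plain numpy coordinates in Å.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueId",
    "RigidTransform",
    "StructIOError",
    "ParseError",
    "EmptyStructureError",
    "SelectionError",
    "DegenerateGeometryError",
    "read_structure",
    "write_structure",
    "write_multi_model",
    "extract_ca",
    "superpose",
]

# Residue names never treated as polymer residues when pulling Cα traces.
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructIOError(Exception):
    """Base error for structure I/O and geometry operations."""


class ParseError(StructIOError):
    pass


class EmptyStructureError(StructIOError):
    pass


class SelectionError(StructIOError):
    pass


class DegenerateGeometryError(StructIOError):
    pass


ResidueId = tuple[str, int, str]  # (chain id, author residue number, insertion code)


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise StructIOError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    """Hierarchical atomic model: chains → residues → atoms (coordinates in Å)."""

    chains: list[Chain] = field(default_factory=list)
    name: str = ""

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(f"chain {chain_id!r} not found (have {self.chain_ids})")

    def iter_residues(self, chains: Sequence[str] | None = None) -> Iterator[tuple[str, Residue]]:
        for c in self.chains:
            if chains is not None and c.id not in chains:
                continue
            for r in c.residues:
                yield c.id, r

    def residue(self, rid: ResidueId) -> Residue:
        chain_id, number, icode = rid
        for r in self.chain(chain_id).residues:
            if r.number == number and r.icode == icode:
                return r
        raise SelectionError(f"residue {rid} not found")

    def ligand_atoms(self, resnames: Iterable[str]) -> list[Atom]:
        """All atoms of HETATM residues whose name is in *resnames* (waters excluded)."""
        wanted = {n.upper() for n in resnames}
        out: list[Atom] = []
        for _cid, res in self.iter_residues():
            if res.name.upper() in wanted and res.name.upper() not in _WATER_NAMES:
                out.extend(res.atoms)
        return out

    def atom_coords(self, chains: Sequence[str] | None = None,
                    include_hetero: bool = False) -> np.ndarray:
        pts = [a.pos for _cid, r in self.iter_residues(chains)
               for a in r.atoms if include_hetero or not r.hetero]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _c, r in self.iter_residues())

    def subset(self, chains: Sequence[str]) -> "Structure":
        missing = [c for c in chains if c not in self.chain_ids]
        if missing:
            raise SelectionError(f"chains {missing} not found")
        return Structure(chains=[c for c in self.chains if c.id in chains], name=self.name)

    def transformed(self, t: "RigidTransform") -> "Structure":
        new_chains = []
        for c in self.chains:
            rs = []
            for r in c.residues:
                atoms = [Atom(a.name, a.element, t.apply(a.pos), a.occupancy, a.b_iso)
                         for a in r.atoms]
                rs.append(Residue(r.number, r.name, atoms, r.icode, r.hetero))
            new_chains.append(Chain(c.id, rs))
        return Structure(chains=new_chains, name=self.name)


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t with R a rotation matrix (det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise StructIOError(f"rotation not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise StructIOError("rotation is improper (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying *other* first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def power(self, k: int) -> "RigidTransform":
        if k < 0:
            return self.inverse().power(-k)
        out = RigidTransform.identity()
        for _ in range(k):
            out = self.compose(out)
        return out


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _dedup_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer for each atom name."""
    best: dict[str, gemmi.Atom] = {}
    for a in res:
        prev = best.get(a.name)
        if prev is None or a.occ > prev.occ:
            best[a.name] = a
    # preserve file order
    seen: set[str] = set()
    out = []
    for a in res:
        if a.name not in seen and best[a.name] is a:
            out.append(a)
            seen.add(a.name)
        elif a.name not in seen:
            out.append(best[a.name])
            seen.add(a.name)
    return out


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is kept.  Alternate locations are collapsed to the
    highest-occupancy conformer.  HETATM ligands are retained (flagged
    ``hetero``) and retrievable via :meth:`Structure.ligand_atoms`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt not in {"pdb", "mmcif", "cif", "auto"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in {"mmcif", "cif"}:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with line info
        raise ParseError(f"{path}: {exc}") from exc

    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise EmptyStructureError(f"{path}: no atoms in first model")

    chains: list[Chain] = []
    for ch in st[0]:
        residues = []
        for res in ch:
            atoms = [Atom(a.name, a.element.name,
                          np.array([a.pos.x, a.pos.y, a.pos.z]),
                          a.occ, a.b_iso)
                     for a in _dedup_altlocs(res)]
            residues.append(Residue(number=res.seqid.num, name=res.name, atoms=atoms,
                                    icode=(res.seqid.icode or "").strip(),
                                    hetero=(res.het_flag == "H")))
        chains.append(Chain(ch.name, residues))
    return Structure(chains=chains, name=path.stem)


def _to_gemmi(structure: Structure, model_num: int = 1) -> gemmi.Model:
    model = gemmi.Model(model_num)
    for chain in structure.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or "X")
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    return model


def _write_gemmi(st: gemmi.Structure, path: Path, format: str) -> None:
    fmt = format.lower()
    if fmt == "auto":
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in {"cif", "mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    st = gemmi.Structure()
    st.name = structure.name or path.stem
    st.add_model(_to_gemmi(structure))
    st.setup_entities()
    _write_gemmi(st, path, format)


def write_multi_model(structures: Sequence[Structure], path: str | Path,
                      format: str = "pdb") -> None:
    """Write several structures (filament copies, trajectory frames) as models."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    for i, s in enumerate(structures, start=1):
        st.add_model(_to_gemmi(s, i))
    st.setup_entities()
    _write_gemmi(st, path, format)


# ---------------------------------------------------------------------------
# Cα extraction
# ---------------------------------------------------------------------------

def extract_ca(structure: Structure, chains: Sequence[str] | None = None
               ) -> list[tuple[ResidueId, np.ndarray]]:
    """Ordered Cα trace: one ``((chain, resnum, icode), xyz)`` entry per
    polymer residue that has a CA atom, in chain-then-residue order.

    Ligands (HETATM) and waters are excluded; residues lacking a CA atom are
    skipped with a warning.
    """
    if not structure.chains:
        raise EmptyStructureError("empty structure")
    if chains is not None:
        missing = [c for c in chains if c not in structure.chain_ids]
        if missing:
            raise SelectionError(f"chains {missing} not in structure {structure.chain_ids}")
    out: list[tuple[ResidueId, np.ndarray]] = []
    for cid, res in structure.iter_residues(chains):
        if res.hetero or res.name.upper() in _WATER_NAMES:
            continue
        ca = res.atom("CA")
        if ca is None:
            logger.warning("residue %s %s%d%s has no CA atom; skipped",
                           res.name, cid, res.number, res.icode)
            continue
        out.append(((cid, res.number, res.icode), ca.pos))
    return out


def ca_array(trace: Sequence[tuple[ResidueId, np.ndarray]]) -> np.ndarray:
    """Stack a Cα trace into an (N, 3) coordinate array."""
    return np.array([p for _rid, p in trace], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of *mobile* onto *reference* (Kabsch).

    Returns the proper rigid transform T minimising ‖T(mobile) − reference‖
    and the RMSD of the residuals after applying it.  Reflections are
    corrected by flipping the sign of the smallest singular vector.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise StructIOError(f"coordinate shapes differ: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    # Degenerate when points are (nearly) collinear or coincident: the second
    # singular value of the centered set vanishes and the rotation about the
    # line is unconstrained.
    s_ref = np.linalg.svd(y, compute_uv=False)
    if s_ref[1] <= 1e-8 * max(1.0, s_ref[0]):
        raise DegenerateGeometryError("reference points are collinear or coincident")

    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    t = RigidTransform(rot, trans)
    resid = t.apply(mobile) - reference
    rmsd = math.sqrt((resid ** 2).sum() / n)
    return t, rmsd
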