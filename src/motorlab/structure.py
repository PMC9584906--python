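"""Rigid-body domain superposition and core-domain displacement.

SLC26 transporters (prestin included) split each protomer into a *core*
domain (TM1-4, 8-11) and a *gate* domain (TM5-7, 12-14); transport-like
motion is an elevator-style rigid-body slide of the core against the gate.
To measure that motion between two structures, the models are superimposed
on gate-domain Calpha atoms (removing the shared frame) and the residual
displacement of a reference atom in the core (by default S398 Calpha, at the
centre of TM10) is reported in Angstrom.

Superposition is least-squares rigid (Kabsch, via Biopython's
SVDSuperimposer); reflections are excluded, so the rotation determinant is
always +1.  Residue correspondence between models is by residue number
(optionally through a chain mapping supplied by the caller) — no sequence
alignment is attempted across differently numbered models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .mdbinding import AtomRecord

__all__ = [
    "StructureModel",
    "DomainSelection",
    "Superposition",
    "superpose",
    "domain_displacement",
    "ligand_contacts",
    "read_structure",
]


@dataclass
class StructureModel:
    """A static atomic model (one conformation)."""

    atoms: list                       # AtomRecord list
    hetero: list = field(default_factory=list)  # AtomRecord list (ions, ligands, lipids)
    source: str = ""

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, residue_number, atom_name) keys in model")

    def atom_map(self) -> dict:
        return {a.key: np.asarray(a.xyz, dtype=float) for a in self.atoms}

    def find_atom(self, chain: str, residue_number: int, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if a.key == (chain, residue_number, atom_name):
                return a
        raise KeyError(f"atom {chain}:{residue_number}:{atom_name} not found")


@dataclass
class DomainSelection:
    """Residue intervals per domain: {'core': [(lo, hi), ...], 'gate': [...]}.

    Helix-to-residue assignments are configuration: supply the intervals that
    define the core and gate domains for the numbering scheme of your models.
    """

    domains: dict

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("empty domain selection")
        seen: dict = {}
        for name, ranges in self.domains.items():
            if not ranges:
                raise ValueError(f"domain {name!r} has no residue ranges")
            for lo, hi in ranges:
                for r in range(lo, hi + 1):
                    if r in seen and seen[r] != name:
                        raise ValueError(f"residue {r} in both {seen[r]!r} and {name!r}")
                    seen[r] = name

    def residues(self, domain: str) -> set:
        return {
            r for lo, hi in self.domains[domain] for r in range(lo, hi + 1)
        }


@dataclass
class Superposition:
    rotation: np.ndarray     # 3x3, orthonormal, det +1
    translation: np.ndarray  # Angstrom
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _paired_ca(
    mobile: StructureModel,
    reference: StructureModel,
    residues: Iterable[int],
    chain_map: Optional[dict] = None,
    atom_name: str = "CA",
):
    """Coordinates of Calpha pairs present in both models for the residues."""
    ref_map = reference.atom_map()
    mob_map = mobile.atom_map()
    residues = set(residues)
    mob_pts, ref_pts = [], []
    for key, xyz in mob_map.items():
        chain, resnum, aname = key
        if aname != atom_name or resnum not in residues:
            continue
        ref_chain = (chain_map or {}).get(chain, chain)
        ref_key = (ref_chain, resnum, aname)
        if ref_key in ref_map:
            mob_pts.append(xyz)
            ref_pts.append(ref_map[ref_key])
    return np.asarray(mob_pts), np.asarray(ref_pts)


def _collinear(pts: np.ndarray, tol: float = 1e-8) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    residues: Iterable[int],
    chain_map: Optional[dict] = None,
) -> Superposition:
    """Least-squares rigid superposition of mobile onto reference Calphas.

    Pairs Calpha atoms by (chain via ``chain_map``, residue number) over the
    given residues.  Requires >= 3 non-collinear pairs.  The returned
    transform maps mobile coordinates into the reference frame.
    """
    mob, ref = _paired_ca(mobile, reference, residues, chain_map)
    if len(mob) < 3:
        raise ValueError(f"need >= 3 paired Calpha atoms, found {len(mob)}")
    if _collinear(mob) or _collinear(ref):
        raise ValueError("selection is collinear; superposition is degenerate")
    sup = SVDSuperimposer()
    sup.set(ref, mob)
    sup.run()
    rot, tran = sup.get_rotran()
    # SVDSuperimposer convention: ref ~ mob @ rot + tran (row vectors)
    rotation = np.asarray(rot, dtype=float).T
    translation = np.asarray(tran, dtype=float)
    assert np.linalg.det(rotation) > 0
    return Superposition(
        rotation=rotation,
        translation=translation,
        rmsd=float(sup.get_rms()),
        n_atoms=len(mob),
    )


def domain_displacement(
    model_a: StructureModel,
    model_b: StructureModel,
    gate_residues: Iterable[int],
    reference_atom: tuple = ("A", 398, "CA"),
    chain_map: Optional[dict] = None,
) -> float:
    """Core displacement (A) after gate superposition, at a reference atom.

    ``model_a`` is superposed onto ``model_b`` using gate-domain Calpha
    atoms; the reported value is the distance between the transformed
    position of ``reference_atom`` in model_a and its position in model_b.
    The default reference atom is S398 Calpha (TM10 centre).
    """
    chain, resnum, aname = reference_atom
    sup = superpose(model_a, model_b, gate_residues, chain_map)
    a = np.asarray(model_a.find_atom(chain, resnum, aname).xyz, dtype=float)
    ref_chain = (chain_map or {}).get(chain, chain)
    b = np.asarray(model_b.find_atom(ref_chain, resnum, aname).xyz, dtype=float)
    moved = sup.apply(a[None, :])[0]
    return float(np.linalg.norm(moved - b))


def ligand_contacts(
    model: StructureModel,
    ligand_selector: str,
    targets: Sequence[tuple],
    cutoff: float = 5.0,
) -> list:
    """Distances from a hetero ligand to named target atoms.

    ``ligand_selector`` matches hetero residue names (e.g. "CL", "SAL");
    ``targets`` is a list of (chain, residue_number, atom_name).  Returns one
    record per (ligand atom, target): ``{"ligand", "target", "distance",
    "contact"}`` with ``contact`` true within ``cutoff`` Angstrom.
    """
    lig_atoms = [a for a in model.hetero if a.residue_name.strip().upper() == ligand_selector.upper()]
    if not lig_atoms:
        raise ValueError(f"ligand {ligand_selector!r} not found in model")
    out = []
    for lig in lig_atoms:
        lp = np.asarray(lig.xyz, dtype=float)
        for chain, resnum, aname in targets:
            t = np.asarray(model.find_atom(chain, resnum, aname).xyz, dtype=float)
            d = float(np.linalg.norm(lp - t))
            out.append(
                {
                    "ligand": lig.key,
                    "target": (chain, resnum, aname),
                    "distance": d,
                    "contact": d <= cutoff,
                }
            )
    return out


_HETERO_FLAG = True


def read_structure(path, model_index: int = 0, altloc: str = "A") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (gemmi backend).

    Hetero records (ions, ligands, waters, lipids) are separated from polymer
    atoms.  When alternate locations are present, altloc ``A`` (or blank) is
    taken.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[model_index]
    atoms, hetero = [], []
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            for atom in res:
                if atom.altloc not in ("", "\0", altloc):
                    continue
                rec = AtomRecord(
                    chain=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    atom_name=atom.name,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                (hetero if is_het else atoms).append(rec)
    return StructureModel(atoms=atoms, hetero=hetero, source=str(path))
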