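"""Anion-binding classification and electrostatic decomposition of MD frames.

Chloride occupancy of prestin's central anion pocket is read out per frame
from three distances of the nearest Cl- ion to the pocket probes:

    r1 : R399 Czeta     r2 : S396 Ogamma     r3 : S398 Ogamma

A frame is *bound* when 4 A < r1 < 10 A, 2 A < r2 < 6 A and 2 A < r3 < 6 A,
*unbound* when r1 > 15 A, r2 > 10 A and r3 > 10 A, and *intermediate*
otherwise (the two published windows do not tile distance space, so a third
class is needed to account for every frame).  A release event is the first
run of consecutive unbound frames; rebinding is the first bound frame after a
release.

The electrostatic side decomposes the bound ion's interaction with named atom
groups (e.g. the R399 side chain vs. the TM3/TM10 main-chain dipoles) by a
direct Coulomb sum over group atoms, with relative permittivity 1, no cutoff
and no periodic images:

    E_group = sum_i k_e q_i q_ion / r_i,   k_e = 332.0636 kcal*A/(mol*e^2).

Partial charges are those of the simulation force field, supplied as a
per-atom table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "TrajectoryFrame",
    "BindingDistances",
    "ChargeSet",
    "TrajectoryClassification",
    "PROBE_ATOMS",
    "COULOMB_CONSTANT",
    "BOUND_WINDOW",
    "UNBOUND_MIN",
    "binding_distances",
    "classify_frame",
    "classify_trajectory",
    "coulomb_decomposition",
    "compare_contributions",
    "read_multimodel_pdb",
    "read_charge_table",
]

#: Coulomb constant in kcal*A/(mol*e^2) (Amber convention).
COULOMB_CONSTANT = 332.0636

#: (low, high) exclusive bounds per distance for the bound class, Angstrom.
BOUND_WINDOW = ((4.0, 10.0), (2.0, 6.0), (2.0, 6.0))
#: exclusive lower bounds per distance for the unbound class, Angstrom.
UNBOUND_MIN = (15.0, 10.0, 10.0)

#: probe atoms keyed by distance name: (residue_number, atom_name).
PROBE_ATOMS = {"r1": (399, "CZ"), "r2": (396, "OG"), "r3": (398, "OG")}

ION_CHARGE = -1.0  # Cl- in elementary charges
CLASH_DISTANCE = 0.1  # Angstrom


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    xyz: tuple

    @property
    def key(self) -> tuple:
        return (self.chain, self.residue_number, self.atom_name)


@dataclass
class TrajectoryFrame:
    """One MD snapshot: labelled protein atoms plus Cl- ion positions."""

    atoms: list
    ions: list           # list of (x, y, z) in Angstrom
    time: float = 0.0    # ns

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.xyz):
                raise ValueError(f"non-finite coordinates for atom {a.key}")
        for p in self.ions:
            if not all(math.isfinite(c) for c in p):
                raise ValueError("non-finite ion coordinates")

    def find_atom(self, residue_number: int, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if a.residue_number == residue_number and a.atom_name == atom_name:
                return a
        raise KeyError(f"probe atom {residue_number}:{atom_name} not found in frame")


@dataclass
class BindingDistances:
    r1: float
    r2: float
    r3: float
    ion_index: dict = field(default_factory=dict)  # distance name -> nearest ion index

    def as_tuple(self) -> tuple:
        return (self.r1, self.r2, self.r3)


def binding_distances(frame: TrajectoryFrame, probes: dict = PROBE_ATOMS) -> BindingDistances:
    """Nearest-ion distance to each probe atom (each probe independently)."""
    if not frame.ions:
        raise ValueError("frame contains no ions")
    ions = np.asarray(frame.ions, dtype=float)
    values = {}
    nearest = {}
    for name, (resnum, atom) in probes.items():
        p = np.asarray(frame.find_atom(resnum, atom).xyz, dtype=float)
        d = np.linalg.norm(ions - p, axis=1)
        i = int(np.argmin(d))
        values[name] = float(d[i])
        nearest[name] = i
    return BindingDistances(r1=values["r1"], r2=values["r2"], r3=values["r3"], ion_index=nearest)


def classify_frame(d: BindingDistances) -> str:
    """Three-way bound / unbound / intermediate call from (r1, r2, r3)."""
    r = d.as_tuple()
    if all(lo < x < hi for x, (lo, hi) in zip(r, BOUND_WINDOW)):
        return "bound"
    if all(x > m for x, m in zip(r, UNBOUND_MIN)):
        return "unbound"
    return "intermediate"


@dataclass
class TrajectoryClassification:
    labels: list
    times: list                      # ns, per frame
    counts: dict
    occupancy: dict                  # label -> fraction of frames
    release_time: Optional[float]    # ns, or None
    rebinding_events: list           # times (ns) of first bound frame after each release


def classify_trajectory(
    frames: Sequence[TrajectoryFrame],
    min_unbound_run: int = 1,
) -> TrajectoryClassification:
    """Classify a time-ordered trajectory and locate release/rebinding events.

    Release is the first frame of the first run of >= ``min_unbound_run``
    consecutive unbound frames; after each release, the next bound frame is a
    rebinding event (further releases after rebinding are detected the same
    way).
    """
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    times = [f.time for f in frames]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frames are not time-ordered")
    labels = [classify_frame(binding_distances(f)) for f in frames]
    counts = {lab: labels.count(lab) for lab in ("bound", "unbound", "intermediate")}
    n = len(labels)
    occupancy = {lab: c / n for lab, c in counts.items()}

    release_time: Optional[float] = None
    rebinding: list = []
    i = 0
    released = False
    while i < n:
        if not released:
            # search for a qualifying unbound run
            if labels[i] == "unbound":
                j = i
                while j < n and labels[j] == "unbound":
                    j += 1
                if j - i >= min_unbound_run:
                    if release_time is None:
                        release_time = times[i]
                    released = True
                    i = j
                    continue
                i = j
            else:
                i += 1
        else:
            if labels[i] == "bound":
                rebinding.append(times[i])
                released = False
            i += 1
    return TrajectoryClassification(
        labels=labels,
        times=times,
        counts=counts,
        occupancy=occupancy,
        release_time=release_time,
        rebinding_events=rebinding,
    )


@dataclass
class ChargeSet:
    """Per-atom partial charges (e) and named atom-group definitions.

    ``charges`` maps (chain, residue_number, atom_name) -> charge in e.
    ``groups`` maps a group name -> iterable of such keys.
    """

    charges: dict
    groups: dict = field(default_factory=dict)

    def validate_against(self, frame: TrajectoryFrame) -> None:
        present = {a.key for a in frame.atoms}
        for gname, keys in self.groups.items():
            for k in keys:
                if k not in self.charges:
                    raise KeyError(f"group {gname!r}: atom {k} has no charge")
                if k not in present:
                    raise KeyError(f"group {gname!r}: atom {k} not in frame")


def main_chain_dipole_group(frame: TrajectoryFrame, residue_numbers: Iterable[int]) -> list:
    """Backbone N, H(N), C, O atom keys of the given residues (Calpha excluded).

    These atoms carry the peptide-bond dipole in standard force fields and
    define a "main-chain dipole" group for the decomposition.
    """
    wanted = set(residue_numbers)
    names = {"N", "H", "HN", "C", "O"}
    return [a.key for a in frame.atoms if a.residue_number in wanted and a.atom_name in names]


def coulomb_decomposition(
    frame: TrajectoryFrame,
    charges: ChargeSet,
    groups: Optional[dict] = None,
    ion_index: int = 0,
    ion_charge: float = ION_CHARGE,
) -> dict:
    """Direct Coulomb sum of ion-group interactions, per group (kcal/mol).

    No cutoff, no periodic images, relative permittivity 1.  Atoms closer
    than 0.1 A to the ion are flagged as clashes but still summed.  Returns
    ``{group: {"energy": kcal/mol, "clashes": [atom keys]}}``.
    """
    groups = groups if groups is not None else charges.groups
    if not groups:
        raise ValueError("no groups given")
    ion = np.asarray(frame.ions[ion_index], dtype=float)
    coords = {a.key: np.asarray(a.xyz, dtype=float) for a in frame.atoms}
    out = {}
    for gname, keys in groups.items():
        e = 0.0
        clashes = []
        for k in keys:
            if k not in charges.charges:
                raise KeyError(f"group {gname!r}: atom {k} has no charge")
            if k not in coords:
                raise KeyError(f"group {gname!r}: atom {k} not in frame")
            r = float(np.linalg.norm(coords[k] - ion))
            if r < CLASH_DISTANCE:
                clashes.append(k)
                r = max(r, 1e-12)
            e += COULOMB_CONSTANT * charges.charges[k] * ion_charge / r
        out[gname] = {"energy": e, "clashes": clashes}
    return out


def compare_contributions(
    frames: Sequence[TrajectoryFrame],
    charges: ChargeSet,
    groups: Optional[dict] = None,
    bound_only: bool = True,
) -> list:
    """Mean +/- SD group energies over (bound) frames, ranked by mean.

    Returns a list of dicts ``{"group", "mean", "sd", "n"}`` sorted from most
    negative (most stabilizing) mean energy to least.  With no qualifying
    frames an empty list is returned.
    """
    groups = groups if groups is not None else charges.groups
    per_group: dict = {g: [] for g in groups}
    for frame in frames:
        if bound_only:
            d = binding_distances(frame)
            if classify_frame(d) != "bound":
                continue
            ion_i = d.ion_index["r1"]
        else:
            ion_i = 0
        dec = coulomb_decomposition(frame, charges, groups, ion_index=ion_i)
        for g, rec in dec.items():
            per_group[g].append(rec["energy"])
    table = []
    for g, vals in per_group.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        table.append({"group": g, "mean": float(arr.mean()), "sd": sd, "n": int(arr.size)})
    table.sort(key=lambda rec: rec["mean"])
    return table


# ---------------------------------------------------------------------------
# I/O: multi-model PDB trajectories and charge tables

ION_RESNAMES = {"CL", "CLA", "CL-"}


def read_multimodel_pdb(path) -> list:
    """Read a multi-model PDB (MODEL/ENDMDL records) as trajectory frames.

    Ions are recognised by residue name (CL / CLA / CL-).  Frame times are
    taken as the model index (caller may rescale by the frame interval).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    frames = []
    for mi, model in enumerate(st):
        atoms = []
        ions = []
        for chain in model:
            for res in chain:
                for atom in res:
                    xyz = (atom.pos.x, atom.pos.y, atom.pos.z)
                    if res.name.strip().upper() in ION_RESNAMES:
                        ions.append(xyz)
                    else:
                        atoms.append(
                            AtomRecord(
                                chain=chain.name,
                                residue_number=res.seqid.num,
                                residue_name=res.name,
                                atom_name=atom.name,
                                xyz=xyz,
                            )
                        )
        frames.append(TrajectoryFrame(atoms=atoms, ions=ions, time=float(mi)))
    if not frames:
        raise ValueError(f"no models found in {path}")
    return frames


def read_charge_table(path) -> dict:
    """Charge CSV (chain, resnum, resname, atomname, charge_e) -> key map."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"chain", "resnum", "atomname", "charge_e"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"charge table missing columns: {sorted(missing)}")
    return {
        (str(row.chain), int(row.resnum), str(row.atomname)): float(row.charge_e)
        for row in df.itertuples()
    }
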