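"""Synthetic inputs for every pipeline stage.

Each generator plants a known ground truth with the statistical structure the
corresponding analysis assumes, so parameter recovery and classification
accuracy can be tested end-to-end without any external data:

* capacitance-voltage sweeps from the two-state Boltzmann NLC function plus
  i.i.d. Gaussian capacitance noise;
* ion trajectories with bound / unbound / intermediate segments planted by
  construction of the three probe distances (release and rebinding events
  fall out of the segment order);
* alignments with planted per-column conservation of a template sequence;
* structure pairs differing by a rigid translation of a core selection with
  the gate fixed;
* single-site titration thermograms (delegated to :mod:`motorlab.itc`).

All generators take an explicit integer seed; the same spec and seed give
byte-identical output.  With zero noise each generator reproduces its
analytic model exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .consensus import AMINO_ACIDS, MSA
from .itc import BindingParams, TitrationSchedule, simulate_titration
from .mdbinding import AtomRecord, TrajectoryFrame
from .nlc import CapacitanceSweep, NLCParams, eval_nlc
from .structure import StructureModel

__all__ = [
    "SweepSpec",
    "TrajectorySpec",
    "AlignmentSpec",
    "gen_nlc_sweeps",
    "gen_trajectory",
    "gen_alignment",
    "gen_structure_pair",
    "gen_itc_heats",
    "write_sweeps_csv",
    "read_sweeps_csv",
    "write_msa_fasta",
    "write_trajectory_pdb",
    "write_labels_csv",
    "write_structure_pdb",
]


# ---------------------------------------------------------------------------
# Capacitance sweeps


@dataclass(frozen=True)
class SweepSpec:
    """Recipe for a batch of synthetic capacitance-voltage sweeps."""

    params: NLCParams
    v_min: float = -150.0   # mV
    v_max: float = 150.0    # mV
    v_step: float = 5.0     # mV
    noise_sd: float = 0.02  # pF
    n_sweeps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.v_min < self.v_max:
            raise ValueError("v_min must be < v_max")
        if self.v_step <= 0:
            raise ValueError("v_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")

    @property
    def voltages(self) -> np.ndarray:
        n = int(math.floor((self.v_max - self.v_min) / self.v_step + 1e-9)) + 1
        return self.v_min + self.v_step * np.arange(n)


def gen_nlc_sweeps(spec: SweepSpec) -> list:
    """Generate sweeps: C_m(V) = Boltzmann NLC + Gaussian noise."""
    V = spec.voltages
    clean = eval_nlc(spec.params, V)
    rng = np.random.default_rng(spec.seed)
    sweeps = []
    for i in range(spec.n_sweeps):
        noise = rng.normal(0.0, spec.noise_sd, size=V.shape) if spec.noise_sd > 0 else 0.0
        sweeps.append(CapacitanceSweep(V=V.copy(), C_m=clean + noise, cell_id=f"sim_{i:03d}"))
    return sweeps


# ---------------------------------------------------------------------------
# Ion trajectories
#
# Minimal collinear probe geometry: the ion moves on the y-axis, the probes
# sit at fixed positions so all three distances are monotone functions of the
# ion's y coordinate.  Per label the y range is chosen so the (r1, r2, r3)
# triple lands strictly inside the corresponding classification window
# (bound / unbound) or strictly outside both (intermediate).

_PROBE_GEOMETRY = (
    AtomRecord("A", 399, "ARG", "CZ", (0.0, -5.0, 0.0)),
    AtomRecord("A", 396, "SER", "OG", (1.0, 0.0, 0.0)),
    AtomRecord("A", 398, "SER", "OG", (-1.0, 0.0, 0.0)),
)

# y ranges per label: r1 = y + 5, r2 = r3 = sqrt(1 + y^2)
_LABEL_Y_RANGE = {
    "bound": (2.1, 4.4),         # r1 in (7.1, 9.4), r2 in (2.3, 4.5)
    "unbound": (10.6, 14.0),     # r1 in (15.6, 19.0), r2 in (10.6, 14.0)
    "intermediate": (6.1, 9.9),  # r1 in (11.1, 14.9), r2 in (6.2, 9.9)
}


@dataclass(frozen=True)
class TrajectorySpec:
    """Ordered (label, n_frames) segments at a fixed frame interval (ns)."""

    segments: tuple
    frame_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        segs = tuple((str(lab), int(n)) for lab, n in self.segments)
        if not segs:
            raise ValueError("segment list is empty")
        for lab, n in segs:
            if lab not in _LABEL_Y_RANGE:
                raise ValueError(f"unknown segment label {lab!r}")
            if n < 0:
                raise ValueError("segment frame counts must be >= 0")
        if sum(n for _, n in segs) < 1:
            raise ValueError("trajectory needs at least 1 frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "segments", segs)


def gen_trajectory(spec: TrajectorySpec):
    """Generate frames plus the planted per-frame labels.

    Returns ``(frames, labels)``.  Frame k (0-based) carries time
    k * frame_interval, so a trajectory of 153 bound frames followed by
    unbound frames at 1 ns/frame has its first unbound frame — the release
    event — at t = 153 ns.
    """
    rng = np.random.default_rng(spec.seed)
    frames: list = []
    labels: list = []
    k = 0
    for lab, n in spec.segments:
        lo, hi = _LABEL_Y_RANGE[lab]
        ys = rng.uniform(lo, hi, size=n)
        for y in ys:
            frames.append(
                TrajectoryFrame(
                    atoms=list(_PROBE_GEOMETRY),
                    ions=[(0.0, float(y), 0.0)],
                    time=k * spec.frame_interval,
                )
            )
            labels.append(lab)
            k += 1
    return frames, labels


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class AlignmentSpec:
    """Alignment with planted per-position template-residue conservation."""

    target_sequence: str
    per_position_conservation: tuple
    n_sequences: int = 100
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        seq = str(self.target_sequence).upper()
        if not seq or any(c not in AMINO_ACIDS for c in seq):
            raise ValueError("target_sequence must be a non-empty amino-acid string")
        cons = tuple(float(c) for c in self.per_position_conservation)
        if len(cons) != len(seq):
            raise ValueError("per_position_conservation length must match target")
        if any(not 0.0 <= c <= 1.0 for c in cons):
            raise ValueError("conservation values must lie in [0, 1]")
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        object.__setattr__(self, "target_sequence", seq)
        object.__setattr__(self, "per_position_conservation", cons)


def _alternative_residue(res: str) -> str:
    """Fixed planted alternative: the next residue in alphabet order."""
    i = AMINO_ACIDS.index(res)
    return AMINO_ACIDS[(i + 1) % len(AMINO_ACIDS)]


def gen_alignment(spec: AlignmentSpec) -> MSA:
    """Generate an MSA whose first row is the template.

    At each position, each other row carries the template residue with the
    planted conservation probability and a fixed alternative residue
    otherwise (binomial sampling); cells are then gapped at ``gap_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(spec.target_sequence)
    n_others = spec.n_sequences - 1
    rows = [list(spec.target_sequence)]
    others = [[None] * L for _ in range(n_others)]
    for j, (t_res, c) in enumerate(
        zip(spec.target_sequence, spec.per_position_conservation)
    ):
        alt = _alternative_residue(t_res)
        keep = rng.random(n_others) < c
        gap = rng.random(n_others) < spec.gap_rate
        for i in range(n_others):
            others[i][j] = "-" if gap[i] else (t_res if keep[i] else alt)
    rows.extend("".join(r) for r in others)
    rows[0] = "".join(rows[0])
    ids = ["target"] + [f"seq_{i:04d}" for i in range(n_others)]
    return MSA(sequences=rows, ids=ids, target_id="target")


# ---------------------------------------------------------------------------
# Structure pairs


def _toy_structure(n_gate: int = 8, n_core: int = 8, seed: int = 0) -> StructureModel:
    """Toy model: gate residues 1..n_gate, core residues 101..100+n_core.

    Calpha atoms on a jittered helix-like path — non-collinear by
    construction so the gate is always a valid superposition selection.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_gate):
        theta = 2.0 * math.pi * i / 3.6
        xyz = (5.0 * math.cos(theta), 5.0 * math.sin(theta), 1.5 * i)
        xyz = tuple(c + rng.normal(0, 0.2) for c in xyz)
        atoms.append(AtomRecord("A", i + 1, "ALA", "CA", xyz))
    for i in range(n_core):
        theta = 2.0 * math.pi * i / 3.6 + 0.5
        xyz = (15.0 + 5.0 * math.cos(theta), 5.0 * math.sin(theta), 1.5 * i)
        xyz = tuple(c + rng.normal(0, 0.2) for c in xyz)
        atoms.append(AtomRecord("A", 101 + i, "ALA", "CA", xyz))
    return StructureModel(atoms=atoms, source="synthetic")


def gen_structure_pair(
    shift_vector: Sequence[float],
    core_selection: Optional[Sequence[int]] = None,
    n_gate: int = 8,
    n_core: int = 8,
    seed: int = 0,
):
    """A structure and a copy with the core selection rigidly translated.

    Gate atoms are identical between the two models; every atom whose
    residue number is in ``core_selection`` (default: the toy core residues
    101..100+n_core) is translated by ``shift_vector`` (Angstrom).
    Returns ``(reference, shifted)``.
    """
    shift = np.asarray(shift_vector, dtype=float)
    if shift.shape != (3,):
        raise ValueError("shift_vector must be a 3-vector")
    ref = _toy_structure(n_gate=n_gate, n_core=n_core, seed=seed)
    if core_selection is None:
        core_selection = range(101, 101 + n_core)
    core = set(int(r) for r in core_selection)
    if not core & {a.residue_number for a in ref.atoms}:
        raise ValueError("core selection matches no atoms")
    moved = [
        AtomRecord(
            a.chain,
            a.residue_number,
            a.residue_name,
            a.atom_name,
            tuple(np.asarray(a.xyz) + shift) if a.residue_number in core else a.xyz,
        )
        for a in ref.atoms
    ]
    return ref, StructureModel(atoms=moved, source="synthetic-shifted")


# ---------------------------------------------------------------------------
# ITC thermograms


def gen_itc_heats(
    schedule: TitrationSchedule,
    params: BindingParams,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Synthetic per-injection heats; thin wrapper over the forward model."""
    return simulate_titration(schedule, params, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# Plain-text writers (CSV / FASTA / PDB)


def write_sweeps_csv(sweeps, handle) -> None:
    handle.write("sweep_id,V_mV,Cm_pF\n")
    for sw in sweeps:
        for v, c in zip(sw.V, sw.C_m):
            handle.write(f"{sw.cell_id},{v:.6g},{c:.9g}\n")


def read_sweeps_csv(path) -> list:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("sweep_id", sort=False):
        out.append(
            CapacitanceSweep(
                V=grp["V_mV"].to_numpy(float),
                C_m=grp["Cm_pF"].to_numpy(float),
                cell_id=str(sid),
            )
        )
    return out


def write_msa_fasta(msa: MSA, handle) -> None:
    for sid, seq in zip(msa.ids, msa.sequences):
        handle.write(f">{sid}\n")
        for i in range(0, len(seq), 60):
            handle.write(seq[i : i + 60] + "\n")


def _pdb_atom_line(serial: int, a: AtomRecord, hetatm: bool = False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
    x, y, z = a.xyz
    element = a.atom_name.strip()[0]
    return (
        f"{record}{serial:>5d} {name:<4s}{a.residue_name:>4s} {a.chain:1s}"
        f"{a.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_trajectory_pdb(frames, handle) -> None:
    """Multi-model PDB: MODEL/ENDMDL per frame, Cl- ions as HETATM CL."""
    for mi, frame in enumerate(frames, start=1):
        handle.write(f"MODEL     {mi:>4d}\n")
        serial = 0
        for a in frame.atoms:
            serial += 1
            handle.write(_pdb_atom_line(serial, a))
        for xyz in frame.ions:
            serial += 1
            ion = AtomRecord("I", 999, "CL", "CL", tuple(xyz))
            handle.write(_pdb_atom_line(serial, ion, hetatm=True))
        handle.write("ENDMDL\n")
    handle.write("END\n")


def write_labels_csv(frames, labels, handle) -> None:
    handle.write("frame,time_ns,label\n")
    for i, (frame, lab) in enumerate(zip(frames, labels)):
        handle.write(f"{i},{frame.time:.6g},{lab}\n")


def write_structure_pdb(model: StructureModel, handle) -> None:
    serial = 0
    for a in model.atoms:
        serial += 1
        handle.write(_pdb_atom_line(serial, a))
    for a in model.hetero:
        serial += 1
        handle.write(_pdb_atom_line(serial, a, hetatm=True))
    handle.write("END\n")
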