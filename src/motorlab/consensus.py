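"""Consensus-mutagenesis thermostabilization design.

Membrane proteins that are too unstable for structural work can often be
rescued by replacing poorly conserved residues with the residue most common
at that position across an alignment of homologues ("consensus mutagenesis").
Given a multiple sequence alignment containing the design template, this
module computes per-position conservation of the template residue, applies a
conservation threshold to decide which positions to substitute (optionally
exempting a preserve set, e.g. residues lining a ligand-binding site), and
sweeps a range of thresholds to produce a family of candidate constructs.

Coordinates are 1-based positions in the ungapped template sequence
throughout, so a preserve entry like "S396" refers to template residue 396.

Conservation of the template residue at a position is computed over the
non-gap symbols of the other alignment rows at that column, with the
template's own residue included in both numerator and denominator.  A residue
unique to the template therefore has conservation 1/(n+1) > 0, which makes a
threshold of 0 the identity design.  The threshold test is strict
("conserved in MORE than"): a position is kept when its conservation exceeds
the threshold, and mutated on a tie.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

__all__ = [
    "MSA",
    "PositionConservation",
    "ConservationProfile",
    "ConsensusDesign",
    "read_msa",
    "column_conservation",
    "design_construct",
    "threshold_sweep",
    "percent_identity",
    "parse_preserve_list",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.")


@dataclass
class MSA:
    """Aligned sequences with a designated design-template row."""

    sequences: list[str]
    ids: list[str]
    target_id: str

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids differ in length")
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.target_id not in self.ids:
            raise ValueError(f"target_id {self.target_id!r} not in alignment")
        if all(c in GAP_CHARS for c in self.target_row):
            raise ValueError("target row is all gaps")

    @property
    def target_index(self) -> int:
        return self.ids.index(self.target_id)

    @property
    def target_row(self) -> str:
        return self.sequences[self.ids.index(self.target_id)]

    @property
    def target_sequence(self) -> str:
        """Ungapped template sequence."""
        return "".join(c for c in self.target_row if c not in GAP_CHARS)


@dataclass
class PositionConservation:
    """Conservation record for one ungapped template position."""

    position: int              # 1-based ungapped template coordinate
    column_index: int          # 0-based column in the alignment
    target_residue: str
    frequencies: dict          # residue -> fraction among counted symbols
    target_conservation: float
    consensus_residue: str
    consensus_conservation: float
    undefined: bool = False    # all non-target rows gapped at this column


@dataclass
class ConservationProfile:
    positions: list[PositionConservation]
    target_id: str = ""
    n_rows: int = 0

    def __getitem__(self, position: int) -> PositionConservation:
        return self.positions[position - 1]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ConsensusDesign:
    threshold: float
    preserve_set: frozenset
    designed_sequence: str
    mutations: list = field(default_factory=list)  # (position, wt, replacement)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def read_msa(path, target_id: str, fmt: str = "fasta") -> MSA:
    """Read a FASTA or Stockholm alignment into an :class:`MSA`."""
    aln = AlignIO.read(path, fmt)
    return MSA(
        sequences=[str(rec.seq).upper() for rec in aln],
        ids=[rec.id for rec in aln],
        target_id=target_id,
    )


def column_conservation(msa: MSA) -> ConservationProfile:
    """Per-position residue frequencies and template-residue conservation.

    For each ungapped template position, symbols are tallied over the non-gap
    residues of the other rows at that alignment column plus the template
    residue itself.  A column where every other row is gapped is flagged
    ``undefined`` and is never mutated downstream.
    """
    ti = msa.target_index
    others = [s for i, s in enumerate(msa.sequences) if i != ti]
    target_row = msa.sequences[ti]
    positions: list[PositionConservation] = []
    pos = 0
    for col, t_res in enumerate(target_row):
        if t_res in GAP_CHARS:
            continue
        pos += 1
        counts = Counter(
            row[col] for row in others if row[col] not in GAP_CHARS
        )
        undefined = sum(counts.values()) == 0
        counts[t_res] += 1  # template residue enters numerator and denominator
        total = sum(counts.values())
        freqs = {res: n / total for res, n in counts.items()}
        # consensus tie-break: prefer template residue, then alphabetical
        best = max(freqs.values())
        tied = sorted(r for r, f in freqs.items() if f == best)
        consensus = t_res if t_res in tied else tied[0]
        positions.append(
            PositionConservation(
                position=pos,
                column_index=col,
                target_residue=t_res,
                frequencies=freqs,
                target_conservation=freqs[t_res],
                consensus_residue=consensus,
                consensus_conservation=freqs[consensus],
                undefined=undefined,
            )
        )
    return ConservationProfile(positions=positions, target_id=msa.target_id, n_rows=len(msa.sequences))


def design_construct(
    profile: ConservationProfile,
    threshold: float,
    preserve_set: Iterable[int] = (),
) -> ConsensusDesign:
    """Apply a conservation threshold to produce a consensus construct.

    A position keeps its template residue when its conservation exceeds the
    threshold (strict), when it is in ``preserve_set``, when the consensus
    residue already equals the template residue, or when conservation is
    undefined; otherwise it is replaced by the column consensus residue.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    preserve = frozenset(int(p) for p in preserve_set)
    n = len(profile)
    bad = [p for p in preserve if not 1 <= p <= n]
    if bad:
        raise ValueError(f"preserve positions outside target range 1..{n}: {sorted(bad)}")
    out = []
    mutations = []
    for pc in profile.positions:
        keep = (
            pc.undefined
            or pc.position in preserve
            or pc.consensus_residue == pc.target_residue
            or pc.target_conservation > threshold
        )
        if keep:
            out.append(pc.target_residue)
        else:
            out.append(pc.consensus_residue)
            mutations.append((pc.position, pc.target_residue, pc.consensus_residue))
    return ConsensusDesign(
        threshold=threshold,
        preserve_set=preserve,
        designed_sequence="".join(out),
        mutations=sorted(mutations),
    )


def threshold_sweep(
    profile: ConservationProfile,
    thresholds: Sequence[float],
    preserve_set: Iterable[int] = (),
) -> list[ConsensusDesign]:
    """One design per threshold; mutation counts are non-decreasing."""
    if len(thresholds) == 0:
        raise ValueError("empty threshold list")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return [design_construct(profile, t, preserve_set) for t in thresholds]


_PRESERVE_TOKEN = re.compile(r"^(?:[A-Za-z])?(\d+)$")


def parse_preserve_list(lines: Iterable[str]) -> frozenset:
    """Parse preserve entries: bare positions ("396") or residue tokens ("S396")."""
    out = set()
    for line in lines:
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        m = _PRESERVE_TOKEN.match(tok)
        if not m:
            raise ValueError(f"unparseable preserve token: {tok!r}")
        out.add(int(m.group(1)))
    return frozenset(out)


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two protein sequences.

    Needleman-Wunsch with BLOSUM62, gap open 11 / extend 1; identity is
    matches divided by aligned residue pairs (columns where both sequences
    have a residue).  Returns percent at full precision; round for display.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        for i, c in enumerate(seq):
            if c not in AMINO_ACIDS:
                raise ValueError(f"{name}: non-amino-acid symbol {c!r} at position {i + 1}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    pairs = matches = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            continue
        pairs += 1
        if x == y:
            matches += 1
    if pairs == 0:
        return 0.0
    return 100.0 * matches / pairs


def write_design_fasta(design: ConsensusDesign, handle, name: str = "consensus_design") -> None:
    handle.write(f">{name} threshold={design.threshold}\n")
    seq = design.designed_sequence
    for i in range(0, len(seq), 60):
        handle.write(seq[i : i + 60] + "\n")


def write_mutation_report(design: ConsensusDesign, profile: ConservationProfile, handle) -> None:
    """TSV mutation report: position, wt, mut, conservation, consensus."""
    handle.write("position\twt\tmut\twt_conservation\tconsensus_conservation\n")
    for pos, wt, mut in design.mutations:
        pc = profile[pos]
        handle.write(
            f"{pos}\t{wt}\t{mut}\t{pc.target_conservation:.4f}\t{pc.consensus_conservation:.4f}\n"
        )
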