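"""Peptide bookkeeping: locating peptides on the protein, sequence coverage,
exchangeable-amide counting, and molecular masses.

Residue numbering is 1-based with inclusive ranges throughout, so a peptide
spanning residues 102-120 has 19 residues.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .chem import molecular_mass  # noqa: F401  (re-exported: part of this API)

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "PeptideRecord",
    "CoverageMask",
    "locate_peptide",
    "compute_coverage",
    "count_exchangeable_amides",
    "amide_positions",
    "molecular_mass",
    "read_fasta",
    "write_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "write_coverage_csv",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PEPTIDE_TABLE_COLUMNS = ["sequence", "start", "end", "charge", "sn_ratio"]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain: identifier plus one-letter residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = sorted(set(self.residues) - AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-standard residue letters: "
                + ", ".join(bad)
            )

    def __len__(self) -> int:
        return len(self.residues)

    def substring(self, start: int, end: int) -> str:
        """Residues ``start..end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(
                f"range {start}-{end} outside protein {self.id!r} (length {len(self)})"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide mapped onto the protein."""

    sequence: str
    start: int
    end: int
    charge: int
    sn_ratio: float = float("inf")

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence is empty")
        bad = sorted(set(self.sequence) - AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"peptide {self.sequence!r} contains non-standard letters: "
                + ", ".join(bad)
            )
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: range {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )
        if self.start < 1:
            raise ValueError(f"peptide {self.sequence!r}: start must be >= 1")
        if self.charge < 1:
            raise ValueError(f"peptide {self.sequence!r}: charge must be >= 1")

    @property
    def key(self) -> tuple[str, int]:
        """Identity used to join peptides with their clusters."""
        return (self.sequence, self.charge)

    def validate_against(self, protein: ProteinSequence) -> None:
        observed = protein.substring(self.start, self.end)
        if observed != self.sequence:
            raise ValueError(
                f"peptide {self.sequence!r} does not match protein {protein.id!r} "
                f"residues {self.start}-{self.end} ({observed!r})"
            )


@dataclass(frozen=True)
class CoverageMask:
    """Per-residue coverage flags plus the covered fraction (3 decimals)."""

    covered: tuple[bool, ...]
    coverage_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        fraction = round(sum(self.covered) / len(self.covered), 3) if self.covered else 0.0
        object.__setattr__(self, "coverage_fraction", fraction)


def locate_peptide(
    peptide_sequence: str, protein: ProteinSequence
) -> list[tuple[int, int]]:
    """All exact-match placements of a peptide on the protein.

    Returns 1-based inclusive ``(start, end)`` ranges sorted by start,
    including overlapping occurrences; an empty list if the peptide is absent.
    """
    if not peptide_sequence:
        raise ValueError("peptide sequence is empty")
    hits: list[tuple[int, int]] = []
    pos = protein.residues.find(peptide_sequence)
    while pos != -1:
        hits.append((pos + 1, pos + len(peptide_sequence)))
        pos = protein.residues.find(peptide_sequence, pos + 1)
    return hits


def compute_coverage(
    peptides: Iterable[PeptideRecord], protein: ProteinSequence
) -> CoverageMask:
    """Union coverage of the peptides' residue ranges over the protein."""
    mask = [False] * len(protein)
    for peptide in peptides:
        peptide.validate_against(protein)
        for i in range(peptide.start - 1, peptide.end):
            mask[i] = True
    return CoverageMask(covered=tuple(mask))


def amide_positions(sequence: str, exclude_n_terminal: int = 1) -> list[int]:
    """Peptide-local positions (1-based) of counted exchangeable amides.

    The first ``exclude_n_terminal`` residues are excluded (their amides
    back-exchange too fast to measure) as is every proline (no amide
    hydrogen).
    """
    if not sequence:
        raise ValueError("peptide sequence is empty")
    if exclude_n_terminal < 0:
        raise ValueError("exclude_n_terminal must be >= 0")
    return [
        i + 1
        for i in range(exclude_n_terminal, len(sequence))
        if sequence[i] != "P"
    ]


def count_exchangeable_amides(sequence: str, exclude_n_terminal: int = 1) -> int:
    """Number of backbone amides counted toward maximal deuterium uptake."""
    return len(amide_positions(sequence, exclude_n_terminal))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ProteinSequence:
    """First record of a FASTA file as a ProteinSequence."""
    for record in SeqIO.parse(str(path), "fasta"):
        return ProteinSequence(id=record.id, residues=str(record.seq).upper())
    raise ValueError(f"no sequences found in {path}")


def write_fasta(protein: ProteinSequence, path: str | Path, width: int = 60) -> None:
    lines = [f">{protein.id}"]
    for i in range(0, len(protein.residues), width):
        lines.append(protein.residues[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Peptide identification table: CSV with header
    ``sequence,start,end,charge,sn_ratio``."""
    peptides: list[PeptideRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        missing = set(PEPTIDE_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"{path}: peptide table missing columns: {', '.join(sorted(missing))}"
            )
        for row in reader:
            peptides.append(
                PeptideRecord(
                    sequence=row["sequence"].strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    charge=int(row["charge"]),
                    sn_ratio=float(row["sn_ratio"]),
                )
            )
    return peptides


def write_peptide_table(peptides: Sequence[PeptideRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PEPTIDE_TABLE_COLUMNS)
        for p in peptides:
            writer.writerow([p.sequence, p.start, p.end, p.charge, f"{p.sn_ratio:g}"])


def write_coverage_csv(mask: CoverageMask, path: str | Path) -> str:
    """Write a ``residue,covered`` CSV; return a one-line human summary."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["residue", "covered"])
        for i, flag in enumerate(mask.covered, start=1):
            writer.writerow([i, int(flag)])
    return (
        f"coverage: {sum(mask.covered)}/{len(mask.covered)} residues "
        f"({100 * mask.coverage_fraction:.1f}%)"
    )
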