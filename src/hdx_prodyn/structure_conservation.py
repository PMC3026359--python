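"""Residue-level projection of differential uptake, PDB B-factor coloring,
and alignment-conservation comparison."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import AlignIO
from scipy import stats as _scipy_stats

from .differential_stats import DifferentialResult
from .peptide_map import PeptideRecord, ProteinSequence, locate_peptide

__all__ = [
    "ResidueProjection",
    "ConservationProfile",
    "ConservationReport",
    "project_to_residues",
    "write_bfactor_pdb",
    "read_bfactors",
    "column_conservation",
    "conservation_protection_report",
    "write_projection_csv",
    "write_conservation_csv",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ResidueProjection:
    """Per-residue differential-uptake values.

    ``values[i]`` is NaN for residue ``i + 1`` when no retained peptide
    covers it (status ``undetected``); otherwise it is the unweighted mean
    of delta-HDX over covering peptides (status ``measured``).
    """

    values: tuple[float, ...]
    status: tuple[str, ...]
    sources: tuple[tuple[tuple[str, int], ...], ...]

    def __len__(self) -> int:
        return len(self.values)

    def measured_residues(self) -> list[int]:
        return [i + 1 for i, s in enumerate(self.status) if s == "measured"]


def project_to_residues(
    results: Iterable[DifferentialResult],
    peptides: Iterable[PeptideRecord],
    protein: ProteinSequence,
    select: Callable[[DifferentialResult], bool] | None = None,
) -> ResidueProjection:
    """Project peptide-level delta-HDX onto residues.

    Each covered residue receives the unweighted mean over all covering
    peptides' results (optionally filtered by ``select``); uncovered
    residues are marked undetected.  Peptides whose sequence occurs more
    than once on the protein are ambiguous and skipped.
    """
    peptide_by_key = {p.key: p for p in peptides}
    sums = np.zeros(len(protein))
    counts = np.zeros(len(protein), dtype=int)
    sources: list[list[tuple[str, int]]] = [[] for _ in range(len(protein))]
    for result in sorted(results, key=lambda r: (r.start, r.peptide_key)):
        if select is not None and not select(result):
            continue
        peptide = peptide_by_key.get(result.peptide_key)
        if peptide is None:
            raise ValueError(f"no peptide record for result key {result.peptide_key}")
        if len(locate_peptide(peptide.sequence, protein)) != 1:
            continue  # ambiguous placement: excluded from residue projection
        for i in range(peptide.start - 1, peptide.end):
            sums[i] += result.delta_hdx_percent
            counts[i] += 1
            sources[i].append(result.peptide_key)
    values = tuple(
        float(sums[i] / counts[i]) if counts[i] else float("nan")
        for i in range(len(protein))
    )
    status = tuple("measured" if c else "undetected" for c in counts)
    return ResidueProjection(
        values=values, status=status, sources=tuple(tuple(s) for s in sources)
    )


# ---------------------------------------------------------------------------
# PDB B-factor rewriting (fixed-column, byte-preserving outside cols 61-66)
# ---------------------------------------------------------------------------


def write_bfactor_pdb(
    pdb_text: str,
    chain: str,
    projection: ResidueProjection,
    sentinel: float = 0.0,
    residue_offset: int = 0,
) -> tuple[str, list[str]]:
    """Rewrite the B-factor column of a PDB chain from a residue projection.

    For every ATOM/HETATM record of ``chain``, the B-factor (columns 61-66)
    becomes the projected value of residue ``resSeq + residue_offset``
    (sentinel for undetected or out-of-range residues).  Everything outside
    those six columns is byte-identical to the input.  Returns the new text
    and a list of warnings for projected residues absent from the PDB.
    """
    lines = pdb_text.splitlines(keepends=True)
    seen_chain = False
    seen_residues: set[int] = set()
    out_lines = []
    for line in lines:
        record = line[:6]
        if record in ("ATOM  ", "HETATM") and len(line) >= 66 and line[21] == chain:
            seen_chain = True
            try:
                res_seq = int(line[22:26])
            except ValueError:
                out_lines.append(line)
                continue
            residue = res_seq + residue_offset
            seen_residues.add(residue)
            if 1 <= residue <= len(projection) and projection.status[
                residue - 1
            ] == "measured":
                value = projection.values[residue - 1]
            else:
                value = sentinel
            formatted = f"{value:6.2f}"
            if len(formatted) > 6:
                raise ValueError(
                    f"B-factor value {value} does not fit the 6-column field"
                )
            line = line[:60] + formatted + line[66:]
        out_lines.append(line)
    if not seen_chain:
        raise ValueError(f"chain {chain!r} not found in PDB text")
    warnings = [
        f"residue {r} is projected but absent from chain {chain}"
        for r in projection.measured_residues()
        if r not in seen_residues
    ]
    return "".join(out_lines), warnings


def read_bfactors(pdb_text: str, chain: str) -> dict[int, float]:
    """Per-residue B-factor of a chain (first atom of each residue)."""
    bfactors: dict[int, float] = {}
    for line in pdb_text.splitlines():
        if line[:6] in ("ATOM  ", "HETATM") and len(line) >= 66 and line[21] == chain:
            res_seq = int(line[22:26])
            if res_seq not in bfactors:
                bfactors[res_seq] = float(line[60:66])
    if not bfactors:
        raise ValueError(f"chain {chain!r} not found in PDB text")
    return bfactors


# ---------------------------------------------------------------------------
# Alignment conservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores plus reference-residue mapping.

    ``column_to_residue`` maps 0-based alignment columns to 1-based residue
    indices of the reference sequence; columns gapped in the reference are
    unmapped.
    """

    scores: tuple[float, ...]
    column_to_residue: Mapping[int, int]

    def residue_scores(self) -> dict[int, float]:
        return {res: self.scores[col] for col, res in self.column_to_residue.items()}


def column_conservation(
    alignment: "AlignIO.MultipleSeqAlignment | str | Path",
    reference_id: str,
    fmt: str | None = None,
) -> ConservationProfile:
    """Modal-symbol conservation per alignment column.

    ``alignment`` may be a Biopython alignment object or a path to an
    aligned-FASTA or Clustal file (format auto-detected unless given).
    Score = count of the most common non-gap symbol divided by the number
    of sequences; an all-gap column scores 0.
    """
    if isinstance(alignment, (str, Path)):
        alignment = _read_alignment(alignment, fmt)
    reference = None
    for record in alignment:
        if record.id == reference_id:
            reference = str(record.seq)
            break
    if reference is None:
        raise ValueError(f"reference sequence {reference_id!r} not in alignment")

    n_sequences = len(alignment)
    n_columns = alignment.get_alignment_length()
    scores = []
    for col in range(n_columns):
        symbols = [str(rec.seq[col]).upper() for rec in alignment]
        counts: dict[str, int] = {}
        for s in symbols:
            if s not in GAP_CHARS:
                counts[s] = counts.get(s, 0) + 1
        scores.append(max(counts.values()) / n_sequences if counts else 0.0)

    column_to_residue = {}
    residue = 0
    for col, symbol in enumerate(reference):
        if symbol not in GAP_CHARS:
            residue += 1
            column_to_residue[col] = residue
    return ConservationProfile(
        scores=tuple(scores), column_to_residue=column_to_residue
    )


def _read_alignment(path: str | Path, fmt: str | None):
    if fmt is not None:
        return AlignIO.read(str(path), fmt)
    text = Path(path).read_text()
    guessed = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    return AlignIO.read(str(path), guessed)


class ConservationReport(NamedTuple):
    spearman_rho: float
    p_value: float
    n_residues: int
    flag: str  # "" or "untestable"
    peptide_rows: tuple[tuple[tuple[str, int], float, float], ...]


def conservation_protection_report(
    projection: ResidueProjection,
    profile: ConservationProfile,
    peptides: Sequence[PeptideRecord] = (),
) -> ConservationReport:
    """Spearman rank correlation of residue conservation vs delta-HDX.

    Restricted to residues that are both measured and mapped; fewer than 5
    such residues, or zero variance on either side, yields an untestable
    flag.  ``peptide_rows`` lists (key, mean conservation, mean delta) for
    any supplied peptides.
    """
    residue_scores = profile.residue_scores()
    residues = [r for r in projection.measured_residues() if r in residue_scores]
    conservation = [residue_scores[r] for r in residues]
    delta = [projection.values[r - 1] for r in residues]

    rows = []
    for peptide in peptides:
        covered = [r for r in range(peptide.start, peptide.end + 1) if r in residue_scores]
        measured = [
            r
            for r in range(peptide.start, peptide.end + 1)
            if projection.status[r - 1] == "measured"
        ]
        if not covered or not measured:
            continue
        rows.append(
            (
                peptide.key,
                sum(residue_scores[r] for r in covered) / len(covered),
                sum(projection.values[r - 1] for r in measured) / len(measured),
            )
        )

    if len(residues) < 5:
        return ConservationReport(
            float("nan"), float("nan"), len(residues), "untestable", tuple(rows)
        )
    if len(set(conservation)) < 2 or len(set(delta)) < 2:
        return ConservationReport(
            float("nan"), float("nan"), len(residues), "untestable", tuple(rows)
        )
    rho, p = _scipy_stats.spearmanr(conservation, delta)
    return ConservationReport(float(rho), float(p), len(residues), "", tuple(rows))


def write_projection_csv(projection: ResidueProjection, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["residue", "delta", "status"])
        for i, (value, status) in enumerate(zip(projection.values, projection.status)):
            writer.writerow(
                [i + 1, "" if status == "undetected" else f"{value:.4f}", status]
            )


def write_conservation_csv(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["residue", "conservation"])
        for residue, score in sorted(profile.residue_scores().items()):
            writer.writerow([residue, f"{score:.4f}"])
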