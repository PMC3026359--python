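"""End-to-end orchestration: validate inputs, build uptake curves, run the
differential comparison for every holo condition, and optionally project the
result onto a structure and a conservation profile.

All parameters come from a single YAML config; every run writes the resolved
config, a machine-readable JSON manifest, and a plain-text log next to its
outputs.  Given identical inputs and config, all CSV outputs are
byte-identical between runs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .design import ExperimentDesign
from .differential_stats import differential_table, write_differential_csv
from .peptide_map import (
    PeptideRecord,
    ProteinSequence,
    compute_coverage,
    read_fasta,
    read_peptide_table,
    write_coverage_csv,
)
from .structure_conservation import (
    column_conservation,
    conservation_protection_report,
    project_to_residues,
    write_bfactor_pdb,
    write_conservation_csv,
    write_projection_csv,
)
from .uptake_core import (
    CorrectionParams,
    build_uptake_curves,
    read_peak_csv,
    summarize_hdx,
    write_uptake_csv,
)

__all__ = [
    "PipelineConfig",
    "Finding",
    "ValidationReport",
    "RunReport",
    "validate_inputs",
    "run_pipeline",
]

ALL_STAGES = frozenset({"uptake", "diff", "overlay", "conservation"})


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for one analysis run."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    fasta: str = "protein.fasta"
    peptides: str = "peptides.csv"
    peaks: str = "peaks.csv"
    structure: str | None = None
    alignment: str | None = None
    alignment_reference: str | None = None
    chain: str = "A"
    residue_offset: int = 0
    sentinel: float = 0.0
    basis: str = "centroid"
    bh_correction: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        design_kwargs = dict(raw.pop("design", {}))
        if "correction" in design_kwargs:
            design_kwargs["correction"] = CorrectionParams(**design_kwargs["correction"])
        files = raw.pop("files", {})
        return cls(design=ExperimentDesign(**design_kwargs), **files, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_dict(self) -> dict:
        return {
            "design": {
                "timepoints": list(self.design.timepoints),
                "conditions": list(self.design.conditions),
                "sn_threshold": self.design.sn_threshold,
                "last_k": self.design.last_k,
                "alpha": self.design.alpha,
                "correction": {
                    "recovery": self.design.correction.recovery,
                    "buffer_d_fraction": self.design.correction.buffer_d_fraction,
                    "deuterium_mass_shift": self.design.correction.deuterium_mass_shift,
                },
            },
            "files": {
                "fasta": self.fasta,
                "peptides": self.peptides,
                "peaks": self.peaks,
                "structure": self.structure,
                "alignment": self.alignment,
            },
            "alignment_reference": self.alignment_reference,
            "chain": self.chain,
            "residue_offset": self.residue_offset,
            "sentinel": self.sentinel,
            "basis": self.basis,
            "bh_correction": self.bh_correction,
        }


@dataclass(frozen=True)
class Finding:
    severity: str  # "warning" | "error"
    message: str


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def exit_code(self) -> int:
        if self.errors:
            return 2
        return 1 if self.warnings else 0


def validate_inputs(
    input_dir: str | Path, config: PipelineConfig = PipelineConfig()
) -> ValidationReport:
    """Check the input directory against the design; never raises."""
    input_dir = Path(input_dir)
    findings: list[Finding] = []

    def error(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warning(msg: str) -> None:
        findings.append(Finding("warning", msg))

    fasta_path = input_dir / config.fasta
    peptides_path = input_dir / config.peptides
    peaks_path = input_dir / config.peaks
    for path in (fasta_path, peptides_path, peaks_path):
        if not path.exists():
            error(f"missing input file: {path.name}")
    if any(f.severity == "error" for f in findings):
        return ValidationReport(tuple(findings))

    protein: ProteinSequence | None = None
    try:
        protein = read_fasta(fasta_path)
    except Exception as exc:
        error(f"{fasta_path.name}: {exc}")

    peptides: list[PeptideRecord] = []
    try:
        peptides = read_peptide_table(peptides_path)
    except Exception as exc:
        error(f"{peptides_path.name}: {exc}")
    if protein is not None:
        for peptide in peptides:
            try:
                peptide.validate_against(protein)
            except ValueError as exc:
                error(f"{peptides_path.name}: {exc}")

    known_keys = {p.key for p in peptides}
    cells: set[tuple] = set()
    with open(peaks_path, newline="") as handle:
        reader = csv.DictReader(handle)
        required = {
            "peptide_sequence", "charge", "condition", "time_s",
            "replicate", "mz", "intensity", "sn_ratio",
        }
        missing = required - set(reader.fieldnames or [])
        if missing:
            error(
                f"{peaks_path.name}: missing columns: {', '.join(sorted(missing))}"
            )
            return ValidationReport(tuple(findings))
        for line_no, row in enumerate(reader, start=2):
            try:
                key = (row["peptide_sequence"].strip(), int(row["charge"]))
                condition = row["condition"].strip()
                time_s = float(row["time_s"])
                intensity = float(row["intensity"])
                float(row["mz"])
            except (ValueError, AttributeError, TypeError):
                error(f"{peaks_path.name}:{line_no}: malformed row")
                continue
            if intensity < 0:
                error(f"{peaks_path.name}:{line_no}: negative intensity {intensity}")
            if key not in known_keys:
                warning(
                    f"{peaks_path.name}:{line_no}: peptide {key[0]} (z={key[1]}) "
                    "has no record in the peptide table"
                )
            if condition not in config.design.conditions:
                warning(
                    f"{peaks_path.name}:{line_no}: condition {condition!r} "
                    "not in the design"
                )
            cells.add((key, condition, time_s))

    for key in sorted(known_keys):
        for condition in config.design.conditions:
            for time_s in config.design.timepoints:
                if (key, condition, time_s) not in cells:
                    warning(
                        f"missing cluster: peptide {key[0]} (z={key[1]}), "
                        f"condition {condition}, t={time_s:g}s"
                    )
    return ValidationReport(tuple(findings))


@dataclass(frozen=True)
class RunReport:
    outputs: Mapping[str, Path]
    summary: str
    n_peptides_input: int
    n_peptides_retained: int
    coverage_fraction: float
    exclusions: tuple[tuple[tuple[str, int], str], ...]


def run_pipeline(
    config: PipelineConfig | str | Path,
    input_dir: str | Path,
    output_dir: str | Path,
    stages: frozenset[str] | set[str] = ALL_STAGES,
) -> RunReport:
    """Run the analysis stages on an input directory.

    Raises on validation errors; on any failure all partially written
    outputs are removed.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    report = validate_inputs(input_dir, config)
    if report.errors:
        details = "; ".join(f.message for f in report.errors[:10])
        raise ValueError(f"input validation failed: {details}")

    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{_time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    def out(name: str) -> Path:
        path = output_dir / name
        written.append(path)
        return path

    try:
        design = config.design
        protein = read_fasta(input_dir / config.fasta)
        peptides = read_peptide_table(input_dir / config.peptides)
        clusters = read_peak_csv(input_dir / config.peaks)
        log(f"loaded {len(peptides)} peptides, {len(clusters)} clusters")

        curves, exclusions = build_uptake_curves(
            clusters,
            peptides,
            design.correction,
            sn_threshold=design.sn_threshold,
        )
        retained_keys = sorted({c.key for c in curves})
        retained_peptides = [
            p for p in peptides if p.key in set(retained_keys)
        ]
        coverage = compute_coverage(retained_peptides, protein)
        outputs: dict[str, Path] = {}

        if "uptake" in stages:
            write_uptake_csv(curves, out("uptake.csv"))
            outputs["uptake"] = output_dir / "uptake.csv"
            summary_line = write_coverage_csv(coverage, out("coverage.csv"))
            outputs["coverage"] = output_dir / "coverage.csv"
            log(summary_line)

        curves_by_condition: dict[str, list] = {}
        for curve in curves:
            curves_by_condition.setdefault(curve.condition, []).append(curve)

        diff_results: dict[str, list] = {}
        if "diff" in stages or "overlay" in stages or "conservation" in stages:
            apo_curves = curves_by_condition.get(design.apo_condition, [])
            for holo in design.holo_conditions:
                holo_curves = curves_by_condition.get(holo, [])
                if not apo_curves or not holo_curves:
                    log(f"skipping {holo}: missing curves")
                    continue
                results, dropped = differential_table(
                    apo_curves,
                    holo_curves,
                    alpha=design.alpha,
                    last_k=design.last_k,
                    basis=config.basis,
                    bh_correction=config.bh_correction,
                )
                diff_results[holo] = results
                for key, reason in dropped:
                    log(f"diff {holo}: excluded {key}: {reason}")
                if "diff" in stages:
                    name = f"differential_{holo}.csv"
                    write_differential_csv(results, out(name))
                    outputs[f"diff_{holo}"] = output_dir / name

        projections = {}
        for holo, results in diff_results.items():
            projections[holo] = project_to_residues(results, peptides, protein)

        if "overlay" in stages and config.structure:
            pdb_text = (input_dir / config.structure).read_text()
            for holo, projection in projections.items():
                recolored, warnings = write_bfactor_pdb(
                    pdb_text,
                    config.chain,
                    projection,
                    sentinel=config.sentinel,
                    residue_offset=config.residue_offset,
                )
                name = f"recolored_{holo}.pdb"
                out(name).write_text(recolored)
                outputs[f"overlay_{holo}"] = output_dir / name
                proj_name = f"projection_{holo}.csv"
                write_projection_csv(projection, out(proj_name))
                outputs[f"projection_{holo}"] = output_dir / proj_name
                for message in warnings:
                    log(f"overlay {holo}: {message}")

        if "conservation" in stages and config.alignment:
            reference = config.alignment_reference or protein.id
            profile = column_conservation(input_dir / config.alignment, reference)
            write_conservation_csv(profile, out("conservation.csv"))
            outputs["conservation"] = output_dir / "conservation.csv"
            report_lines = []
            for holo, projection in projections.items():
                cons_report = conservation_protection_report(
                    projection, profile, retained_peptides
                )
                report_lines.append(
                    f"{holo}: spearman rho="
                    + (
                        "untestable"
                        if cons_report.flag
                        else f"{cons_report.spearman_rho:.4f} "
                        f"(p={cons_report.p_value:.4g}, n={cons_report.n_residues})"
                    )
                )
            out("conservation_report.txt").write_text("\n".join(report_lines) + "\n")
            outputs["conservation_report"] = output_dir / "conservation_report.txt"

        # summary + reproducibility artifacts
        resolved = yaml.safe_dump(config.to_dict(), sort_keys=True)
        out("resolved_config.yaml").write_text(resolved)
        config_hash = hashlib.sha256(resolved.encode()).hexdigest()

        summary_lines = [
            f"peptides in input: {len({p.key for p in peptides})}",
            f"peptides retained: {len(retained_keys)}",
            f"sequence coverage: {100 * coverage.coverage_fraction:.1f}%",
            f"excluded: {len(exclusions)}",
        ]
        for condition in design.conditions:
            if condition in curves_by_condition:
                cond_summary = summarize_hdx(curves, condition)
                summary_lines.append(
                    f"mean uptake [{condition}]: {cond_summary.grand_mean:.1f}%"
                )
        for key, reason in exclusions:
            summary_lines.append(f"  - {key[0]} (z={key[1]}): {reason}")
        for warning_finding in report.warnings:
            summary_lines.append(f"warning: {warning_finding.message}")
        summary = "\n".join(summary_lines)
        out("summary.txt").write_text(summary + "\n")
        outputs["summary"] = output_dir / "summary.txt"

        manifest = {
            "version": __version__,
            "config_sha256": config_hash,
            "inputs": {
                "fasta": config.fasta,
                "peptides": config.peptides,
                "peaks": config.peaks,
            },
            "stages": sorted(stages),
            "peptides_input": len({p.key for p in peptides}),
            "peptides_retained": len(retained_keys),
            "coverage_fraction": coverage.coverage_fraction,
            "exclusions": [
                {"peptide": key[0], "charge": key[1], "reason": reason}
                for key, reason in exclusions
            ],
            "outputs": {k: str(v.name) for k, v in outputs.items()},
        }
        out("manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        outputs["manifest"] = output_dir / "manifest.json"
        log("run complete")
        out("run.log").write_text("\n".join(log_lines) + "\n")
        outputs["log"] = output_dir / "run.log"

        return RunReport(
            outputs=outputs,
            summary=summary,
            n_peptides_input=len({p.key for p in peptides}),
            n_peptides_retained=len(retained_keys),
            coverage_fraction=coverage.coverage_fraction,
            exclusions=tuple(exclusions),
        )
    except Exception:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise
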