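"""Synthetic HDX experiments with known ground truth.

The generative model is deliberately minimal: each exchangeable amide
exchanges with first-order kinetics at an intrinsic rate slowed by the
protection factor of the region it sits in,

    P(deuterated at t) = buffer_d_fraction * (1 - exp(-(rate / protection) * t)),

back-exchange retains each incorporated deuteron independently with
probability ``recovery``, the deuteron-count distribution over a peptide's
amides is therefore a Poisson binomial, and the observed cluster is that
distribution convolved with the peptide's natural isotopic envelope (exact
elemental composition, no averagine).  Peak intensities get multiplicative
lognormal noise.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .chem import (
    DEUTERIUM_MASS_SHIFT,
    PROTON_MASS,
    isotopic_envelope,
    peptide_composition,
)
from .design import ExperimentDesign
from .peptide_map import (
    PeptideRecord,
    ProteinSequence,
    amide_positions,
    locate_peptide,
    write_fasta,
    write_peptide_table,
)
from .uptake_core import CorrectionParams, IsotopicCluster, write_peak_csv

__all__ = [
    "ExchangeModel",
    "Region",
    "SyntheticTruth",
    "SimulatedExperiment",
    "SimulationConfig",
    "simulate_residue_deuteration",
    "deuteron_distribution",
    "simulate_peptide_cluster",
    "generate_experiment",
    "write_experiment",
    "demo_protein",
    "tile_peptides",
]


@dataclass(frozen=True)
class ExchangeModel:
    """Labeling-chemistry constants of the generative model."""

    buffer_d_fraction: float = 0.80
    recovery: float = 0.70
    intrinsic_rate_range: tuple[float, float] = (1e-4, 1e-1)
    deuterium_mass_shift: float = DEUTERIUM_MASS_SHIFT

    def __post_init__(self) -> None:
        if not (0 < self.buffer_d_fraction <= 1):
            raise ValueError("buffer_d_fraction must be in (0, 1]")
        if not (0 < self.recovery <= 1):
            raise ValueError("recovery must be in (0, 1]")
        lo, hi = self.intrinsic_rate_range
        if not (0 < lo <= hi):
            raise ValueError("intrinsic_rate_range must satisfy 0 < low <= high")

    def correction_params(self) -> CorrectionParams:
        return CorrectionParams(
            recovery=self.recovery,
            buffer_d_fraction=self.buffer_d_fraction,
            deuterium_mass_shift=self.deuterium_mass_shift,
        )


@dataclass(frozen=True)
class Region:
    """A contiguous residue range with per-condition protection factors."""

    start: int
    end: int
    protection: Mapping[str, float]

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region bounds {self.start}-{self.end}")
        for condition, factor in self.protection.items():
            if factor < 1:
                raise ValueError(
                    f"protection factor {factor} < 1 for condition {condition!r} "
                    f"in region {self.start}-{self.end}"
                )
        object.__setattr__(self, "protection", dict(self.protection))

    def factor(self, condition: str) -> float:
        return self.protection.get(condition, 1.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one simulated experiment."""

    protein_id: str
    regions: tuple[Region, ...]
    residue_rates: tuple[float, ...]  # per second, one per residue
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "residue_rates", tuple(self.residue_rates))
        length = len(self.residue_rates)
        ordered = sorted(self.regions, key=lambda r: r.start)
        cursor = 1
        for region in ordered:
            if region.start != cursor:
                raise ValueError(
                    f"regions must tile the sequence without gaps or overlap; "
                    f"expected a region starting at {cursor}, got {region.start}"
                )
            cursor = region.end + 1
        if cursor != length + 1:
            raise ValueError(
                f"regions end at {cursor - 1} but the protein has {length} residues"
            )
        if any(rate <= 0 for rate in self.residue_rates):
            raise ValueError("residue rates must be positive")

    def protection_profile(self, condition: str) -> np.ndarray:
        """Per-residue protection factors (index 0 = residue 1)."""
        profile = np.ones(len(self.residue_rates))
        for region in self.regions:
            profile[region.start - 1 : region.end] = region.factor(condition)
        return profile

    def residue_range(self, condition_a: str, condition_b: str) -> set[int]:
        """Residues whose protection differs between two conditions."""
        pa = self.protection_profile(condition_a)
        pb = self.protection_profile(condition_b)
        return {i + 1 for i in np.nonzero(pa != pb)[0]}

    def mean_deuteration(
        self,
        peptide: PeptideRecord,
        time: float,
        condition: str,
        model: ExchangeModel,
        exclude_n_terminal: int = 1,
    ) -> float:
        """Expected labeling fraction (before back-exchange) averaged over
        the peptide's counted amides; the recovery target for round-trip
        tests is ``100 * mean_deuteration / buffer_d_fraction``."""
        probs = _residue_probabilities(
            peptide, self, time, condition, model, exclude_n_terminal,
            apply_recovery=False,
        )
        if probs.size == 0:
            raise ValueError(f"peptide {peptide.sequence!r} has no counted amides")
        return float(probs.mean())


@dataclass(frozen=True)
class SimulatedExperiment:
    clusters: tuple[IsotopicCluster, ...]
    peptides: tuple[PeptideRecord, ...]
    protein: ProteinSequence
    truth: SyntheticTruth
    design: ExperimentDesign
    replicates: int = 1

    def __post_init__(self) -> None:
        expected = (
            len(self.peptides)
            * len(self.design.conditions)
            * len(self.design.timepoints)
            * self.replicates
        )
        cells = {
            (c.key, c.condition, c.time, c.replicate) for c in self.clusters
        }
        if len(self.clusters) != expected or len(cells) != expected:
            raise ValueError(
                f"expected exactly one cluster per design cell "
                f"({expected} cells, got {len(self.clusters)} clusters, "
                f"{len(cells)} distinct cells)"
            )


def simulate_residue_deuteration(
    residue_rate: float, protection: float, time: float, model: ExchangeModel
) -> float:
    """Probability that one amide carries deuterium after ``time`` seconds
    of labeling (before back-exchange)."""
    if time < 0:
        raise ValueError(f"labeling time must be >= 0, got {time}")
    if protection < 1:
        raise ValueError(f"protection factor must be >= 1, got {protection}")
    if residue_rate <= 0:
        raise ValueError(f"residue rate must be > 0, got {residue_rate}")
    return model.buffer_d_fraction * (-np.expm1(-(residue_rate / protection) * time))


def deuteron_distribution(probabilities: Sequence[float]) -> np.ndarray:
    """Poisson-binomial distribution of the deuteron count.

    ``probabilities[i]`` is the retention-adjusted deuteration probability of
    amide ``i``; returns an array of length ``n + 1`` summing to 1.
    """
    dist = np.ones(1)
    for p in probabilities:
        if not (0 <= p <= 1):
            raise ValueError(f"probability {p} outside [0, 1]")
        extended = np.zeros(dist.size + 1)
        extended[:-1] += dist * (1 - p)
        extended[1:] += dist * p
        dist = extended
    return dist


def _residue_probabilities(
    peptide: PeptideRecord,
    truth: SyntheticTruth,
    time: float,
    condition: str,
    model: ExchangeModel,
    exclude_n_terminal: int,
    apply_recovery: bool = True,
) -> np.ndarray:
    protection = truth.protection_profile(condition)
    if peptide.end > len(truth.residue_rates):
        raise ValueError(
            f"peptide {peptide.sequence!r} ({peptide.start}-{peptide.end}) extends "
            f"past the truth protein ({len(truth.residue_rates)} residues)"
        )
    probs = []
    for local in amide_positions(peptide.sequence, exclude_n_terminal):
        residue = peptide.start + local - 1  # 1-based global index
        p = simulate_residue_deuteration(
            truth.residue_rates[residue - 1], protection[residue - 1], time, model
        )
        probs.append(model.recovery * p if apply_recovery else p)
    return np.asarray(probs)


def simulate_peptide_cluster(
    peptide: PeptideRecord,
    truth: SyntheticTruth,
    time: float,
    condition: str,
    model: ExchangeModel,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    replicate: int = 1,
    exclude_n_terminal: int = 1,
    base_intensity: float = 1e6,
    envelope_prune: float = 1e-12,
) -> IsotopicCluster:
    """Simulate one isotopic cluster for a peptide ion.

    The deuteron-count Poisson binomial is convolved with the peptide's
    natural envelope; peaks falling in the same nominal isotope bin are
    merged with an intensity-weighted m/z, so the cluster centroid equals
    the analytic value exactly at ``noise_cv=0``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    probs = _residue_probabilities(
        peptide, truth, time, condition, model, exclude_n_terminal
    )
    deut = deuteron_distribution(probs)
    natural = isotopic_envelope(peptide_composition(peptide.sequence), envelope_prune)

    # bin index -> [summed abundance, abundance-weighted neutral mass]
    bins: dict[int, list[float]] = {}
    for j, (mass_j, abundance_j) in enumerate(natural):
        for d, p_d in enumerate(deut):
            weight = abundance_j * p_d
            if weight < envelope_prune:
                continue
            acc = bins.setdefault(j + d, [0.0, 0.0])
            acc[0] += weight
            acc[1] += weight * (mass_j + d * model.deuterium_mass_shift)
    z = peptide.charge
    peaks = []
    for _, (abundance, mass_acc) in sorted(bins.items()):
        mz = (mass_acc / abundance + z * PROTON_MASS) / z
        peaks.append((mz, abundance))

    scale = base_intensity / max(i for _, i in peaks)
    intensities = np.array([i * scale for _, i in peaks])
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = np.exp(rng.normal(size=intensities.size) * sigma - sigma**2 / 2)
        intensities = intensities * factors
    return IsotopicCluster(
        peptide_sequence=peptide.sequence,
        charge=z,
        condition=condition,
        time=time,
        replicate=replicate,
        peaks=tuple((mz, float(i)) for (mz, _), i in zip(peaks, intensities)),
        sn_ratio=peptide.sn_ratio,
    )


# ---------------------------------------------------------------------------
# Whole-experiment generation
# ---------------------------------------------------------------------------

# Fragments observed for the model xylanase, pinned at their literature
# residue coordinates; the rest of the demo chain is seeded filler.
_DEMO_FRAGMENTS: tuple[tuple[int, str], ...] = (
    (6, "SVNWNTQDD"),
    (38, "VGWTTGSSAPINF"),
    (63, "LSVYGWSTNPLVEYY"),
    (102, "YTIWENTRVNEPSIQGTATFNQY"),
)

_DEMO_LENGTH = 190


def demo_protein(seed: int = 0, protein_id: str = "demo_xylanase") -> ProteinSequence:
    """A deterministic ~190-residue demo chain with known peptide anchors.

    Anchored fragments sit at fixed coordinates; filler residues come from
    the seed.  Each anchored fragment is guaranteed to occur exactly once.
    """
    alphabet = sorted("ACDEFGHIKLMNQRSTVWY")  # no proline in filler
    for attempt in range(32):
        rng = np.random.default_rng([seed, attempt, 0xDE30])
        residues = [alphabet[i] for i in rng.integers(0, len(alphabet), _DEMO_LENGTH)]
        for start, fragment in _DEMO_FRAGMENTS:
            residues[start - 1 : start - 1 + len(fragment)] = fragment
        sequence = "".join(residues)
        protein = ProteinSequence(id=protein_id, residues=sequence)
        if all(
            locate_peptide(fragment, protein) == [(start, start + len(fragment) - 1)]
            for start, fragment in _DEMO_FRAGMENTS
        ):
            return protein
    raise RuntimeError("could not build a demo protein with unique anchors")


def tile_peptides(
    protein: ProteinSequence,
    seed: int = 0,
    min_length: int = 9,
    max_length: int = 16,
    overlap: int = 3,
    sn_ratio: float = 10.0,
) -> list[PeptideRecord]:
    """Pepsin-style overlapping peptides tiling the whole chain."""
    rng = np.random.default_rng([seed, 0x9E9])
    peptides: list[PeptideRecord] = []
    start = 1
    length = len(protein)
    while start <= length:
        size = int(rng.integers(min_length, max_length + 1))
        end = min(start + size - 1, length)
        if length - end < min_length:
            end = length
        peptides.append(
            PeptideRecord(
                sequence=protein.substring(start, end),
                start=start,
                end=end,
                charge=int(rng.integers(1, 3)),
                sn_ratio=sn_ratio,
            )
        )
        if end == length:
            break
        start = end - overlap + 1
    return peptides


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic experiment."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    model: ExchangeModel = field(default_factory=ExchangeModel)
    protein_id: str = "demo_xylanase"
    sequence: str | None = None
    peptides: tuple[PeptideRecord, ...] | None = None
    regions: tuple[Region, ...] | None = None
    replicates: int = 1
    noise_cv: float = 0.05
    sn_ratio: float = 10.0
    exclude_n_terminal: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        design_kwargs = dict(raw.pop("design", {}))
        if "correction" in design_kwargs:
            design_kwargs["correction"] = CorrectionParams(**design_kwargs["correction"])
        design = ExperimentDesign(**design_kwargs)
        model_kwargs = dict(raw.pop("model", {}))
        model_kwargs.setdefault("buffer_d_fraction", design.correction.buffer_d_fraction)
        model_kwargs.setdefault("recovery", design.correction.recovery)
        if "intrinsic_rate_range" in model_kwargs:
            model_kwargs["intrinsic_rate_range"] = tuple(
                model_kwargs["intrinsic_rate_range"]
            )
        model = ExchangeModel(**model_kwargs)
        peptides = raw.pop("peptides", None)
        if peptides is not None:
            peptides = tuple(PeptideRecord(**p) for p in peptides)
        regions = raw.pop("regions", None)
        if regions is not None:
            regions = tuple(
                Region(r["start"], r["end"], r.get("protection", {})) for r in regions
            )
        return cls(design=design, model=model, peptides=peptides, regions=regions, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


def generate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete synthetic experiment; deterministic in the seed."""
    if config.sequence is not None:
        protein = ProteinSequence(id=config.protein_id, residues=config.sequence)
    else:
        protein = demo_protein(seed=config.seed, protein_id=config.protein_id)

    if config.peptides is not None:
        peptides = tuple(config.peptides)
        for peptide in peptides:
            peptide.validate_against(protein)
    else:
        peptides = tuple(
            tile_peptides(protein, seed=config.seed, sn_ratio=config.sn_ratio)
        )

    if config.regions is not None:
        regions = tuple(config.regions)
    else:
        regions = (Region(1, len(protein), {}),)

    lo, hi = config.model.intrinsic_rate_range
    rate_rng = np.random.default_rng([config.seed, 0x7A7E])
    rates = np.exp(rate_rng.uniform(np.log(lo), np.log(hi), len(protein)))
    truth = SyntheticTruth(
        protein_id=protein.id,
        regions=regions,
        residue_rates=tuple(float(r) for r in rates),
        seed=config.seed,
    )

    clusters = []
    for pep_idx, peptide in enumerate(peptides):
        for cond_idx, condition in enumerate(config.design.conditions):
            for time_idx, time in enumerate(config.design.timepoints):
                for replicate in range(1, config.replicates + 1):
                    rng = np.random.default_rng(
                        [config.seed, 0xC1, pep_idx, cond_idx, time_idx, replicate]
                    )
                    clusters.append(
                        simulate_peptide_cluster(
                            peptide,
                            truth,
                            time,
                            condition,
                            config.model,
                            noise_cv=config.noise_cv,
                            seed=rng,
                            replicate=replicate,
                            exclude_n_terminal=config.exclude_n_terminal,
                        )
                    )
    return SimulatedExperiment(
        clusters=tuple(clusters),
        peptides=peptides,
        protein=protein,
        truth=truth,
        design=config.design,
        replicates=config.replicates,
    )


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write peaks.csv, peptides.csv, protein.fasta and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out / "peaks.csv",
        "peptides": out / "peptides.csv",
        "fasta": out / "protein.fasta",
        "truth": out / "truth.json",
    }
    write_peak_csv(experiment.clusters, paths["peaks"])
    write_peptide_table(experiment.peptides, paths["peptides"])
    write_fasta(experiment.protein, paths["fasta"])
    truth = experiment.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "protein_id": truth.protein_id,
                "seed": truth.seed,
                "regions": [
                    {
                        "start": r.start,
                        "end": r.end,
                        "protection": dict(sorted(r.protection.items())),
                    }
                    for r in truth.regions
                ],
                "residue_rates": list(truth.residue_rates),
                "conditions": list(experiment.design.conditions),
                "timepoints": list(experiment.design.timepoints),
                "replicates": experiment.replicates,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths
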