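"""Shared fixtures: a demo protein, small simulated experiments, and a
synthetic PDB builder (all generated at test time; no binary fixtures)."""

from __future__ import annotations

import pytest

from hdx_prodyn.design import ExperimentDesign
from hdx_prodyn.peptide_map import PeptideRecord, ProteinSequence
from hdx_prodyn.synthetic_data import (
    ExchangeModel,
    Region,
    SimulationConfig,
    demo_protein,
    generate_experiment,
)
from hdx_prodyn.uptake_core import IsotopicCluster


@pytest.fixture(scope="session")
def protein() -> ProteinSequence:
    return demo_protein(seed=0)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Default-design experiment, noise-free, fixed seed."""
    return generate_experiment(SimulationConfig(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def two_condition_design() -> ExperimentDesign:
    return ExperimentDesign(conditions=("apo", "holo"))


@pytest.fixture
def make_cluster():
    def _make(
        peaks,
        sequence="SVNWNTQDD",
        charge=1,
        condition="apo",
        time=0.0,
        replicate=1,
        sn_ratio=10.0,
    ) -> IsotopicCluster:
        return IsotopicCluster(
            peptide_sequence=sequence,
            charge=charge,
            condition=condition,
            time=time,
            replicate=replicate,
            peaks=tuple(peaks),
            sn_ratio=sn_ratio,
        )

    return _make


def make_pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz=(1.0, 2.0, 3.0),
    bfactor: float = 11.11,
    occupancy: float = 1.0,
    record: str = "ATOM",
    element: str = "C",
) -> str:
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {name:<4} {resname:>3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {element:>2}"
    )


def make_pdb(residues_by_chain: dict[str, list[int]], bfactor: float = 11.11) -> str:
    """A minimal but column-correct PDB with N/CA/C atoms per residue."""
    lines = ["HEADER    SYNTHETIC TEST STRUCTURE"]
    serial = 1
    for chain, residues in residues_by_chain.items():
        for resseq in residues:
            for name in ("N", "CA", "C"):
                lines.append(
                    make_pdb_line(
                        serial, name, "ALA", chain, resseq,
                        xyz=(serial * 0.1, 2.0, 3.0), bfactor=bfactor,
                    )
                )
                serial += 1
        lines.append(f"TER   {serial:>5}      ALA {chain}{residues[-1]:>4}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_builder():
    return make_pdb


@pytest.fixture(scope="session")
def localized_protection_setup():
    """Design used by the power/localization checks: one 5x-protected region
    with peptide spans aligned to its boundaries."""
    sequence = demo_protein(seed=0).residues[:120]
    spans = [(1, 20), (21, 40), (41, 55), (54, 68), (66, 80), (81, 100), (101, 120)]
    peptides = tuple(
        PeptideRecord(
            sequence=sequence[s - 1 : e], start=s, end=e,
            charge=1 + (i % 2), sn_ratio=10.0,
        )
        for i, (s, e) in enumerate(spans)
    )
    regions = (
        Region(1, 40, {}),
        Region(41, 80, {"holo": 5.0}),
        Region(81, 120, {}),
    )

    def make_config(seed: int, noise_cv: float = 0.02, replicates: int = 4):
        return SimulationConfig(
            design=ExperimentDesign(conditions=("apo", "holo")),
            model=ExchangeModel(intrinsic_rate_range=(2e-3, 2e-2)),
            sequence=sequence,
            protein_id="p",
            peptides=peptides,
            regions=regions,
            noise_cv=noise_cv,
            replicates=replicates,
            seed=seed,
        )

    return {
        "make_config": make_config,
        "inside_spans": {(41, 55), (54, 68), (66, 80)},
        "region_residues": set(range(41, 81)),
    }
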