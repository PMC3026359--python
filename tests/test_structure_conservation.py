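import math

import numpy as np
import pytest

from hdx_prodyn.differential_stats import DifferentialResult
from hdx_prodyn.peptide_map import PeptideRecord, ProteinSequence
from hdx_prodyn.structure_conservation import (
    ConservationProfile,
    column_conservation,
    conservation_protection_report,
    project_to_residues,
    read_bfactors,
    write_bfactor_pdb,
    write_conservation_csv,
    write_projection_csv,
)

from conftest import make_pdb


def _result(peptide: PeptideRecord, delta: float, classification="protected"):
    return DifferentialResult(
        peptide_key=peptide.key,
        start=peptide.start,
        end=peptide.end,
        apo_condition="apo",
        holo_condition="holo",
        delta_hdx_percent=delta,
        t_statistic=5.0,
        p_value=0.01,
        df=2,
        classification=classification,
    )


@pytest.fixture
def small_protein():
    return ProteinSequence(id="p", residues="ACDEFGHIKLMNQRSTVWYA")


class TestProjection:
    def test_single_cover(self, small_protein):
        peptide = PeptideRecord(small_protein.substring(5, 10), 5, 10, 1)
        projection = project_to_residues(
            [_result(peptide, 20.0)], [peptide], small_protein
        )
        for residue in range(1, 21):
            if 5 <= residue <= 10:
                assert projection.values[residue - 1] == 20.0
                assert projection.status[residue - 1] == "measured"
            else:
                assert math.isnan(projection.values[residue - 1])
                assert projection.status[residue - 1] == "undetected"
                assert projection.sources[residue - 1] == ()

    def test_overlap_mean(self, small_protein):
        p1 = PeptideRecord(small_protein.substring(1, 10), 1, 10, 1)
        p2 = PeptideRecord(small_protein.substring(6, 15), 6, 15, 1)
        projection = project_to_residues(
            [_result(p1, 10.0), _result(p2, 30.0)], [p1, p2], small_protein
        )
        for residue in range(6, 11):
            assert projection.values[residue - 1] == pytest.approx(20.0)
        for residue in range(1, 6):
            assert projection.values[residue - 1] == pytest.approx(10.0)
        for residue in range(11, 16):
            assert projection.values[residue - 1] == pytest.approx(30.0)

    def test_empty_results_all_undetected(self, small_protein):
        projection = project_to_residues([], [], small_protein)
        assert all(s == "undetected" for s in projection.status)

    def test_permutation_invariant(self, small_protein):
        p1 = PeptideRecord(small_protein.substring(1, 10), 1, 10, 1)
        p2 = PeptideRecord(small_protein.substring(6, 15), 6, 15, 1)
        results = [_result(p1, 10.0), _result(p2, 30.0)]
        forward = project_to_residues(results, [p1, p2], small_protein)
        backward = project_to_residues(results[::-1], [p2, p1], small_protein)
        assert np.array_equal(forward.values, backward.values, equal_nan=True)
        assert forward.status == backward.status

    def test_ambiguous_peptide_skipped(self):
        protein = ProteinSequence(id="p", residues="ACDACDGH")
        peptide = PeptideRecord("ACD", 1, 3, 1)
        projection = project_to_residues([_result(peptide, 5.0)], [peptide], protein)
        assert all(s == "undetected" for s in projection.status)

    def test_select_filter(self, small_protein):
        p1 = PeptideRecord(small_protein.substring(1, 10), 1, 10, 1)
        p2 = PeptideRecord(small_protein.substring(11, 20), 11, 20, 1)
        results = [
            _result(p1, 10.0, "protected"),
            _result(p2, 1.0, "not_significant"),
        ]
        projection = project_to_residues(
            results, [p1, p2], small_protein,
            select=lambda r: r.classification == "protected",
        )
        assert projection.status[0] == "measured"
        assert projection.status[10] == "undetected"


class TestBfactorPdb:
    def test_all_sentinel(self, small_protein):
        pdb = make_pdb({"A": [1, 2, 3]})
        projection = project_to_residues([], [], small_protein)
        recolored, warnings = write_bfactor_pdb(pdb, "A", projection, sentinel=7.5)
        assert warnings == []
        assert set(read_bfactors(recolored, "A").values()) == {7.5}
        # coordinates untouched
        for old, new in zip(pdb.splitlines(), recolored.splitlines()):
            if old.startswith("ATOM"):
                assert old[30:54] == new[30:54]

    def test_single_residue_format(self, small_protein):
        peptide = PeptideRecord(small_protein.substring(2, 2), 2, 2, 1)
        projection = project_to_residues(
            [_result(peptide, 12.3)], [peptide], small_protein
        )
        pdb = make_pdb({"A": [1, 2, 3]})
        recolored, _ = write_bfactor_pdb(pdb, "A", projection)
        for line in recolored.splitlines():
            if line.startswith("ATOM") and int(line[22:26]) == 2:
                assert line[60:66] == " 12.30"

    def test_round_trip_recovers_values(self, small_protein):
        p1 = PeptideRecord(small_protein.substring(1, 10), 1, 10, 1)
        p2 = PeptideRecord(small_protein.substring(6, 15), 6, 15, 1)
        projection = project_to_residues(
            [_result(p1, 10.0), _result(p2, 30.0)], [p1, p2], small_protein
        )
        pdb = make_pdb({"A": list(range(1, 21))})
        recolored, _ = write_bfactor_pdb(pdb, "A", projection, sentinel=-1.0)
        recovered = read_bfactors(recolored, "A")
        for residue in range(1, 21):
            if projection.status[residue - 1] == "measured":
                assert recovered[residue] == pytest.approx(
                    round(projection.values[residue - 1], 2), abs=1e-9
                )
            else:
                assert recovered[residue] == -1.0

    def test_only_bfactor_columns_of_target_chain_change(self, small_protein):
        peptide = PeptideRecord(small_protein.substring(1, 10), 1, 10, 1)
        projection = project_to_residues(
            [_result(peptide, 42.0)], [peptide], small_protein
        )
        pdb = make_pdb({"A": [1, 2], "B": [1, 2]})
        recolored, _ = write_bfactor_pdb(pdb, "A", projection)
        for old, new in zip(pdb.splitlines(keepends=True),
                            recolored.splitlines(keepends=True)):
            if old[:6] in ("ATOM  ", "HETATM") and old[21] == "A":
                assert old[:60] == new[:60]
                assert old[66:] == new[66:]
            else:
                assert old == new

    def test_missing_chain_raises(self, small_protein):
        pdb = make_pdb({"A": [1]})
        projection = project_to_residues([], [], small_protein)
        with pytest.raises(ValueError, match="chain 'Z'"):
            write_bfactor_pdb(pdb, "Z", projection)

    def test_projected_residue_absent_from_pdb_warned(self, small_protein):
        peptide = PeptideRecord(small_protein.substring(1, 10), 1, 10, 1)
        projection = project_to_residues(
            [_result(peptide, 5.0)], [peptide], small_protein
        )
        pdb = make_pdb({"A": [1, 2, 3]})
        _, warnings = write_bfactor_pdb(pdb, "A", projection)
        assert len(warnings) == 7  # residues 4..10 measured but absent

    def test_residue_offset(self, small_protein):
        peptide = PeptideRecord(small_protein.substring(5, 5), 5, 5, 1)
        projection = project_to_residues(
            [_result(peptide, 9.0)], [peptide], small_protein
        )
        # PDB numbering starts at 101 -> offset maps 105 back to residue 5
        pdb = make_pdb({"A": [104, 105, 106]})
        recolored, _ = write_bfactor_pdb(
            pdb, "A", projection, residue_offset=-100
        )
        assert read_bfactors(recolored, "A")[105] == 9.0


def _write_alignment_fasta(path, records):
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in records))


class TestConservation:
    def test_fully_identical_column(self, tmp_path):
        path = tmp_path / "msa.fasta"
        _write_alignment_fasta(
            path, [(f"s{i}", "ACDE") for i in range(13)]
        )
        profile = column_conservation(path, "s0")
        assert profile.scores == (1.0, 1.0, 1.0, 1.0)

    def test_partial_agreement_counting_oracle(self, tmp_path):
        path = tmp_path / "msa.fasta"
        records = [(f"s{i}", "A") for i in range(7)] + [
            (f"s{i}", "G") for i in range(7, 13)
        ]
        _write_alignment_fasta(path, records)
        profile = column_conservation(path, "s0")
        assert profile.scores[0] == pytest.approx(7 / 13)

    def test_all_gap_column_unmapped(self, tmp_path):
        path = tmp_path / "msa.fasta"
        _write_alignment_fasta(path, [("a", "A-C"), ("b", "A-C"), ("c", "A-C")])
        profile = column_conservation(path, "a")
        assert profile.scores[1] == 0.0
        assert profile.column_to_residue == {0: 1, 2: 2}

    def test_reference_gaps_unmapped(self, tmp_path):
        path = tmp_path / "msa.fasta"
        _write_alignment_fasta(path, [("ref", "A-CD"), ("x", "AGCD")])
        profile = column_conservation(path, "ref")
        assert profile.column_to_residue == {0: 1, 2: 2, 3: 3}
        assert profile.residue_scores()[1] == 1.0

    def test_sequence_order_invariant(self, tmp_path):
        records = [("ref", "ACD-"), ("x", "ACDE"), ("y", "GCDE")]
        p1 = tmp_path / "a.fasta"
        p2 = tmp_path / "b.fasta"
        _write_alignment_fasta(p1, records)
        _write_alignment_fasta(p2, records[::-1])
        a = column_conservation(p1, "ref")
        b = column_conservation(p2, "ref")
        assert a.scores == b.scores

    def test_missing_reference_raises(self, tmp_path):
        path = tmp_path / "msa.fasta"
        _write_alignment_fasta(path, [("a", "AC"), ("b", "AC")])
        with pytest.raises(ValueError, match="nope"):
            column_conservation(path, "nope")

    def test_clustal_format(self, tmp_path):
        path = tmp_path / "msa.aln"
        path.write_text(
            "CLUSTAL W (1.82) multiple sequence alignment\n\n"
            "ref             ACDE\n"
            "other           ACDE\n"
        )
        profile = column_conservation(path, "ref")
        assert profile.scores == (1.0, 1.0, 1.0, 1.0)

    def test_conservation_csv(self, tmp_path):
        profile = ConservationProfile(scores=(0.5, 1.0), column_to_residue={0: 1, 1: 2})
        write_conservation_csv(profile, tmp_path / "cons.csv")
        lines = (tmp_path / "cons.csv").read_text().splitlines()
        assert lines == ["residue,conservation", "1,0.5000", "2,1.0000"]


class TestConservationReport:
    def _projection(self, small_protein, deltas):
        peptides = []
        results = []
        for (start, end), delta in deltas:
            peptide = PeptideRecord(small_protein.substring(start, end), start, end, 1)
            peptides.append(peptide)
            results.append(_result(peptide, delta))
        return project_to_residues(results, peptides, small_protein), peptides

    def test_constant_conservation_flagged(self, small_protein):
        projection, _ = self._projection(
            small_protein, [((1, 10), 5.0), ((11, 20), 15.0)]
        )
        profile = ConservationProfile(
            scores=tuple([0.8] * 20), column_to_residue={i: i + 1 for i in range(20)}
        )
        report = conservation_protection_report(projection, profile)
        assert report.flag == "untestable"
        assert math.isnan(report.spearman_rho)

    def test_constructed_positive_correlation(self, small_protein):
        projection, peptides = self._projection(
            small_protein, [((1, 10), 2.0), ((11, 20), 30.0)]
        )
        scores = tuple([0.3] * 10 + [0.9] * 10)
        rng = np.random.default_rng(0)
        jitter = tuple(s + 0.001 * rng.random() for s in scores)
        profile = ConservationProfile(
            scores=jitter, column_to_residue={i: i + 1 for i in range(20)}
        )
        report = conservation_protection_report(projection, profile, peptides)
        assert report.flag == ""
        assert report.spearman_rho > 0
        assert len(report.peptide_rows) == 2

    def test_insufficient_overlap_flagged(self, small_protein):
        projection, _ = self._projection(small_protein, [((1, 3), 5.0)])
        profile = ConservationProfile(
            scores=(0.1, 0.5, 0.9), column_to_residue={0: 1, 1: 2, 2: 3}
        )
        report = conservation_protection_report(projection, profile)
        assert report.flag == "untestable"
        assert report.n_residues == 3

    def test_permutation_null_mean_near_zero(self, small_protein):
        rng = np.random.default_rng(7)
        projection, _ = self._projection(
            small_protein,
            [((1, 5), 1.0), ((6, 10), 8.0), ((11, 15), 3.0), ((16, 20), 12.0)],
        )
        scores = tuple(rng.random(20))
        correlations = []
        values = np.array(projection.values)
        for _ in range(500):
            permuted = rng.permutation(values)
            perm_projection = type(projection)(
                values=tuple(permuted),
                status=projection.status,
                sources=projection.sources,
            )
            profile = ConservationProfile(
                scores=scores, column_to_residue={i: i + 1 for i in range(20)}
            )
            report = conservation_protection_report(perm_projection, profile)
            if not report.flag:
                correlations.append(report.spearman_rho)
        assert abs(np.mean(correlations)) < 0.05

    def test_projection_csv(self, small_protein, tmp_path):
        projection, _ = self._projection(small_protein, [((1, 2), 5.0)])
        write_projection_csv(projection, tmp_path / "proj.csv")
        lines = (tmp_path / "proj.csv").read_text().splitlines()
        assert lines[0] == "residue,delta,status"
        assert lines[1] == "1,5.0000,measured"
        assert lines[3] == "3,,undetected"
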