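"""Ensemble, annotation and report I/O round-trips and error contracts."""

import numpy as np
import pandas as pd
import pytest

import pbflex as pf
from pbflex.ensemble_io import (
    EnsembleFormatError,
    EnsembleStructureError,
    read_report,
)

PDB_3x2 = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.004   1.424   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.040   2.810   0.100  1.00  0.00           C
ATOM      6  C   ALA A   2       5.500   2.600   0.500  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.104   1.424   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.432   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.140   2.810   0.100  1.00  0.00           C
ATOM      6  C   ALA A   2       5.600   2.600   0.500  1.00  0.00           C
ENDMDL
END
"""


class TestPDBRead:
    def test_roster_preservation(self, tmp_path):
        """A 3-model PDB of a 5-residue chain gives 3 frames x 5 residues."""
        spec = pf.GeneratorSpec(n_residues=5, n_frames=3, base_letters="mmmmm")
        ens, _, _ = pf.generate_ensemble(spec, np.random.default_rng(0))
        path = tmp_path / "ens.pdb"
        pf.write_ensemble_pdb(ens, path)
        back = pf.read_ensemble(path)
        assert back.n_frames == 3 and back.n_residues == 5
        # PDB stores 3 decimals
        assert np.allclose(back.coords, ens.coords, atol=1.5e-3)
        assert list(back.chain_ids) == ["A"] * 5
        assert list(back.residue_indices) == list(range(5))

    def test_read_is_deterministic(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(PDB_3x2)
        a = pf.read_ensemble(path)
        b = pf.read_ensemble(path)
        assert np.array_equal(a.coords, b.coords)
        assert a.coords.shape == (2, 2, 3, 3)

    def test_model_missing_backbone_atom_drops_residue(self, tmp_path):
        broken = PDB_3x2.replace(
            "ATOM      5  CA  ALA A   2       4.140   2.810   0.100  1.00  0.00           C\n",
            "",
        )
        path = tmp_path / "broken.pdb"
        path.write_text(broken)
        with pytest.warns(UserWarning, match="dropped"):
            ens = pf.read_ensemble(path)
        assert ens.n_residues == 1 and ens.n_frames == 2

    def test_divergent_roster_names_model(self, tmp_path):
        extra = PDB_3x2.replace(
            "ATOM      6  C   ALA A   2       5.600   2.600   0.500  1.00  0.00           C\n",
            "ATOM      6  C   ALA A   2       5.600   2.600   0.500  1.00  0.00           C\n"
            "ATOM      7  N   ALA A   3       6.600   2.600   0.500  1.00  0.00           N\n"
            "ATOM      8  CA  ALA A   3       7.600   2.600   0.500  1.00  0.00           C\n"
            "ATOM      9  C   ALA A   3       8.600   2.600   0.500  1.00  0.00           C\n",
        )
        path = tmp_path / "divergent.pdb"
        path.write_text(extra)
        with pytest.raises(EnsembleStructureError, match="model 2"):
            pf.read_ensemble(path)

    def test_insertion_codes_rejected(self, tmp_path):
        with_icode = PDB_3x2.replace(
            "ATOM      4  N   ALA A   2       3.332",
            "ATOM      4  N   ALA A   2A      3.332",
        )
        path = tmp_path / "icode.pdb"
        path.write_text(with_icode)
        with pytest.raises(EnsembleStructureError, match="nsertion"):
            pf.read_ensemble(path)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        doubled = PDB_3x2.replace(
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CA AALA A   1       9.000   9.000   9.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       1.458   0.000   0.000  0.70  0.00           C",
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(doubled)
        ens = pf.read_ensemble(path)
        assert ens.coords[0, 0, 1, 0] == pytest.approx(1.458)

    def test_unparsable_file_is_format_error(self, tmp_path):
        path = tmp_path / "junk.pdb"
        path.write_text("this is not\x00 a pdb\n")
        with pytest.raises((EnsembleFormatError, EnsembleStructureError)):
            pf.read_ensemble(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pf.read_ensemble(tmp_path / "absent.pdb")


class TestDihedralTSV:
    def test_round_trip_is_a_fixpoint(self, tmp_path, rng):
        """Write -> read -> write -> read reproduces values bitwise."""
        spec = pf.GeneratorSpec(n_residues=8, n_frames=5, base_letters="m" * 8, sigma=10.0)
        ens, _, _ = pf.generate_ensemble(spec, rng)
        dih = pf.compute_dihedrals(ens)
        p1 = tmp_path / "a.tsv"
        pf.write_dihedral_tsv(dih, p1)
        first = pf.read_ensemble(p1, fmt="dihedral_tsv")
        assert np.allclose(first.phi, dih.phi, atol=5e-7, equal_nan=True)
        p2 = tmp_path / "b.tsv"
        pf.write_dihedral_tsv(first, p2)
        second = pf.read_dihedral_tsv(p2)
        assert np.array_equal(first.phi, second.phi, equal_nan=True)
        assert np.array_equal(first.psi, second.psi, equal_nan=True)
        assert first.n_frames * first.n_residues == 5 * 8

    def test_roster_divergence_across_frames_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "frame\tchain\tresidue\tphi_deg\tpsi_deg\n"
            "0\tA\t1\tNA\t-47.0\n0\tA\t2\t-57.0\tNA\n"
            "1\tA\t1\tNA\t-47.0\n1\tA\t3\t-57.0\tNA\n"
        )
        with pytest.raises(EnsembleStructureError, match="frame 1"):
            pf.read_dihedral_tsv(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("frame\tchain\tphi_deg\n0\tA\t1.0\n")
        with pytest.raises(EnsembleFormatError, match="residue"):
            pf.read_dihedral_tsv(path)


class TestReports:
    def test_na_encoding_and_header(self, tmp_path):
        df = pd.DataFrame(
            {"chain": ["A"] * 3, "residue": [0, 1, 2], "neq": [1.0, np.nan, 2.5]}
        )
        path = tmp_path / "neq.tsv"
        pf.write_report(df, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "chain\tresidue\tneq"
        assert len(lines) == 4
        assert lines[2].split("\t")[2] == "NA"
        assert lines[1].split("\t")[1] == "1"  # 1-based residue numbering on disk

    def test_frequency_round_trip_to_six_decimals(self, tmp_path, rng):
        from pbflex.flexibility import frequency_table

        spec = pf.GeneratorSpec(n_residues=10, n_frames=30, base_letters="m" * 10,
                                position_target=_uniform_target(10), rho=0.0)
        states, _ = pf.sample_pb_trajectory(spec, rng)
        pbs = _states_to_pbs(states)
        freq = pf.pb_frequencies(pbs)
        path = tmp_path / "freq.tsv"
        pf.write_report(frequency_table(freq), path)
        back = read_report(path)
        cols = [c for c in back.columns if c.startswith("f_")]
        assert np.allclose(back[cols].to_numpy(), freq.freq, atol=5e-7, equal_nan=True)


def _uniform_target(L):
    t = np.full((L, 16), 1.0 / 16)
    return t


def _states_to_pbs(states):
    letters = np.array(list(pf.PB_LABELS), dtype="U1")[states]
    L = states.shape[1]
    return pf.PBEnsemble(letters, ["A"] * L, np.arange(L))


class TestAnnotation:
    def test_read_and_segment_partition(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "chain\tresidue\ttopology\tss\tsegment\texon\n"
            "A\t1\tIC\tcoil\tloop1\t1\n"
            "A\t2\tTM\talpha\thelix1\t1\n"
            "A\t3\tTM\talpha\thelix1\t2\n"
        )
        ann = pf.read_annotation(path)
        segs = ann.segments()
        assert set(segs) == {"loop1", "helix1"}
        assert list(ann.table["residue"]) == [0, 1, 2]  # re-based internally

    def test_duplicate_annotation_rejected(self):
        df = pd.DataFrame(
            {
                "chain": ["A", "A"],
                "residue": [0, 0],
                "topology": ["TM", "TM"],
                "ss": ["alpha", "alpha"],
                "segment": ["helix1", "helix2"],
            }
        )
        with pytest.raises(ValueError, match="partition"):
            pf.AnnotationTrack(df)


class TestBackboneEnsembleInvariants:
    def test_nonfinite_coordinates_rejected(self):
        coords = np.zeros((1, 3, 3, 3))
        coords[0, 1, 1, 2] = np.inf
        with pytest.raises(ValueError, match="finite"):
            pf.BackboneEnsemble(coords, ["A"] * 3, np.arange(3))

    def test_frame_times_must_increase(self):
        coords = np.zeros((2, 3, 3, 3))
        with pytest.raises(ValueError, match="increasing"):
            pf.BackboneEnsemble(coords, ["A"] * 3, np.arange(3), frame_times=[0.2, 0.1])

    def test_truncate_requires_leftover_frames(self, helix_ensemble):
        with pytest.raises(ValueError, match="truncate"):
            helix_ensemble.truncate(4)
        assert helix_ensemble.truncate(2).n_frames == 2
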