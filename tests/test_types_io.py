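import numpy as np
import pytest

import saxskit as sk
from saxskit.io import read_bead_model, read_profile, write_bead_model, write_profile


class TestScatteringProfile:
    def test_validates_lengths_and_monotonicity(self):
        with pytest.raises(ValueError):
            sk.ScatteringProfile([0.01, 0.02], [1.0], [0.1])
        with pytest.raises(ValueError):
            sk.ScatteringProfile([0.02, 0.01], [1.0, 1.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            sk.ScatteringProfile([-0.01, 0.02], [1.0, 1.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            sk.ScatteringProfile([0.01, 0.02], [1.0, 1.0], [-0.1, 0.1])

    def test_q_conversion_roundtrip(self):
        s = np.linspace(0.002, 0.08, 17)
        assert np.allclose(sk.q_to_s(sk.s_to_q(s)), s, rtol=0, atol=1e-15)

    def test_zero_sigma_allowed_for_model_curves(self):
        p = sk.ScatteringProfile([0.01, 0.02], [2.0, 1.0], [0.0, 0.0])
        assert len(p) == 2


class TestProfileIO:
    def test_basic_parse(self, tmp_path):
        f = tmp_path / "p.dat"
        f.write_text("0.01 100 1\n0.02 90 1\n0.03 70 1\n")
        p = read_profile(f, concentration=1.0)
        assert len(p) == 3
        assert np.allclose(p.s_grid, [0.01, 0.02, 0.03])
        assert p.concentration == 1.0

    def test_bad_rows_dropped(self, tmp_path):
        f = tmp_path / "p.dat"
        f.write_text("0.01 100 1\n0.015 -5 0\n0.02 90 1\n0.03 70 1\n")
        p = read_profile(f)
        assert len(p) == 3  # the zero-sigma row is dropped, intensity sign kept

    def test_comments_and_extra_columns(self, tmp_path):
        f = tmp_path / "p.dat"
        f.write_text("# header\n0.01 100 1 999\n0.02 90 1 999\n")
        assert len(read_profile(f)) == 2

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "p.dat"
        f.write_text("# nothing\n")
        with pytest.raises(ValueError, match="no usable data"):
            read_profile(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_profile(tmp_path / "absent.dat")

    def test_roundtrip(self, tmp_path):
        p = sk.ScatteringProfile(
            np.linspace(0.002, 0.08, 40), np.linspace(5, 1, 40), np.full(40, 0.05),
            concentration=2.5, label="dark",
        )
        write_profile(p, tmp_path / "out.dat")
        back = read_profile(tmp_path / "out.dat", concentration=2.5)
        assert np.allclose(back.s_grid, p.s_grid)
        assert np.allclose(back.intensity, p.intensity)
        assert np.allclose(back.sigma, p.sigma)


class TestBeadModelIO:
    def test_single_bead_at_origin(self, tmp_path):
        write_bead_model(sk.BeadModel([[0.0, 0.0, 0.0]]), tmp_path / "m.pdb")
        text = (tmp_path / "m.pdb").read_text()
        atom_lines = [l for l in text.splitlines() if l.startswith(("ATOM", "HETATM"))]
        assert len(atom_lines) == 1
        assert "DUM" in atom_lines[0]
        m = read_bead_model(tmp_path / "m.pdb")
        assert np.allclose(m.coords, 0.0, atol=1e-3)

    def test_roundtrip_50_beads(self, tmp_path):
        rng = np.random.default_rng(0)
        m = sk.BeadModel(rng.uniform(-40, 40, (50, 3)))
        write_bead_model(m, tmp_path / "m.pdb")
        back = read_bead_model(tmp_path / "m.pdb")
        assert len(back) == 50
        assert np.abs(back.coords - m.coords).max() <= 1e-3
        assert back.bead_diameter == pytest.approx(3.8)

    def test_c2_symmetry_survives_roundtrip(self, tmp_path):
        m = sk.generate_shape(
            sk.ShapeSpec(kind="c2_dimer", n_beads=60, domain_radii=(10.0, 10.0)), seed=1
        )
        write_bead_model(m, tmp_path / "d.pdb")
        back = read_bead_model(tmp_path / "d.pdb")
        assert back.symmetry is not None
        assert back.satisfies_c2(1e-3)

    def test_header_only_file_errors(self, tmp_path):
        f = tmp_path / "h.pdb"
        f.write_text("HEADER    NOTHING\nREMARK 1\nEND\n")
        with pytest.raises(ValueError, match="no atom records"):
            read_bead_model(f)

    def test_crystal_style_pdb_record_count(self, tmp_path):
        # generic protein-like ATOM records; count checked against an
        # independent parser (biopython) rather than our own writer
        lines = []
        rng = np.random.default_rng(3)
        names = ["N", "CA", "C", "O"]
        serial = 1
        for res in range(1, 8):
            for name in names:
                x, y, z = rng.uniform(-9, 9, 3)
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s}ALA A{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 10.00           "
                    f"{name[0]}"
                )
                serial += 1
        f = tmp_path / "xtal.pdb"
        f.write_text("\n".join(lines) + "\nEND\n")

        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("x", str(f))
        n_ref = sum(1 for _ in structure.get_atoms())
        m = read_bead_model(f)
        assert len(m) == n_ref == 28


class TestBeadModel:
    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            sk.BeadModel(np.empty((0, 3)))

    def test_rejects_broken_c2_annotation(self):
        coords = [[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]]
        with pytest.raises(ValueError, match="C2"):
            sk.BeadModel(coords, symmetry=sk.C2Symmetry())

    def test_rg_of_two_points(self):
        m = sk.BeadModel([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        assert m.radius_of_gyration() == pytest.approx(5.0)
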