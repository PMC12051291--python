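import numpy as np
import pytest

from ptmbind.structures_io import (
    StructureError,
    chain_sequence,
    extract_ligands,
    read_component_atom_order,
    read_structure,
    write_structure,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.056   2.799   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.556   2.570   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.301   3.676   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.753   3.606   0.000  1.00  0.00           C
ATOM      9  C   SER A   3       8.343   5.007   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.500   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.700   0.200   0.000  0.40  0.00           C
ATOM      4  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""

HETERO_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    4  C1  NAP A 101      10.000   5.000   0.000  1.00  0.00           C
HETATM    5  N1  NAP A 101      11.400   5.000   0.000  1.00  0.00           N
HETATM    6  C1  NAP A 102      20.000   5.000   0.000  1.00  0.00           C
HETATM    7  N1  NAP A 102      21.400   5.000   0.000  1.00  0.00           N
HETATM    8  O   HOH A 201      15.000  15.000   0.000  1.00  0.00           O
HETATM    9  O   HOH A 202      16.000  15.000   0.000  1.00  0.00           O
HETATM   10 MG    MG A 301       5.000  10.000   0.000  1.00  0.00          MG
END
"""

MSE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

CCD_CIF = """\
data_TOY
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
TOY C1 C
TOY N1 N
TOY O1 O
TOY H1 H
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        s = read_structure(_write(tmp_path, "m.pdb", MINIMAL_PDB))
        assert len(s.chains) == 1
        assert len(s.chains[0].residues) == 3
        assert sum(1 for _ in s.iter_atoms()) == 9

    def test_pdb_mmcif_equivalence(self, toy):
        """The same model stored as PDB and mmCIF parses identically."""
        s_pdb = read_structure(toy.paths["pdb"])
        s_cif = read_structure(toy.paths["cif"])
        a_pdb = sorted((a.residue_key, a.name) for a in s_pdb.iter_atoms())
        a_cif = sorted((a.residue_key, a.name) for a in s_cif.iter_atoms())
        assert a_pdb == a_cif
        xyz_pdb = {(a.residue_key, a.name): a.coord for a in s_pdb.iter_atoms()}
        for a in s_cif.iter_atoms():
            assert np.allclose(a.coord, xyz_pdb[(a.residue_key, a.name)],
                               atol=1e-3)

    def test_altloc_highest_occupancy_retained(self, tmp_path):
        s = read_structure(_write(tmp_path, "alt.pdb", ALTLOC_PDB))
        res = s.chains[0].residues[0]
        assert len(res.atoms) == 3  # N, one CA conformer, C
        ca = res.atom("CA")
        assert np.allclose(ca.coord, [1.5, 0.0, 0.0], atol=1e-3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureError, match="no such file"):
            read_structure(tmp_path / "absent.pdb")

    def test_garbage_file(self, tmp_path):
        p = _write(tmp_path, "bad.pdb", "this is not a structure\n")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_roundtrip_preserves_names_keys_coords(self, toy, tmp_path):
        s = read_structure(toy.paths["pdb"])
        out = tmp_path / "rt.pdb"
        write_structure(s, out)
        s2 = read_structure(out)
        atoms1 = {(a.residue_key, a.name): a.coord for a in s.iter_atoms()}
        atoms2 = {(a.residue_key, a.name): a.coord for a in s2.iter_atoms()}
        assert atoms1.keys() == atoms2.keys()
        for k in atoms1:
            assert np.allclose(atoms1[k], atoms2[k], atol=1e-3)


class TestExtractLigands:
    def test_copies_and_exclusions(self, tmp_path):
        s = read_structure(_write(tmp_path, "h.pdb", HETERO_PDB))
        ligs = extract_ligands(s)
        assert [(l.comp_id, l.copy_key) for l in ligs] == [
            ("NAP", ("A", 101)), ("NAP", ("A", 102))
        ]
        with_ions = extract_ligands(s, exclude_ions=False)
        assert {l.comp_id for l in with_ions} == {"NAP", "MG"}
        assert extract_ligands(s, exclude={"NAP"}) == []

    def test_never_returns_water(self, tmp_path):
        s = read_structure(_write(tmp_path, "h.pdb", HETERO_PDB))
        for lig in extract_ligands(s, exclude_ions=False):
            assert lig.comp_id not in {"HOH", "WAT"}
        total_het = sum(1 for a in s.iter_atoms() if a.is_hetero)
        total_lig = sum(len(l.atoms) for l in extract_ligands(s, exclude_ions=False))
        assert total_lig <= total_het

    def test_no_hetero_groups(self, tmp_path):
        s = read_structure(_write(tmp_path, "m.pdb", MINIMAL_PDB))
        assert extract_ligands(s) == []


class TestChainSequence:
    def test_three_residue_chain(self, tmp_path):
        s = read_structure(_write(tmp_path, "m.pdb", MINIMAL_PDB))
        cs = chain_sequence(s, "A")
        assert cs.sequence == "AGS"
        assert cs.index == {1: ("A", 1, ""), 2: ("A", 2, ""), 3: ("A", 3, "")}

    def test_mse_maps_to_met(self, tmp_path):
        s = read_structure(_write(tmp_path, "mse.pdb", MSE_PDB))
        assert chain_sequence(s, "A").sequence == "AMG"

    def test_missing_chain_names_available(self, tmp_path):
        s = read_structure(_write(tmp_path, "m.pdb", MINIMAL_PDB))
        with pytest.raises(StructureError, match="available.*A"):
            chain_sequence(s, "Z")

    def test_length_matches_index(self, toy):
        s = read_structure(toy.paths["pdb"])
        cs = chain_sequence(s, "A")
        assert len(cs.sequence) == len(cs.index)


class TestComponentAtomOrder:
    def test_sdf_order_and_hydrogen_exclusion(self, toy):
        """The fixture SDF carries two trailing H atoms; only heavy atoms
        appear in the canonical order, in file order."""
        order = read_component_atom_order(toy.paths["sdf"])
        assert order.atom_names == toy.manifest["ligand_atom_names"]
        assert order.elements == toy.manifest["ligand_elements"]
        assert not any(e == "H" for e in order.elements)

    def test_ccd_component(self, tmp_path):
        p = _write(tmp_path, "TOY.cif", CCD_CIF)
        order = read_component_atom_order(p)
        assert order.comp_id == "TOY"
        assert order.atom_names == ["C1", "N1", "O1"]  # H1 dropped

    def test_duplicate_names_rejected(self, tmp_path):
        bad = CCD_CIF.replace("TOY N1 N", "TOY C1 N")
        with pytest.raises(StructureError, match="duplicate"):
            read_component_atom_order(_write(tmp_path, "BAD.cif", bad))

    def test_empty_component_rejected(self, tmp_path):
        empty = "data_EMP\nloop_\n_chem_comp_atom.comp_id\n" \
                "_chem_comp_atom.atom_id\n_chem_comp_atom.type_symbol\n" \
                "EMP H1 H\n"
        with pytest.raises(StructureError):
            read_component_atom_order(_write(tmp_path, "EMP.cif", empty))
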