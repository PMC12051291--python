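import numpy as np
import pytest

from ptmbind import FixtureSpec, make_toy_complex
from ptmbind.structures_io import Atom, Chain, Residue, Structure, extract_ligands


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Default toy complex written to disk: sites planted at 8 and 12 Å."""
    outdir = tmp_path_factory.mktemp("toy")
    toy = make_toy_complex(FixtureSpec(seed=1), outdir)
    return toy


@pytest.fixture(scope="session")
def toy(toy_dir):
    return toy_dir


@pytest.fixture(scope="session")
def binding_toy():
    """Toy complex whose ligand makes genuine <5 Å interface contacts."""
    spec = FixtureSpec(
        seed=2,
        planted_sites=[
            (10, "S", "Phosphorylation", 3.0),
            (14, "K", "Acetylation", 4.0),
            (18, "T", "Phosphorylation", 8.0),
        ],
    )
    return make_toy_complex(spec)


def build_structure(protein_xyz, ligand_xyz, ligand_elements=None,
                    comp_id="LIG"):
    """Hand-built minimal complex: one CA-like atom per protein point."""
    residues = []
    for i, xyz in enumerate(protein_xyz, start=1):
        key = ("A", i, "")
        residues.append(
            Residue("GLY", key, [Atom("CA", "C", np.asarray(xyz, float), key)])
        )
    elements = ligand_elements or ["C"] * len(ligand_xyz)
    counters: dict[str, int] = {}
    lig_atoms = []
    key = ("X", 1, "")
    for e, xyz in zip(elements, ligand_xyz):
        counters[e] = counters.get(e, 0) + 1
        lig_atoms.append(
            Atom(f"{e}{counters[e]}", e, np.asarray(xyz, float), key, True)
        )
    lig_res = Residue(comp_id, key, lig_atoms, is_hetero=True)
    s = Structure("manual", [Chain("A", residues), Chain("X", [lig_res])])
    s.ligands = extract_ligands(s)
    return s
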