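"""Macromolecular structure I/O and ligand extraction.

Reads PDB/mmCIF files (via gemmi) into a light-weight in-memory model that
keeps only what downstream geometry needs: heavy atoms with names, elements
and coordinates, grouped into residues and chains, plus ligand instances
(hetero components that are neither water nor, by default, monoatomic ions).

Policies applied uniformly at read time:

* hydrogens are dropped — every distance computed downstream is heavy-atom;
* alternate locations are resolved to the highest-occupancy conformer, ties
  broken by altloc letter order;
* author residue numbering and insertion codes are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "LigandInstance",
    "ChainSequence",
    "ComponentAtomOrder",
    "StructureError",
    "read_structure",
    "write_structure",
    "extract_ligands",
    "chain_sequence",
    "read_component_atom_order",
    "WATER_NAMES",
    "MONOATOMIC_IONS",
]


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


#: three-letter -> one-letter code for the 20 standard amino acids
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: common modified residues mapped to their parent standard residue.
#: Anything not listed here and not standard becomes 'X', and 'X' never
#: counts as identical in sequence-identity checks.
NONSTANDARD_PARENT = {
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "OCS": "C", "CME": "C", "KCX": "K", "MLY": "K", "M3L": "K",
    "ALY": "K", "HYP": "P", "PCA": "E", "FME": "M", "CGU": "E",
    "SAC": "S", "CSD": "C", "MLZ": "K", "HIC": "H", "NEP": "H",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})

#: monoatomic ions excluded from ligand extraction by default
MONOATOMIC_IONS = frozenset({
    "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "CU1",
    "CO", "NI", "CD", "HG", "LI", "SR", "CS", "BA", "RB", "IOD", "BR",
    "F", "YB", "PT", "AU", "AG", "TL", "PB", "MO", "SE", "NI2", "AL",
})

_HYDROGENS = {"H", "D", "T"}


@dataclass
class Atom:
    """One heavy atom: label, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,)
    residue_key: tuple[str, int, str]  # (chain id, residue number, icode)
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(
                f"atom {self.name!r}: coordinate must be 3 finite components"
            )
        if not self.name or not self.element:
            raise StructureError("atom name and element must be non-empty")


@dataclass
class Residue:
    name: str
    key: tuple[str, int, str]
    atoms: list[Atom]
    is_hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class LigandInstance:
    """One bound copy of a small-molecule component."""

    comp_id: str
    copy_key: tuple[str, int]  # (chain id, residue number)
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"ligand {self.comp_id}: no atoms")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise StructureError(
                f"ligand {self.comp_id}{self.copy_key}: duplicate atom names"
            )

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Structure:
    """Parsed macromolecular model: ordered chains of residues plus ligands."""

    id: str
    chains: list[Chain]
    source_format: str = "PDB"
    ligands: list[LigandInstance] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise StructureError(
            f"no chain {chain_id!r}; available: {[c.id for c in self.chains]}"
        )

    def iter_atoms(self):
        for ch in self.chains:
            for res in ch.residues:
                yield from res.atoms

    def protein_atoms(self) -> list[Atom]:
        """Heavy atoms of polymer (non-hetero) residues."""
        out = []
        for ch in self.chains:
            for res in ch.residues:
                if not res.is_hetero:
                    out.extend(res.atoms)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with x -> R x + t applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_chains = []
        for ch in self.chains:
            new_res = []
            for res in ch.residues:
                atoms = [
                    Atom(a.name, a.element, R @ a.coord + t, a.residue_key, a.is_hetero)
                    for a in res.atoms
                ]
                new_res.append(Residue(res.name, res.key, atoms, res.is_hetero))
            new_chains.append(Chain(ch.id, new_res))
        out = Structure(self.id, new_chains, self.source_format)
        out.ligands = extract_ligands(out)
        return out


@dataclass
class ChainSequence:
    """One-letter sequence of a chain with a 1-based position -> residue-key index."""

    chain_id: str
    sequence: str
    index: dict[int, tuple[str, int, str]]

    def __post_init__(self) -> None:
        assert len(self.sequence) == len(self.index)


@dataclass
class ComponentAtomOrder:
    """Canonical heavy-atom names of a chemical component, in reference order."""

    comp_id: str
    atom_names: list[str]
    elements: list[str]

    def __post_init__(self) -> None:
        if not self.atom_names:
            raise StructureError(f"component {self.comp_id}: no heavy atoms")
        if len(set(self.atom_names)) != len(self.atom_names):
            raise StructureError(f"component {self.comp_id}: duplicate atom names")

    def __len__(self) -> int:
        return len(self.atom_names)


def _is_water(name: str) -> bool:
    return name.upper() in WATER_NAMES


def _pick_conformer(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties broken by altloc letter order."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def _coor_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return gemmi.CoorFormat.Pdb
    if suffix in (".cif", ".mmcif"):
        return gemmi.CoorFormat.Mmcif
    return gemmi.CoorFormat.Detect


def read_structure(path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens are dropped, altlocs resolved to the highest-occupancy
    conformer, waters kept as residues but never offered as ligands.

    Parameters
    ----------
    path : filesystem path
    fmt : ``"auto"`` (extension-based), ``"pdb"`` or ``"mmcif"``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(path, fmt))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    src = "mmCIF" if _coor_format(path, fmt) == gemmi.CoorFormat.Mmcif else "PDB"

    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            key = (gchain.name, gres.seqid.num, icode)
            if gres.het_flag in ("A", "H"):
                het = gres.het_flag == "H"
            else:  # minimal files without group_PDB: fall back to name tables
                het = (
                    gres.name not in AA3_TO_1
                    and gres.name not in NONSTANDARD_PARENT
                )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.name.upper() in _HYDROGENS or ga.is_hydrogen():
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, alts in by_name.items():
                ga = _pick_conformer(alts)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name.upper() or "X",
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        residue_key=key,
                        is_hetero=het,
                    )
                )
            if atoms:
                residues.append(Residue(gres.name, key, atoms, het))
        if residues:
            keys = [r.key for r in residues]
            if len(set(keys)) != len(keys):
                raise StructureError(
                    f"{path.name}: duplicate residue keys in chain {gchain.name}"
                )
            chains.append(Chain(gchain.name, residues))

    if not chains:
        raise StructureError(f"{path.name}: structure contains no heavy atoms")
    out = Structure(id=st.name or path.stem, chains=chains, source_format=src)
    out.ligands = extract_ligands(out)
    return out


def extract_ligands(
    s: Structure,
    exclude: set[str] | frozenset[str] | None = None,
    exclude_ions: bool = True,
) -> list[LigandInstance]:
    """Hetero components of ``s`` that qualify as small-molecule ligands.

    Waters are always excluded; monoatomic ions are excluded unless
    ``exclude_ions=False``; ``exclude`` adds component codes to skip.
    Each bound copy is returned as a separate :class:`LigandInstance`.
    """
    skip = {c.upper() for c in (exclude or set())}
    out: list[LigandInstance] = []
    for ch in s.chains:
        for res in ch.residues:
            if not res.is_hetero or _is_water(res.name):
                continue
            comp = res.name.upper()
            if comp in skip:
                continue
            if exclude_ions and comp in MONOATOMIC_IONS:
                continue
            out.append(
                LigandInstance(
                    comp_id=comp,
                    copy_key=(ch.id, res.key[1]),
                    atoms=list(res.atoms),
                )
            )
    return out


def chain_sequence(s: Structure, chain_id: str) -> ChainSequence:
    """One-letter sequence of the observed polymer residues of a chain.

    Nonstandard residues are mapped through a parent-component table
    (MSE→M, SEP→S, ...) or 'X'; hetero groups that are not amino acids
    (ligands, waters) are skipped. The returned index maps 1-based sequence
    position to the residue key.
    """
    ch = s.chain(chain_id)
    letters: list[str] = []
    index: dict[int, tuple[str, int, str]] = {}
    for res in ch.residues:
        name = res.name.upper()
        if name in AA3_TO_1:
            letter = AA3_TO_1[name]
        elif name in NONSTANDARD_PARENT:
            letter = NONSTANDARD_PARENT[name]
        elif not res.is_hetero:
            letter = "X"
        else:
            continue
        letters.append(letter)
        index[len(letters)] = res.key
    if not letters:
        raise StructureError(f"chain {chain_id!r} has no polymer residues")
    return ChainSequence(chain_id, "".join(letters), index)


def write_structure(s: Structure, path, fmt: str = "auto") -> None:
    """Write a :class:`Structure` as PDB (default) or mmCIF via gemmi."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.key[1], res.key[2] or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = 1.0
                ga.b_iso = 0.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    as_cif = fmt.lower() in ("cif", "mmcif") or (
        fmt == "auto" and path.suffix.lower() in (".cif", ".mmcif")
    )
    if as_cif:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def _sdf_atom_order(path: Path) -> ComponentAtomOrder:
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise StructureError(f"cannot parse SDF {path.name}")
    title = ""
    if mol.HasProp("_Name"):
        title = mol.GetProp("_Name").strip()
    comp_id = (title or path.stem).upper()
    counters: dict[str, int] = {}
    names: list[str] = []
    elements: list[str] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol().upper()
        if sym in _HYDROGENS:
            continue
        counters[sym] = counters.get(sym, 0) + 1
        names.append(f"{sym}{counters[sym]}")
        elements.append(sym)
    return ComponentAtomOrder(comp_id, names, elements)


def _ccd_atom_order(path: Path) -> ComponentAtomOrder:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find("_chem_comp_atom.", ["atom_id", "type_symbol"])
    if len(table) == 0:
        raise StructureError(f"{path.name}: no _chem_comp_atom table")
    names, elements = [], []
    for row in table:
        name = gemmi.cif.as_string(row[0])
        sym = gemmi.cif.as_string(row[1]).upper()
        if sym in _HYDROGENS:
            continue
        names.append(name)
        elements.append(sym)
    return ComponentAtomOrder(block.name.upper(), names, elements)


def read_component_atom_order(path) -> ComponentAtomOrder:
    """Canonical heavy-atom name order of one chemical component.

    Accepts an SDF/MOL file or a CCD-style component mmCIF. SDF files carry
    no atom names, so names are synthesized per element in file order
    (C1, C2, N1, O1, ...) — the scheme the synthetic fixtures also use.
    Hydrogens are excluded. Duplicate names or an empty component raise.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if path.suffix.lower() in (".sdf", ".mol"):
        return _sdf_atom_order(path)
    return _ccd_atom_order(path)
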