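"""Self-contained synthetic protein–ligand fixtures with known ground truth.

Builds toy complexes — an idealized helical chain with placeholder side
chains plus a compact multi-atom ligand — in which every quantity the
pipeline later measures is planted analytically:

* PTM sites at *exact* nearest-heavy-atom distances from the ligand (the
  side-chain placeholder CB is placed on the ray from the ligand's extreme
  atom, which makes the minimum over all atom pairs equal the requested
  distance by construction);
* model variants derived from the reference by known perturbations — rigid
  motion (expected post-superposition ligand RMSD 0), uniform coordinate
  jitter of scale σ (expected mean squared per-atom deviation 3σ²), a pure
  ligand shift of d Å (expected no-fit ligand RMSD exactly d), a hinge
  rotation of the C-terminal half (domain-restricted vs whole-chain
  superposition contrast) and a single-residue kick (outlier-rejection
  exercise);
* a PTM table carrying, alongside the planted sites, one duplicated row,
  one residue-type mismatch, one out-of-sequence-range position and one
  non-integer position — the bookkeeping cases a real modification
  database exhibits and the pipeline must exclude loudly.

Everything is seeded; the same spec yields byte-identical files. The
geometry is deliberately idealized (no rotamers, no sterics): all in-scope
computations are pure coordinate geometry, so realism beyond exact
distances buys nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structures_io import (
    AA3_TO_1,
    Atom,
    Chain,
    Residue,
    Structure,
    extract_ligands,
    write_structure,
)

__all__ = ["FixtureSpec", "ToyComplex", "make_toy_complex", "make_model_variant",
           "mean_squared_deviation"]

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å
LIGAND_AXIS_OFFSET = 20.0  # Å from helix axis to ligand centroid


@dataclass
class FixtureSpec:
    """Recipe for one toy complex.

    ``planted_sites`` entries are (reference position, residue letter,
    PTM type, intended nearest-atom distance in Å). Reference numbering is
    the chain numbering shifted by ``ref_flank`` extra N-terminal residues
    present only in the reference sequence, which exercises the
    renumbering stage.
    """

    n_residues: int = 24
    ligand_atoms: int = 6
    seed: int = 0
    accession: str = "P00001"
    comp_id: str = "LIG"
    chain_id: str = "A"
    ref_flank: int = 2
    start_resnum: int = 1
    planted_sites: list[tuple[int, str, str, float]] = field(
        default_factory=lambda: [
            (6, "K", "Acetylation", 3.5),  # genuine binding-site contact
            (10, "S", "Phosphorylation", 8.0),
            (18, "T", "Phosphorylation", 12.0),  # beyond the 10 Å cutoff
        ]
    )
    include_invalid_rows: bool = True

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if self.ligand_atoms < 2:
            raise ValueError("need at least 2 ligand atoms")
        for pos, res, _ptm, dist in self.planted_sites:
            if not (self.ref_flank < pos <= self.ref_flank + self.n_residues):
                raise ValueError(f"planted position {pos} outside the chain")
            if res not in AA1_TO_3:
                raise ValueError(f"unknown residue letter {res!r}")
            if not 1.0 <= dist <= 13.0:
                raise ValueError(
                    f"intended distance {dist} Å infeasible: the backbone "
                    "floor of this geometry is ~14 Å, side chains reach in "
                    "down to 1 Å"
                )


@dataclass
class ToyComplex:
    spec: FixtureSpec
    reference: Structure
    ref_seq: str
    chain_seq: str
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _ligand_coords(n_atoms: int, z_mid: float) -> np.ndarray:
    """Compact planar zig-zag chain, 1.4 Å spacing, centred on the offset."""
    xyz = np.zeros((n_atoms, 3))
    for i in range(n_atoms):
        xyz[i] = (1.2 * i, 0.7 * (i % 2), 0.0)
    xyz -= xyz.mean(axis=0)
    xyz += np.array([LIGAND_AXIS_OFFSET, 0.0, z_mid])
    return xyz


def _ligand_elements(n_atoms: int) -> list[str]:
    elems = ["C", "N", "O"] + ["C"] * max(0, n_atoms - 3)
    return elems[:n_atoms]


def _ligand_names(elements: list[str]) -> list[str]:
    counters: dict[str, int] = {}
    names = []
    for e in elements:
        counters[e] = counters.get(e, 0) + 1
        names.append(f"{e}{counters[e]}")
    return names


def _helix_frame(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.deg2rad(HELIX_TWIST * i)
    ca = np.array([
        HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * i,
    ])
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
    return ca, radial, tangent


def make_toy_complex(spec: FixtureSpec, outdir=None) -> ToyComplex:
    """Build (and optionally write) one toy complex with its manifest.

    When ``outdir`` is given, writes reference.pdb, reference.cif,
    reference.fasta, ptms.tsv, domains.tsv, ligand.sdf and manifest.json.
    """
    rng = np.random.default_rng(spec.seed)

    # --- sequence: random, with planted residue types forced
    letters = sorted(AA1_TO_3)
    chain_letters = [letters[i] for i in rng.integers(0, 20, spec.n_residues)]
    planted_by_chain_pos: dict[int, tuple[int, str, str, float]] = {}
    for site in spec.planted_sites:
        cpos = site[0] - spec.ref_flank  # 1-based chain position
        chain_letters[cpos - 1] = site[1]
        planted_by_chain_pos[cpos] = site
    chain_seq = "".join(chain_letters)
    ref_seq = "M" * spec.ref_flank + chain_seq

    # --- ligand
    z_mid = HELIX_RISE * (spec.n_residues - 1) / 2.0
    lig_xyz = _ligand_coords(spec.ligand_atoms, z_mid)
    lig_elems = _ligand_elements(spec.ligand_atoms)
    lig_names = _ligand_names(lig_elems)
    lig_centroid = lig_xyz.mean(axis=0)

    # --- protein
    residues: list[Residue] = []
    realized: dict[int, float] = {}
    for i in range(spec.n_residues):
        cpos = i + 1
        resnum = spec.start_resnum + i
        key = (spec.chain_id, resnum, "")
        ca, radial, tangent = _helix_frame(i)
        coords = {
            "N": ca - 1.2 * tangent + 0.3 * radial,
            "CA": ca,
            "C": ca + 1.2 * tangent + 0.3 * radial,
            "O": ca + 1.5 * tangent + 0.3 * radial + np.array([0, 0, 1.0]),
        }
        if cpos in planted_by_chain_pos:
            site = planted_by_chain_pos[cpos]
            intended = site[3]
            u = ca - lig_centroid
            u /= np.linalg.norm(u)
            # extreme ligand atom along u: every other ligand atom is then
            # at least `intended` away from the planted CB
            extreme = lig_xyz[np.argmax(lig_xyz @ u)]
            cb = extreme + intended * u
            coords["CB"] = cb
            d = float(np.min(np.linalg.norm(lig_xyz - cb, axis=1)))
            if abs(d - intended) > 1e-6:
                raise RuntimeError("planted geometry failed to realize")
            realized[site[0]] = d
        elif chain_letters[i] != "G":
            coords["CB"] = ca + 1.53 * radial
        name3 = AA1_TO_3[chain_letters[i]]
        atoms = [
            Atom(an, an[0], xyz, key, is_hetero=False)
            for an, xyz in coords.items()
        ]
        residues.append(Residue(name3, key, atoms, is_hetero=False))

    # distance floor of everything that is not a planted side chain
    other_atoms = np.array([
        a.coord
        for r, res in zip(range(1, spec.n_residues + 1), residues)
        for a in res.atoms
        if not (r in planted_by_chain_pos and a.name == "CB")
    ])
    from scipy.spatial.distance import cdist
    floor = float(cdist(other_atoms, lig_xyz).min())
    for pos, site in planted_by_chain_pos.items():
        if site[3] >= floor:
            raise ValueError(
                f"infeasible geometry: intended distance {site[3]} Å is not "
                f"below the backbone floor {floor:.2f} Å"
            )

    lig_key = ("X", 1, "")
    lig_atoms = [
        Atom(n, e, xyz, lig_key, is_hetero=True)
        for n, e, xyz in zip(lig_names, lig_elems, lig_xyz)
    ]
    lig_res = Residue(spec.comp_id, lig_key, lig_atoms, is_hetero=True)
    structure = Structure(
        id=f"toy-{spec.seed}",
        chains=[Chain(spec.chain_id, residues), Chain("X", [lig_res])],
        source_format="PDB",
    )
    structure.ligands = extract_ligands(structure)

    # --- PTM table rows
    rows: list[tuple[str, str, str, str]] = []
    for pos, res, ptm, _d in spec.planted_sites:
        rows.append((spec.accession, str(pos), res, ptm))
    rows.append(tuple(rows[0]))  # duplicate, must collapse
    n_invalid = 0
    if spec.include_invalid_rows:
        p0 = spec.planted_sites[0][0]
        wrong = "A" if ref_seq[p0 - 1] != "A" else "G"
        # ptm_type must differ from any planted row at p0, or the dedup
        # key (accession, position, type) would swallow this row
        rows.append((spec.accession, str(p0), wrong, "Methylation"))
        rows.append((spec.accession, str(len(ref_seq) + 50), "K",
                     "Ubiquitination"))  # beyond the sequence
        rows.append((spec.accession, "abc", "S", "Phosphorylation"))
        n_invalid = 3

    pivot = spec.ref_flank + spec.n_residues // 2
    domains = [
        ("D1", spec.accession, f"{spec.chain_id}:1-{pivot}"),
        ("D2", spec.accession,
         f"{spec.chain_id}:{pivot + 1}-{spec.ref_flank + spec.n_residues}"),
    ]

    manifest = {
        "spec": asdict(spec),
        "ref_seq": ref_seq,
        "chain_seq": chain_seq,
        "planted_distances": {str(p): d for p, d in realized.items()},
        "backbone_floor": floor,
        "hinge_pivot_ref_pos": pivot,
        "ptm_rows_written": len(rows),
        "ptm_rows_invalid": n_invalid,
        "ptm_rows_duplicate": 1,
        # duplicates collapse and the non-integer row is rejected at read
        # time; the mismatch and out-of-range rows survive reading but must
        # fail validation, leaving exactly the planted sites valid
        "expected_unique_sites": len(spec.planted_sites)
        + (2 if spec.include_invalid_rows else 0),
        "expected_valid_sites": len(spec.planted_sites),
        "ligand_atom_names": lig_names,
        "ligand_elements": lig_elems,
    }

    toy = ToyComplex(spec, structure, ref_seq, chain_seq, manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pdb": outdir / "reference.pdb",
            "cif": outdir / "reference.cif",
            "fasta": outdir / "reference.fasta",
            "ptms": outdir / "ptms.tsv",
            "domains": outdir / "domains.tsv",
            "sdf": outdir / "ligand.sdf",
            "manifest": outdir / "manifest.json",
        }
        write_structure(structure, paths["pdb"])
        write_structure(structure, paths["cif"], fmt="mmcif")
        paths["fasta"].write_text(f">{spec.accession}\n{ref_seq}\n")
        with open(paths["ptms"], "w") as fh:
            fh.write("accession\tposition\tresidue\tptm_type\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        with open(paths["domains"], "w") as fh:
            fh.write("domain_id\taccession\tranges\n")
            for row in domains:
                fh.write("\t".join(row) + "\n")
        _write_sdf(paths["sdf"], spec.comp_id, lig_elems, lig_xyz)
        paths["manifest"].write_text(json.dumps(manifest, indent=2))
        toy.paths = paths
    return toy


def _write_sdf(path: Path, comp_id: str, elements: list[str],
               xyz: np.ndarray) -> None:
    """SDF with the ligand heavy atoms in canonical order plus two trailing
    hydrogens (readers must skip them)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    all_elems = list(elements) + ["H", "H"]
    for e in all_elems:
        mol.AddAtom(Chem.Atom(e))
    conf = Chem.Conformer(len(all_elems))
    h_anchor = xyz[0]
    coords = list(xyz) + [h_anchor + (1.0, 0, 0), h_anchor + (0, 1.0, 0)]
    for i, c in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, c)))
    mol.AddConformer(conf)
    m = mol.GetMol()
    m.SetProp("_Name", comp_id)
    Chem.MolToMolFile(m, str(path), kekulize=False)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_model_variant(
    reference: Structure,
    perturbation: dict,
    seed: int = 0,
    outpath=None,
) -> tuple[Structure, dict]:
    """Derive a model structure from a reference by a known perturbation.

    ``perturbation`` is a dict with a ``kind`` key:

    * ``{"kind": "none"}`` — identical copy.
    * ``{"kind": "rigid", "angle_deg": optional, "translation": optional}``
      — whole-complex rigid motion (random from seed when unspecified);
      expected ligand RMSD after superposition: 0.
    * ``{"kind": "jitter", "sigma": σ}`` — i.i.d. Gaussian noise per
      coordinate on every atom; expected mean squared per-atom deviation
      3σ² (χ² sampling spread recorded in the manifest).
    * ``{"kind": "ligand_shift", "d": d}`` — translate the ligand(s) only;
      expected no-fit ligand RMSD exactly d.
    * ``{"kind": "hinge", "angle_deg": a, "pivot_chain_pos": p}`` — rotate
      residues at chain position >= p about an axis through the pivot CA;
      ligand and N-terminal half stay put.
    * ``{"kind": "residue_kick", "chain_pos": p, "d": d}`` — displace one
      residue's atoms by d Å.
    """
    rng = np.random.default_rng(seed)
    kind = perturbation.get("kind", "none")
    model = reference.transformed(np.eye(3), np.zeros(3))  # deep copy
    model.id = f"{reference.id}-{kind}"
    manifest: dict = {"kind": kind, "seed": seed}

    if kind == "none":
        manifest["expected_ligand_rmsd"] = 0.0
    elif kind == "rigid":
        if "angle_deg" in perturbation:
            angle = np.deg2rad(perturbation["angle_deg"])
            axis = _unit(np.asarray(perturbation.get("axis", (0, 0, 1.0)), float))
            R = Rotation.from_rotvec(angle * axis).as_matrix()
        else:
            R = _random_rotation(rng)
        t = np.asarray(
            perturbation.get("translation", rng.uniform(-10, 10, 3)), float
        )
        model = model.transformed(R, t)
        model.id = f"{reference.id}-rigid"
        manifest["expected_ligand_rmsd"] = 0.0
        manifest["rotation"] = R.tolist()
        manifest["translation"] = t.tolist()
    elif kind == "jitter":
        sigma = float(perturbation["sigma"])
        for a in model.iter_atoms():
            a.coord = a.coord + rng.normal(0.0, sigma, 3)
        manifest["sigma"] = sigma
        manifest["expected_mean_squared_deviation"] = 3 * sigma**2
    elif kind == "ligand_shift":
        d = float(perturbation["d"])
        direction = perturbation.get("direction")
        u = _unit(np.asarray(direction, float)) if direction is not None \
            else _unit(rng.normal(size=3))
        shift = d * u
        for ch in model.chains:
            for res in ch.residues:
                if res.is_hetero:
                    for a in res.atoms:
                        a.coord = a.coord + shift
        manifest["expected_ligand_rmsd"] = d
        manifest["shift"] = shift.tolist()
    elif kind == "hinge":
        angle = np.deg2rad(float(perturbation.get("angle_deg", 30.0)))
        pivot = int(perturbation["pivot_chain_pos"])
        chain = model.chains[0]
        pivot_ca = chain.residues[pivot - 1].atom("CA").coord.copy()
        R = Rotation.from_rotvec(angle * np.array([1.0, 0, 0])).as_matrix()
        for res in chain.residues[pivot - 1:]:
            for a in res.atoms:
                a.coord = R @ (a.coord - pivot_ca) + pivot_ca
        manifest["pivot_chain_pos"] = pivot
        manifest["angle_deg"] = float(perturbation.get("angle_deg", 30.0))
        manifest["expected_ligand_rmsd"] = 0.0  # under N-domain-restricted fit
    elif kind == "residue_kick":
        pos = int(perturbation["chain_pos"])
        d = float(perturbation.get("d", 20.0))
        u = _unit(rng.normal(size=3))
        chain = model.chains[0]
        for a in chain.residues[pos - 1].atoms:
            a.coord = a.coord + d * u
        manifest["chain_pos"] = pos
        manifest["d"] = d
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")

    model.ligands = extract_ligands(model)
    if outpath is not None:
        write_structure(model, outpath)
        manifest["path"] = str(outpath)
    return model, manifest


def mean_squared_deviation(a: Structure, b: Structure) -> float:
    """Mean squared per-atom coordinate deviation over shared atoms.

    Atoms matched by (residue key, atom name); used to verify the jitter
    perturbation against its 3σ² expectation.
    """
    bmap = {(at.residue_key, at.name): at.coord for at in b.iter_atoms()}
    sq = [
        float(np.sum((at.coord - bmap[(at.residue_key, at.name)]) ** 2))
        for at in a.iter_atoms()
        if (at.residue_key, at.name) in bmap
    ]
    if not sq:
        raise ValueError("no shared atoms")
    return float(np.mean(sq))
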