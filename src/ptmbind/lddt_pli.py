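"""Interface-contact conservation score (lDDT-PLI) between a reference
complex and a model.

Interface atoms are the protein and ligand heavy atoms of the *reference*
complex lying within 5 Å (inclusive) of any atom of the binding partner.
For every pair of interface atoms the absolute difference Δd between the
reference inter-atom distance and the corresponding model distance is
scored with a stepped function f — full credit below 0.5 Å, then 0.8, 0.6
and 0.4 for the 0.5–1, 1–2 and 2–4 Å bands, zero at 4 Å and beyond (lower
band edges inclusive). f values are averaged per interface atom over its
pairs, and the score is the mean of the per-atom averages:

    lDDT-PLI = (1/N) Σ_i (1/M_i) Σ_j f(|d_ij^pred − d_ij^ref|)

All distances are internal, so the score is invariant to rigid motion of
the model and no superposition is required. By default every unordered
pair of interface atoms contributes to both of its members
(protein–protein pairs included); ``mode="ligand_contacts"`` restricts
pairs to protein–ligand ones. Unlike the CASP-style lDDT there is no
inclusion-radius ceiling on pairs and no stereochemical checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .seq_align import global_align
from .structures_io import LigandInstance, Structure, StructureError, chain_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AtomId",
    "InterfaceAtomSet",
    "InterfaceScore",
    "select_interface_atoms",
    "threshold_score",
    "build_model_correspondence",
    "lddt_pli",
    "score_to_json",
]

DEFAULT_INTERFACE_CUTOFF = 5.0  # Å

#: ("protein", residue key, atom name) or ("ligand", copy key, atom name)
AtomId = tuple


@dataclass
class InterfaceAtomSet:
    atoms: list[AtomId]
    cutoff: float
    coords: np.ndarray  # reference coordinates, one row per atom
    is_ligand: np.ndarray  # bool mask aligned with atoms


@dataclass
class InterfaceScore:
    score: float
    per_atom: dict[AtomId, float]
    n_atoms: int
    #: per-pair audit trail: (atom i, atom j, d_ref, d_pred, delta, f)
    ledger: list[tuple[AtomId, AtomId, float, float, float, float]]
    parameters: dict = field(default_factory=dict)


def threshold_score(delta_d: float) -> float:
    """Stepped distance-agreement score f(Δd) for one interface-atom pair.

    Δd is an absolute distance difference in Å and must be non-negative.
    """
    if delta_d < 0:
        raise ValueError(f"Δd is an absolute difference; got {delta_d}")
    if delta_d < 0.5:
        return 1.0
    if delta_d < 1.0:
        return 0.8
    if delta_d < 2.0:
        return 0.6
    if delta_d < 4.0:
        return 0.4
    return 0.0


def _f_array(delta: np.ndarray) -> np.ndarray:
    return np.select(
        [delta < 0.5, delta < 1.0, delta < 2.0, delta < 4.0],
        [1.0, 0.8, 0.6, 0.4],
        default=0.0,
    )


def select_interface_atoms(
    ref: Structure,
    lig: LigandInstance,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> InterfaceAtomSet:
    """Interface atoms of a reference complex, boundary inclusive.

    Protein heavy atoms within ``cutoff`` of any ligand atom, plus ligand
    atoms within ``cutoff`` of any protein atom. Raises if the interface is
    empty (the ligand is not bound at this cutoff).
    """
    prot_atoms = ref.protein_atoms()
    if not prot_atoms:
        raise StructureError("reference has no protein atoms")
    P = np.array([a.coord for a in prot_atoms])
    L = lig.coords()
    D = cdist(P, L)
    prot_mask = (D <= cutoff).any(axis=1)
    lig_mask = (D <= cutoff).any(axis=0)
    if not prot_mask.any() or not lig_mask.any():
        raise StructureError(
            f"empty interface: no atom pair within {cutoff} Å — "
            f"ligand {lig.comp_id}{lig.copy_key} is not bound"
        )
    atoms: list[AtomId] = []
    coords: list[np.ndarray] = []
    flags: list[bool] = []
    for a, keep in zip(prot_atoms, prot_mask):
        if keep:
            atoms.append(("protein", a.residue_key, a.name))
            coords.append(a.coord)
            flags.append(False)
    for a, keep in zip(lig.atoms, lig_mask):
        if keep:
            atoms.append(("ligand", lig.copy_key, a.name))
            coords.append(a.coord)
            flags.append(True)
    return InterfaceAtomSet(atoms, cutoff, np.array(coords), np.array(flags))


def build_model_correspondence(
    ref: Structure,
    model: Structure,
    lig_comp: str,
    model_copy_key: tuple[str, int] | None = None,
) -> dict[AtomId, np.ndarray]:
    """Map reference atom ids to model coordinates.

    Protein atoms are matched chain-by-chain through a global sequence
    alignment (same-id chains first, else positional) and then by atom name
    within each aligned residue pair. Ligand atoms are matched by name
    inside the model copy of ``lig_comp`` (``model_copy_key`` selects among
    several; the model ligand must already carry canonical names — apply
    :func:`~ptmbind.ligand_rmsd.harmonize_atom_names` first if needed).
    """
    corr: dict[AtomId, np.ndarray] = {}
    model_chain_ids = [c.id for c in model.chains]
    for rch in ref.chains:
        if all(res.is_hetero for res in rch.residues):
            continue
        mcid = rch.id if rch.id in model_chain_ids else model_chain_ids[0]
        try:
            rseq = chain_sequence(ref, rch.id)
            mseq = chain_sequence(model, mcid)
        except StructureError:
            continue
        aln = global_align(rseq.sequence, mseq.sequence)
        mres_by_key = {r.key: r for r in model.chain(mcid).residues}
        rres_by_key = {r.key: r for r in ref.chain(rch.id).residues}
        for pr, pm in aln.pairs:
            rres = rres_by_key.get(rseq.index[pr])
            mres = mres_by_key.get(mseq.index[pm])
            if rres is None or mres is None:
                continue
            mat = {a.name: a for a in mres.atoms}
            for a in rres.atoms:
                if a.name in mat:
                    corr[("protein", rres.key, a.name)] = mat[a.name].coord

    lig_comp = lig_comp.upper()
    ref_copies = [l for l in ref.ligands if l.comp_id == lig_comp]
    model_copies = [l for l in model.ligands if l.comp_id == lig_comp]
    if not ref_copies or not model_copies:
        raise StructureError(f"component {lig_comp} missing from ref or model")
    if model_copy_key is not None:
        model_copies = [l for l in model_copies if l.copy_key == model_copy_key]
        if not model_copies:
            raise StructureError(f"no model copy {model_copy_key} of {lig_comp}")
    for rlig, mlig in zip(ref_copies, model_copies):
        mat = {a.name: a for a in mlig.atoms}
        for a in rlig.atoms:
            if a.name in mat:
                corr[("ligand", rlig.copy_key, a.name)] = mat[a.name].coord
    return corr


def lddt_pli(
    ref: Structure,
    model: Structure,
    lig_comp: str,
    corr: dict[AtomId, np.ndarray] | None = None,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
    mode: str = "all_pairs",
    strict: bool = True,
    ref_copy_key: tuple[str, int] | None = None,
) -> InterfaceScore:
    """Interface-contact conservation score of ``model`` against ``ref``.

    The interface is defined on the reference only. ``mode="all_pairs"``
    scores every unordered interface-atom pair for both members;
    ``mode="ligand_contacts"`` keeps only protein–ligand pairs. With
    ``strict=True`` an interface atom without a model correspondent is an
    error; lenient mode drops it with a logged count.
    """
    lig_comp = lig_comp.upper()
    copies = [l for l in ref.ligands if l.comp_id == lig_comp]
    if not copies:
        raise StructureError(f"component {lig_comp} absent from the reference")
    if ref_copy_key is not None:
        copies = [l for l in copies if l.copy_key == ref_copy_key]
        if not copies:
            raise StructureError(f"no reference copy {ref_copy_key}")
    lig = copies[0]
    iface = select_interface_atoms(ref, lig, cutoff)
    if corr is None:
        corr = build_model_correspondence(ref, model, lig_comp)

    keep, missing = [], []
    for idx, aid in enumerate(iface.atoms):
        (keep if aid in corr else missing).append(idx)
    if missing:
        names = [iface.atoms[i] for i in missing]
        if strict:
            raise StructureError(
                f"{len(missing)} interface atom(s) lack a model "
                f"correspondent: {names[:5]}{'...' if len(names) > 5 else ''}"
            )
        logger.warning("dropping %d interface atom(s) without model "
                       "correspondent", len(missing))
    atoms = [iface.atoms[i] for i in keep]
    is_lig = iface.is_ligand[keep]
    ref_xyz = iface.coords[keep]
    mod_xyz = np.array([corr[a] for a in atoms])
    n = len(atoms)
    if n < 2:
        raise StructureError("fewer than two scorable interface atoms")

    d_ref = cdist(ref_xyz, ref_xyz)
    d_mod = cdist(mod_xyz, mod_xyz)
    delta = np.abs(d_mod - d_ref)
    f = _f_array(delta)

    if mode == "all_pairs":
        pair_mask = ~np.eye(n, dtype=bool)
    elif mode == "ligand_contacts":
        pair_mask = is_lig[:, None] != is_lig[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    per_atom: dict[AtomId, float] = {}
    counted = np.zeros(n, bool)
    for i in range(n):
        js = np.nonzero(pair_mask[i])[0]
        if len(js) == 0:
            continue
        per_atom[atoms[i]] = float(f[i, js].mean())
        counted[i] = True
    if not counted.any():
        raise StructureError("no scorable interface-atom pairs")
    score = float(np.mean([per_atom[atoms[i]] for i in range(n) if counted[i]]))

    ledger = []
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if pair_mask[i, j]:
            ledger.append((
                atoms[i], atoms[j],
                float(d_ref[i, j]), float(d_mod[i, j]),
                float(delta[i, j]), float(f[i, j]),
            ))
    return InterfaceScore(
        score=score,
        per_atom=per_atom,
        n_atoms=int(counted.sum()),
        ledger=ledger,
        parameters={
            "cutoff": cutoff, "mode": mode, "strict": strict,
            "lig_comp": lig_comp, "ref_copy_key": list(lig.copy_key),
            "dropped_atoms": len(missing),
        },
    )


def score_to_json(s: InterfaceScore) -> str:
    """Serialize an InterfaceScore (score, per-atom table, pair ledger)."""
    def aid(a: AtomId) -> str:
        kind, key, name = a
        return f"{kind}:{':'.join(str(k) for k in key)}:{name}"

    payload = {
        "score": s.score,
        "n_atoms": s.n_atoms,
        "parameters": s.parameters,
        "per_atom": {aid(a): v for a, v in s.per_atom.items()},
        "pairs": [
            {"i": aid(i), "j": aid(j), "d_ref": dr, "d_pred": dp,
             "delta": dl, "f": fv}
            for i, j, dr, dp, dl, fv in s.ledger
        ],
    }
    return json.dumps(payload, indent=2)
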