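"""No-fit ligand RMSD after protein superposition.

The pose error of a modeled small molecule is the root-mean-square
coordinate difference between the model's ligand and the reference ligand,
paired strictly by atom name and computed without any refitting — the
protein superposition has already placed the model in the reference frame.

Models from tools that emit ligand atoms under arbitrary names but in the
canonical component order are harmonized first: atoms are renamed
positionally against a :class:`~ptmbind.structures_io.ComponentAtomOrder`,
refusing on any count or element mismatch (no best-effort mapping).
Symmetry-equivalent names (ring automorphisms) are deliberately not
canonicalized, so the reported RMSD over-estimates for symmetric ligands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures_io import (
    ComponentAtomOrder,
    LigandInstance,
    Structure,
    StructureError,
)

__all__ = [
    "LigandRMSDReport",
    "harmonize_atom_names",
    "rmsd_no_fit",
    "ligand_rmsd_report",
]


@dataclass
class LigandRMSDReport:
    comp_id: str
    model_copy_key: tuple[str, int]
    reference_copy_key: tuple[str, int]
    rmsd: float
    n_atoms: int
    harmonization: str  # "name-matched" | "order-renamed"
    best_match: bool = False


def harmonize_atom_names(
    lig: LigandInstance, order: ComponentAtomOrder
) -> LigandInstance:
    """Rename ligand atoms positionally to the canonical component names.

    The i-th ligand heavy atom receives the i-th canonical name. Refuses
    outright (no partial renaming) if the atom counts differ or if any
    position's element disagrees with the canonical element.
    """
    if len(lig.atoms) != len(order):
        raise StructureError(
            f"{lig.comp_id}: {len(lig.atoms)} ligand atoms vs "
            f"{len(order)} canonical names — cannot rename positionally"
        )
    for i, (atom, elem) in enumerate(zip(lig.atoms, order.elements), start=1):
        if atom.element.upper() != elem.upper():
            raise StructureError(
                f"{lig.comp_id}: element mismatch at position {i}: "
                f"ligand has {atom.element}, canonical order expects {elem}"
            )
    renamed = [
        type(a)(name, a.element, a.coord.copy(), a.residue_key, a.is_hetero)
        for a, name in zip(lig.atoms, order.atom_names)
    ]
    return LigandInstance(lig.comp_id, lig.copy_key, renamed)


def rmsd_no_fit(a: LigandInstance, b: LigandInstance) -> float:
    """RMS coordinate difference over name-matched atoms, no fitting.

    Requires identical atom-name sets; raises listing the symmetric
    difference otherwise.
    """
    names_a = {at.name: at for at in a.atoms}
    names_b = {at.name: at for at in b.atoms}
    if set(names_a) != set(names_b):
        diff = sorted(set(names_a) ^ set(names_b))
        raise StructureError(
            f"atom-name sets differ between {a.comp_id}{a.copy_key} and "
            f"{b.comp_id}{b.copy_key}: {diff}"
        )
    sq = [
        float(np.sum((names_a[n].coord - names_b[n].coord) ** 2))
        for n in names_a
    ]
    return float(np.sqrt(np.mean(sq)))


def ligand_rmsd_report(
    model: Structure,
    reference: Structure,
    comp_id: str,
    order: ComponentAtomOrder | None = None,
) -> list[LigandRMSDReport]:
    """Per-copy no-fit RMSD between model and reference ligands.

    ``model`` must already be superposed onto ``reference`` — this function
    never refits. Every (model copy x reference copy) combination of
    ``comp_id`` yields one report; when the name sets differ and a canonical
    ``order`` is given, the model copy is renamed positionally first. The
    minimum-RMSD report per model copy is flagged ``best_match``.
    """
    comp_id = comp_id.upper()
    model_copies = [l for l in model.ligands if l.comp_id == comp_id]
    ref_copies = [l for l in reference.ligands if l.comp_id == comp_id]
    if not model_copies:
        raise StructureError(f"component {comp_id} absent from the model")
    if not ref_copies:
        raise StructureError(f"component {comp_id} absent from the reference")

    reports: list[LigandRMSDReport] = []
    for mcopy in model_copies:
        group: list[LigandRMSDReport] = []
        for rcopy in ref_copies:
            m, harmonization = mcopy, "name-matched"
            if {a.name for a in mcopy.atoms} != {a.name for a in rcopy.atoms}:
                if order is None:
                    raise StructureError(
                        f"{comp_id}: atom names differ and no canonical "
                        "order was provided for harmonization"
                    )
                m = harmonize_atom_names(mcopy, order)
                r = rcopy
                if {a.name for a in r.atoms} != {a.name for a in m.atoms}:
                    r = harmonize_atom_names(rcopy, order)
                harmonization = "order-renamed"
                group.append(
                    LigandRMSDReport(
                        comp_id, mcopy.copy_key, rcopy.copy_key,
                        rmsd_no_fit(m, r), len(m.atoms), harmonization,
                    )
                )
                continue
            group.append(
                LigandRMSDReport(
                    comp_id, mcopy.copy_key, rcopy.copy_key,
                    rmsd_no_fit(m, rcopy), len(m.atoms), harmonization,
                )
            )
        best = min(group, key=lambda r: r.rmsd)
        best.best_match = True
        reports.extend(group)
    return reports
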