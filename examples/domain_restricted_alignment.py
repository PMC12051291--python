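"""Domain-restricted superposition when a hinge motion misleads the fit.

A two-domain model whose C-terminal half is rotated 35° about a hinge
cannot be superposed well as a whole — the least-squares fit splits the
error between both halves. Restricting the atom correspondence to the
ligand-binding domain recovers an essentially exact fit of that domain,
and with it the true (zero) ligand-pose error.
"""

from ptmbind import (
    FixtureSpec, make_toy_complex, make_model_variant, align_refine,
    ligand_rmsd_report,
)
from ptmbind.ptm_annotation import parse_range_string

toy = make_toy_complex(FixtureSpec(seed=1))
ref = toy.reference
pivot_ref = toy.manifest["hinge_pivot_ref_pos"]
model, _ = make_model_variant(
    ref, {"kind": "hinge", "angle_deg": 35.0,
          "pivot_chain_pos": pivot_ref - toy.spec.ref_flank},
    seed=0,
)

whole, moved_whole = align_refine(ref, model)
print(f"whole-chain fit:        RMSD {whole.final_rmsd:.3f} Å over "
      f"{whole.pairs_final}/{whole.pairs_initial} pairs")

binding_domain = parse_range_string("D1", toy.spec.accession,
                                    f"A:1-{pivot_ref}")
restricted, moved = align_refine(ref, model, restrict_to=[binding_domain])
print(f"binding-domain-only fit: RMSD {restricted.final_rmsd:.2e} Å over "
      f"{restricted.pairs_final} pairs")

rmsd = ligand_rmsd_report(moved, ref, "LIG")[0].rmsd
print(f"ligand RMSD after the restricted fit: {rmsd:.2e} Å")
print("\nThe hinge contaminates the whole-chain fit; restricting the "
      "correspondence to the domain that binds the ligand isolates the "
      "rigid unit that matters and the ligand pose is recovered exactly.")
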