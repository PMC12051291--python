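"""Superpose a model onto its reference and measure the ligand-pose error.

Two model variants of the same synthetic complex: a whole-complex rigid
motion (a perfectly modeled pose in a different frame) and a 5 Å ligand
shift (a mis-docked pose on a perfect protein). The no-fit ligand RMSD —
computed after sequence-guided protein superposition, pairing atoms
strictly by name, with no refitting — recovers 0 and 5 Å respectively.
"""

from ptmbind import (
    FixtureSpec, make_toy_complex, make_model_variant, align_refine,
    ligand_rmsd_report,
)

toy = make_toy_complex(FixtureSpec(seed=1))
ref = toy.reference

for perturbation in ({"kind": "rigid"}, {"kind": "ligand_shift", "d": 5.0}):
    model, manifest = make_model_variant(ref, perturbation, seed=42)
    result, moved = align_refine(ref, model, max_cycles=5, sd_cutoff=2.0)
    report = ligand_rmsd_report(moved, ref, "LIG")[0]
    print(f"{perturbation['kind']:>12}: protein fit "
          f"{result.final_rmsd:.2e} Å over {result.pairs_final} atom pairs; "
          f"ligand RMSD {report.rmsd:.6f} Å "
          f"(expected {manifest['expected_ligand_rmsd']})")

print("\nThe rigid variant scores ~0: superposition absorbs any global "
      "motion. The shifted variant reports the planted 5 Å exactly — the "
      "protein fit is perfect, so the residual is pure ligand displacement.")
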