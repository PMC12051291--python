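"""Score interface-contact conservation (lDDT-PLI) of noisy models.

Interface atoms are the reference's protein and ligand heavy atoms within
5 Å of the binding partner. Every interface-atom pair's distance change
Δd is scored 1/0.8/0.6/0.4/0 by the stepped function f, averaged per atom
and then over atoms. The score needs no superposition: distances are
internal. An identical model scores exactly 1; increasing coordinate
noise erodes the score.
"""

import numpy as np

from ptmbind import FixtureSpec, make_toy_complex, make_model_variant, lddt_pli

toy = make_toy_complex(FixtureSpec(
    seed=2,
    planted_sites=[(6, "K", "Acetylation", 3.5),
                   (10, "S", "Phosphorylation", 4.0),
                   (14, "T", "Phosphorylation", 8.0)],
))
ref = toy.reference

self_score = lddt_pli(ref, ref, "LIG")
print(f"model == reference: lDDT-PLI = {self_score.score:.3f} over "
      f"{self_score.n_atoms} interface atoms "
      f"({len(self_score.ledger)} scored pairs)")

for sigma in (0.2, 0.5, 1.0):
    scores = []
    for seed in range(10):
        model, _ = make_model_variant(ref, {"kind": "jitter", "sigma": sigma},
                                      seed=seed)
        scores.append(lddt_pli(ref, model, "LIG").score)
    print(f"coordinate noise sigma={sigma:.1f} Å: median lDDT-PLI = "
          f"{np.median(scores):.3f} over 10 models")

print("\nThe score starts at its fixed point 1.0 and degrades "
      "monotonically with noise — larger interface-distance changes fall "
      "into lower-credit bands of f.")
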