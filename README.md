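# ptmbind

Structural context of post-translational modifications (PTMs) at
small-molecule binding sites.

Many PTMs — phosphorylation of Ser/Thr/Tyr, acetylation of Lys,
ubiquitination — sit close enough to a bound drug or cofactor to change
its binding. Given an experimental (or ligand-transplanted) complex, a
modification site table and, optionally, a predicted structure of the
PTM-modified protein, `ptmbind` answers three questions:

1. **Which PTM sites are binding-site-proximal?** A site counts when any
   heavy atom of the modified residue lies within 10 Å (inclusive,
   configurable) of any heavy atom of the small molecule. Sites are first
   validated against the reference (UniProt-style) sequence — rows whose
   residue type or numbering disagree with the reference are excluded and
   logged, duplicates per (accession, position, PTM type) collapsed — and
   the structure chain is renumbered onto reference coordinates by global
   Needleman–Wunsch alignment (BLOSUM62, affine gaps, identity floor
   against chimeric chains). Hits are mapped to structural-domain ranges
   (ECOD-style range strings).

2. **How far does a modeled ligand pose drift?** The model is superposed
   onto the reference by a sequence-guided least-squares rigid fit
   (Kabsch) with up to five refinement cycles that drop atom pairs
   deviating by more than two standard deviations above the mean; the
   correspondence can be restricted to the ligand-binding domain when a
   hinge motion between domains would otherwise dominate. The ligand-pose
   error is then the **no-fit RMSD**: the RMS coordinate difference over
   atoms paired strictly by name, with no refitting. Models whose ligand
   atom names differ from the reference but keep the canonical component
   order are renamed positionally against an SDF/CCD component file.
   Every (model copy × reference copy) pair is reported.

3. **Are the interface contacts conserved?** The **lDDT-PLI** score:
   interface atoms are the reference's protein and ligand heavy atoms
   within 5 Å of the binding partner; for each pair (i, j) of interface
   atoms the distance change Δd = |d_ij^pred − d_ij^ref| is scored

       f(Δd) = 1 (Δd < 0.5 Å), 0.8 (0.5 ≤ Δd < 1), 0.6 (1 ≤ Δd < 2),
               0.4 (2 ≤ Δd < 4), 0 (Δd ≥ 4),

   then lDDT-PLI = (1/N) Σ_i (1/M_i) Σ_j f(Δd_ij). Distances are
   internal, so the score is superposition-free and rigid-motion
   invariant; an identical model scores exactly 1.

A first-class synthetic-data module generates toy complexes in which all
of these quantities are planted analytically (exact site–ligand
distances, known rigid motions, exact ligand shifts, Gaussian jitter with
its 3σ² law, hinge rotations), so the whole pipeline is testable without
downloading anything.

## Worked example

`examples/superpose_and_ligand_rmsd.py` builds a synthetic complex and
two model variants, then runs superposition + no-fit ligand RMSD:

```
       rigid: protein fit 5.28e-15 Å over 118 atom pairs; ligand RMSD 0.000000 Å (expected 0.0)
ligand_shift: protein fit 6.40e-15 Å over 118 atom pairs; ligand RMSD 5.000000 Å (expected 5.0)
```

A whole-complex rigid motion is absorbed by the superposition (ligand
RMSD 0); a planted 5 Å ligand shift on an otherwise perfect protein is
reported exactly. `examples/interface_score.py` shows the interface
score's fixed point and its decay under coordinate noise:

```
model == reference: lDDT-PLI = 1.000 over 4 interface atoms (6 scored pairs)
coordinate noise sigma=0.2 Å: median lDDT-PLI = 1.000 over 10 models
coordinate noise sigma=0.5 Å: median lDDT-PLI = 0.883 over 10 models
coordinate noise sigma=1.0 Å: median lDDT-PLI = 0.717 over 10 models
```

The other examples cover PTM annotation with exclusion bookkeeping
(`annotate_proximal_ptms.py`) and hinge-robust, domain-restricted
superposition (`domain_restricted_alignment.py`).

The same stages are available as a thin CLI for file-based use:

```sh
ptmbind simulate --outdir toy --seed 1 --perturb ligand_shift:d=5
ptmbind annotate --reference toy/reference.pdb --ptms toy/ptms.tsv \
        --fasta toy/reference.fasta --domains toy/domains.tsv --out hits.tsv
ptmbind compare  --reference toy/reference.pdb --model toy/model.pdb \
        --comp-id LIG --out-prefix toy/report
```

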