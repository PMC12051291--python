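# Methods

## Scope and data model

`ptmbind` analyses the structural context of post-translational
modifications (PTMs) near bound small molecules. Its inputs are standard:
PDB or mmCIF structures (reference complexes and, optionally, modeled
structures of the modified protein), a dbPTM-like tab-separated table of
modification sites keyed by accession and 1-based reference-sequence
position, reference sequences in FASTA, domain annotations as ECOD-style
range strings, and SDF/CCD component files that define canonical ligand
atom order.

Structures are parsed with gemmi into a minimal in-memory model (chains →
residues → heavy atoms). Three policies are applied uniformly at read
time and never revisited downstream:

* **hydrogens are dropped** — experimental structures mostly lack them
  and model outputs are inconsistent about them, so every distance in the
  pipeline is heavy-atom;
* **alternate locations** resolve to the highest-occupancy conformer,
  ties broken by altloc letter order;
* **author residue numbering** with insertion codes is preserved;
  sequence positions are 1-based (the convention of UniProt-keyed PTM
  resources).

Ligands are hetero components that are not water (always excluded) and
not in a configurable monoatomic-ion list (excluded by default — the
analysis targets drugs and cofactors). Each bound copy is a separate
instance. Nonstandard residues map to a parent one-letter code through a
small built-in table (MSE→M, SEP→S, TPO→T, PTR→Y, …), otherwise `X`;
`X` never counts as identical in sequence-identity accounting.

## Sequence alignment and renumbering

Structure chains are mapped onto reference numbering by global
Needleman–Wunsch alignment in the Gotoh three-state affine-gap
formulation. Defaults: BLOSUM62 (loaded from Biopython's substitution
matrices; user matrices in NCBI text format are also accepted), gap open
11, gap extend 1, a gap of length L costing `open + L·extend` with
terminal gaps penalized. Traceback ties break in a fixed operator order
(diagonal > up > left; within gap states, close-the-gap first), so
alignments are fully deterministic. Unknown letters are treated as `X`
with zero substitution score, logged.

An alignment identity below a floor (default 0.30) aborts renumbering:
such chains are, in practice, chimeric constructs or paired with the
wrong reference, and must be excluded rather than renumbered. The floor,
rather than entity bookkeeping, is the exclusion mechanism.

## Binding-site-proximal PTMs

A site is first validated: the residue letter at its reference position
must match the reference sequence. Mismatches (`residue_mismatch`) and
positions beyond the sequence (`unmapped`) are excluded from every later
stage, each with a warning log line; rows with non-integer positions are
rejected at parse time; duplicate (accession, position, PTM type) rows
collapse. Counts are therefore conserved and every exclusion is visible.

A valid site is **proximal** to a ligand copy iff the minimum over all
(site-residue heavy atom, ligand heavy atom) distances is ≤ the cutoff,
default 10 Å, boundary inclusive. The residue-side atom set is the whole
residue — the most inclusive defensible reading; the measuring side
("all atoms of the small molecule") is unambiguous. Both the cutoff and
(via the atom model) the convention are configurable. The search uses a
k-d tree over ligand atoms but carries the exact all-pairs contract; the
tests hold it to a dense O(N·M) scan to 1e-9 Å.

Domain assignment is interval containment on parsed range strings
(`"A:12-150,A:200-240"`); a position covered by overlapping domains is
assigned to all of them with a logged ambiguity, a position in none to
no domain.

## Superposition with outlier rejection

Models are superposed on references by a sequence-guided rigid fit:

1. global alignment of the two chain sequences (identity floor applies);
2. atom correspondence: within each aligned residue pair, atoms pair by
   identical name in the chosen scope (all heavy atoms by default;
   backbone-only and CA-only available); unpaired atoms drop;
3. initial least-squares fit via the Kabsch SVD solution with the
   determinant sign corrected, so the rotation is always proper;
4. up to `max_cycles` (default 5) refinement cycles: per-pair deviations
   under the current transform; pairs with deviation > mean +
   `sd_cutoff`·SD (default 2.0) are rejected *as atom pairs*, not whole
   residues; refit; stop early when a cycle rejects nothing or when
   rejection would leave fewer than 10 pairs (the last valid fit kept).

Numerical choices: fewer than 3 pairs or a rank-deficient (collinear)
point set is an error, not a silent degenerate fit; the rejection
threshold is floored at 1e-6 Å so an already-exact fit never sheds pairs
on floating-point noise; the centering in the rejection rule is the mean
deviation (centering at zero is the plausible alternative; the mean is
the stricter and the implemented one).

When two domains of a model hinge relative to the experimental
structure, a whole-chain fit splits the error between the halves. The
correspondence can be restricted to the domain ranges that bind the
ligand (`restrict_to`); restriction is explicit, not auto-detected, and
the whole-vs-restricted RMSD contrast is logged to inform the choice.

## No-fit ligand RMSD

After superposition the ligand-pose error is
`sqrt(mean over name-matched atoms of squared coordinate distance)` —
no refitting of any kind. Atom pairing is strictly by name; name sets
must match exactly or the error lists the symmetric difference.

Models from tools that rename ligand atoms but preserve canonical
component order are harmonized first: the i-th ligand heavy atom takes
the i-th canonical name from an SDF or CCD component file. Renaming is
all-or-nothing — any count or per-position element mismatch refuses
(manual curation, not guessing, is the remedy; automatic graph matching
is out of scope). SDF files carry no atom names, so names for SDF-derived
orders are synthesized per element in file order (C1, C2, N1, …); the
synthetic fixtures use the same scheme so PDB and SDF fixtures agree.

Symmetry-equivalent atom names (ring automorphisms) are deliberately not
canonicalized: pairing is by name/order only, which over-estimates the
RMSD of symmetric ligands. With multiple bound copies, every
(model copy × reference copy) combination is reported and the per-model
minimum flagged best-match, leaving the choice auditable.

## lDDT-PLI

Interface atoms are selected on the **reference only**: protein heavy
atoms within 5 Å (inclusive, configurable) of any ligand atom, plus
ligand atoms within 5 Å of any protein atom. For each unordered pair
(i, j) of interface atoms, Δd = |d_ij^pred − d_ij^ref| is scored by the
stepped function f — 1 below 0.5 Å, then 0.8, 0.6, 0.4 on the bands
[0.5, 1), [1, 2), [2, 4), and 0 at ≥ 4 Å; lower band edges inclusive;
negative input is a caller error. Scores average per atom over its M_i
pairs, then over the N atoms:

    lDDT-PLI = (1/N) Σ_i (1/M_i) Σ_j f(|d_ij^pred − d_ij^ref|)

Design points, each a genuinely open choice:

* **Pair universe.** By default all interface-atom co-members pair with
  each other (protein–protein pairs included, each pair contributing to
  both members, M_i = N−1); a `ligand_contacts` mode restricts to
  protein–ligand pairs. The all-co-members reading is the default because
  interface neighbors are defined by membership, not by a distance shell.
* **No inclusion radius.** Classic CASP-style lDDT caps pairs at an
  inner radius and adds stereochemical checks; neither applies here —
  this is a deliberate divergence, documented, not an oversight.
* Model distances come from a correspondence map (protein atoms via
  per-chain sequence alignment + atom name; ligand atoms by name after
  harmonization). Strict mode (default) errors on any reference
  interface atom without a model correspondent; lenient mode drops it
  with a logged count.

All distances are internal to each structure, so the score is invariant
under rigid motion of the model to 1e-12 and needs no superposition.

## Synthetic fixtures

The generator builds an idealized helical chain (rise 1.5 Å, twist 100°,
CA radius 2.3 Å; backbone N/C/O and a CB placeholder per residue) and a
compact zig-zag ligand of 2–9 atoms, its centroid 20 Å off the helix
axis. That offset puts every non-planted atom ≥ ~13.5 Å from the ligand,
so planted sites fully control the proximity structure. A planted site's
CB is placed on the ray through the ligand's extreme atom in the
direction of the site's CA, at exactly the requested distance; because
the anchor atom is extremal along that ray, the minimum over all atom
pairs equals the request to 1e-6 Å by construction (requests outside
[1, 13] Å are rejected as infeasible). Default fixture: 24 residues,
6 ligand atoms, sites at 3.5 Å (a genuine interface contact), 8 Å
(proximal) and 12 Å (beyond the 10 Å cutoff), a 2-residue N-terminal
reference flank to exercise renumbering, and a PTM table that also
carries one duplicate row, one residue-type mismatch, one out-of-range
position and one non-integer position, with the expected surviving
counts recorded in the manifest.

Model variants apply known perturbations: rigid motion (expected
post-superposition ligand RMSD 0), ligand shift of d (expected no-fit
RMSD exactly d), i.i.d. Gaussian jitter of scale σ (expected mean
squared per-atom deviation 3σ², with χ² sampling spread over seeds),
hinge rotation of the C-terminal half about a pivot CA (the
domain-restriction exercise) and a single-residue kick (the
outlier-rejection exercise). Everything derives from one explicit seed;
identical specs produce byte-identical files.

What the fixtures do **not** emulate: real side-chain rotamers and
sterics, solvent, crystallographic artifacts (occupancy quirks beyond
altloc pairs, symmetry mates), PTM chemistry itself (a planted "site" is
geometric, not a modified residue), and the error modes of real
structure predictors, whose outputs have correlated rather than i.i.d.
errors. Passing tests therefore certify the *measurement machinery* —
distances, alignments, fits, scores, bookkeeping — on exactly known
geometry, not biological realism of any model.

## Problem sizes and tolerances

Test fixtures use 5–30 residues and 2–9 ligand atoms — large enough that
fits are overdetermined (≈ 120 atom pairs) and small enough that the
whole suite runs in seconds. Oracle-equivalence checks run the dense
proximity scan on 50 random fixtures, the quaternion (Horn) superposition
solver against the SVD fit on 100 random clouds at 1e-9 Å, and
exhaustive alignment-path enumeration against the DP on 200 random pairs
of length ≤ 8 (enumeration grows with the Delannoy numbers, which caps
the feasible length). Exact planted quantities are asserted at 1e-6 Å
(in-memory; PDB files round to 1e-3 Å), statistical ones (the 3σ² jitter
law) at ±20 % over 20 seeds, and invariance properties at 1e-9–1e-12.

## Known limitations

* Whole-residue proximity is one of two defensible readings of
  "PTM within 10 Å"; the modified-atom-only alternative would need the
  modified atom's identity, which site tables do not carry.
* Ligand RMSD is name-paired, so symmetric ligands over-estimate.
* Automatic hinge detection is out of scope; domain restriction is a
  user decision informed by the logged RMSD contrast.
* The aligner is global-only by design (single-protein chains); it is
  O(n·m) in pure Python and comfortable to a few thousand residues, not
  a general-purpose aligner.
* Multi-chain models are matched chain-by-chain (same-id first, else
  positional); heteromeric reshuffling beyond that is not resolved.
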