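"""Find PTM sites near a bound small molecule and map them to domains.

Builds a synthetic complex with three planted modification sites at known
nearest-atom distances from the ligand (3.5, 8 and 12 Å), then runs the
annotation stage: read the dbPTM-style site table, validate each site
against the reference sequence, renumber the structure chain onto
reference coordinates, and keep the sites within 10 Å of any ligand atom.
"""

import tempfile
from pathlib import Path

from ptmbind import (
    FixtureSpec, make_toy_complex, read_structure, read_ptm_table,
    validate_sites, find_proximal_ptms, map_chain_to_reference,
    chain_sequence,
)
from ptmbind.ptm_annotation import read_domain_table

workdir = Path(tempfile.mkdtemp())
toy = make_toy_complex(FixtureSpec(seed=1), workdir)

ref = read_structure(toy.paths["pdb"])
sites = read_ptm_table(toy.paths["ptms"])
validate_sites(sites, toy.ref_seq)
print(f"{len(sites)} unique sites in the table; "
      f"{sum(s.status == 'valid' for s in sites)} validate against the "
      "reference sequence (the rest are excluded and logged)")

rmap = map_chain_to_reference(chain_sequence(ref, "A"), toy.ref_seq)
domains = read_domain_table(toy.paths["domains"])
hits = find_proximal_ptms(ref, ref.ligands[0], sites, rmap,
                          cutoff=10.0, domains=domains)

print(f"\n{len(hits)} binding-site-proximal PTM(s) at the 10 Å cutoff:")
for h in hits:
    print(f"  {h.site.ptm_type:>15} of {h.site.residue}{h.site.position}: "
          f"min distance {h.min_distance:.3f} Å, domain "
          f"{','.join(h.domain_ids) or '-'}")
print("\nThe site planted at 12 Å is correctly absent: a PTM counts as "
      "binding-site-associated only within 10 Å of the ligand.")
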