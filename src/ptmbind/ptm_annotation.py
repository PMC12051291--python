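"""PTM site ingestion, validation, ligand-proximity search, domain mapping.

The canonical input is a dbPTM-like tab-separated table with columns
(accession, position, residue, ptm_type). Sites are validated against the
reference sequence — a residue-type mismatch or an out-of-range position
marks the site invalid and it is excluded from the proximity search, with
the exclusion logged rather than silently dropped.

A PTM is *binding-site-proximal* when any heavy atom of the modified residue
lies within the cutoff (default 10 Å, boundary inclusive) of any heavy atom
of the bound small molecule. The search uses a k-d tree over ligand atoms
but carries the exact all-pairs contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .seq_align import ResidueMap
from .structures_io import LigandInstance, Structure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "PTMSite",
    "DomainRange",
    "ProximalPTM",
    "read_ptm_table",
    "validate_sites",
    "find_proximal_ptms",
    "map_sites_to_domains",
    "parse_range_string",
    "read_domain_table",
    "proximal_ptms_to_table",
]

DEFAULT_PROXIMITY_CUTOFF = 10.0  # Å


@dataclass
class PTMSite:
    accession: str
    position: int  # 1-based reference-sequence position
    residue: str  # one-letter type
    ptm_type: str
    status: str | None = None  # valid | residue_mismatch | unmapped

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"PTM position must be >= 1, got {self.position}")
        self.residue = self.residue.upper()
        if len(self.residue) != 1 or not self.residue.isalpha():
            raise ValueError(f"residue must be one letter, got {self.residue!r}")


@dataclass
class DomainRange:
    """A structural domain as inclusive 1-based residue intervals."""

    domain_id: str
    scope_id: str  # accession (or chain) the positions refer to
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for lo, hi in self.segments:
            if lo > hi:
                raise ValueError(f"{self.domain_id}: segment {lo}-{hi} inverted")
        spans = sorted(self.segments)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"{self.domain_id}: overlapping segments")

    def contains(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.segments)


@dataclass
class ProximalPTM:
    site: PTMSite
    comp_id: str
    copy_key: tuple[str, int]
    min_distance: float  # Å, min over (residue heavy atom, ligand heavy atom)
    residue_key: tuple[str, int, str]
    domain_ids: list[str] = field(default_factory=list)


def read_ptm_table(
    path,
    columns: dict[str, object] | None = None,
    has_header: bool | None = None,
) -> list[PTMSite]:
    """Read a dbPTM-like TSV of PTM sites.

    ``columns`` maps the logical fields accession/position/residue/ptm_type
    to column names (header present) or 0-based indices (positional).
    Duplicate (accession, position, ptm_type) rows are collapsed; rows with
    a non-integer position are rejected with a logged warning.
    """
    columns = columns or {
        "accession": "accession",
        "position": "position",
        "residue": "residue",
        "ptm_type": "ptm_type",
    }
    positional = all(isinstance(v, int) for v in columns.values())
    if has_header is None:
        has_header = not positional
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None, dtype=str,
        comment="#", skip_blank_lines=True,
    )
    if positional:
        getcol = lambda row, f: row.iloc[int(columns[f])]
    else:
        missing = [c for c in columns.values() if c not in df.columns]
        if missing:
            raise ValueError(f"PTM table missing column(s): {missing}")
        getcol = lambda row, f: row[columns[f]]

    sites: list[PTMSite] = []
    seen: set[tuple[str, int, str]] = set()
    n_rejected = 0
    for _, row in df.iterrows():
        raw_pos = str(getcol(row, "position")).strip()
        try:
            pos = int(raw_pos)
            if pos < 1:
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("PTM row rejected: non-positive or non-integer "
                           "position %r", raw_pos)
            n_rejected += 1
            continue
        acc = str(getcol(row, "accession")).strip()
        res = str(getcol(row, "residue")).strip()
        ptm = str(getcol(row, "ptm_type")).strip()
        key = (acc, pos, ptm)
        if key in seen:  # non-duplicated count is per (accession, pos, type)
            continue
        seen.add(key)
        sites.append(PTMSite(acc, pos, res, ptm))
    if n_rejected:
        logger.warning("PTM table: %d row(s) rejected", n_rejected)
    return sites


def validate_sites(sites: list[PTMSite], ref_seq: str) -> list[PTMSite]:
    """Check each site's residue letter against the reference sequence.

    Sets ``status`` to ``valid`` when the letters agree, ``residue_mismatch``
    when they disagree (the site table and the reference are out of sync —
    these are excluded from the proximity search downstream) and
    ``unmapped`` when the position lies beyond the sequence. Every
    non-valid site is logged. The site count never changes.
    """
    ref = ref_seq.upper()
    for site in sites:
        if site.position > len(ref):
            site.status = "unmapped"
            logger.warning(
                "PTM %s pos %d (%s): beyond reference length %d — excluded",
                site.accession, site.position, site.ptm_type, len(ref),
            )
        elif ref[site.position - 1] == site.residue:
            site.status = "valid"
        else:
            site.status = "residue_mismatch"
            logger.warning(
                "PTM %s pos %d: table says %s, reference has %s — excluded",
                site.accession, site.position, site.residue,
                ref[site.position - 1],
            )
    return sites


def find_proximal_ptms(
    s: Structure,
    lig: LigandInstance,
    sites: list[PTMSite],
    rmap: ResidueMap,
    cutoff: float = DEFAULT_PROXIMITY_CUTOFF,
    domains: list[DomainRange] | None = None,
) -> list[ProximalPTM]:
    """Valid PTM sites whose residue lies within ``cutoff`` of the ligand.

    A site qualifies iff the minimum over all (residue heavy atom, ligand
    heavy atom) distances is <= cutoff (inclusive). Sites whose mapped
    residue has no coordinates in the structure are skipped with a log
    entry. Non-valid sites are never searched.
    """
    if not lig.atoms:
        raise StructureError(f"ligand {lig.comp_id}: no atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(lig.coords())
    pos2key = rmap.position_to_key()
    chain = s.chain(rmap.chain_id)
    res_by_key = {r.key: r for r in chain.residues}

    out: list[ProximalPTM] = []
    for site in sites:
        if site.status != "valid":
            continue
        key = pos2key.get(site.position)
        if key is None or key not in res_by_key:
            logger.info(
                "PTM %s pos %d: residue not resolved in structure — skipped",
                site.accession, site.position,
            )
            continue
        res = res_by_key[key]
        coords = np.array([a.coord for a in res.atoms])
        d = float(np.min(tree.query(coords)[0]))
        if d <= cutoff:
            hit = ProximalPTM(site, lig.comp_id, lig.copy_key, d, key)
            if domains:
                assigned = map_sites_to_domains([site], domains)
                hit.domain_ids = assigned.get(id(site), [])
            out.append(hit)
    return out


def map_sites_to_domains(
    sites: list[PTMSite], domains: list[DomainRange]
) -> dict[int, list[str]]:
    """Assign each site to the domain(s) whose segments contain its position.

    Keyed by ``id(site)`` (sites are mutable, unhashable records). A site in
    no domain maps to an empty list; a position covered by overlapping
    domains is assigned to all of them and the ambiguity logged.
    """
    out: dict[int, list[str]] = {}
    for site in sites:
        hits = [d.domain_id for d in domains if d.contains(site.position)]
        if len(hits) > 1:
            logger.warning(
                "PTM %s pos %d falls in overlapping domains %s",
                site.accession, site.position, hits,
            )
        out[id(site)] = hits
    return out


def parse_range_string(domain_id: str, scope_id: str, ranges: str) -> DomainRange:
    """Parse an ECOD-style range string like ``"A:12-150,A:200-240"``.

    The chain token before the colon is accepted and ignored — positions are
    interpreted in the scope's (reference-sequence) numbering. A bare
    number (``"A:57"``) is a one-residue segment.
    """
    segments: list[tuple[int, int]] = []
    for part in ranges.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            part = part.split(":", 1)[1]
        if "-" in part[1:]:  # allow (unused) leading minus
            lo_s, hi_s = part.rsplit("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(part)
        segments.append((lo, hi))
    if not segments:
        raise ValueError(f"empty range string for domain {domain_id}")
    return DomainRange(domain_id, scope_id, segments)


def read_domain_table(path) -> list[DomainRange]:
    """Read a TSV with columns (domain_id, accession, ranges)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"domain_id", "accession", "ranges"}
    if not need.issubset(df.columns):
        raise ValueError(f"domain table needs columns {sorted(need)}")
    return [
        parse_range_string(r["domain_id"], r["accession"], r["ranges"])
        for _, r in df.iterrows()
    ]


def proximal_ptms_to_table(hits: list[ProximalPTM]) -> pd.DataFrame:
    """One row per proximal PTM, ready to write as the stage's TSV report."""
    rows = []
    for h in hits:
        rows.append({
            "accession": h.site.accession,
            "position": h.site.position,
            "residue": h.site.residue,
            "ptm_type": h.site.ptm_type,
            "comp_id": h.comp_id,
            "ligand_chain": h.copy_key[0],
            "ligand_resnum": h.copy_key[1],
            "min_distance": round(h.min_distance, 3),
            "chain": h.residue_key[0],
            "resnum": h.residue_key[1],
            "icode": h.residue_key[2],
            "domains": ";".join(h.domain_ids),
        })
    cols = ["accession", "position", "residue", "ptm_type", "comp_id",
            "ligand_chain", "ligand_resnum", "min_distance", "chain",
            "resnum", "icode", "domains"]
    return pd.DataFrame(rows, columns=cols)
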