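"""Run configuration shared by the pipeline stages.

Every tunable the analysis depends on is surfaced here with its default:
10 Å PTM-to-ligand proximity cutoff, 5 Å interface cutoff, up to five
superposition refinement cycles with a 2-SD outlier rule, all-heavy-atom
correspondence scope and a 0.30 sequence-identity floor for renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    proximity_cutoff: float = 10.0  # Å, PTM residue to ligand
    interface_cutoff: float = 5.0  # Å, interface-atom selection
    max_cycles: int = 5  # superposition refinement cap
    sd_cutoff: float = 2.0  # outlier rejection, mean + k*SD
    scope: str = "heavy"  # heavy | backbone | ca
    identity_floor: float = 0.30
    strict_correspondence: bool = True
    lddt_mode: str = "all_pairs"  # all_pairs | ligand_contacts

    def __post_init__(self) -> None:
        if self.proximity_cutoff <= 0 or self.interface_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.max_cycles < 0 or self.sd_cutoff <= 0:
            raise ValueError("max_cycles >= 0 and sd_cutoff > 0 required")
        if self.scope not in ("heavy", "backbone", "ca"):
            raise ValueError(f"unknown scope {self.scope!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
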