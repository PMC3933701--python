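"""Design and matching constraints shared by the designer and in-silico PCR."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PrimerConstraints:
    """Constraints of the endpoint replicon-typing PCR design.

    Defaults describe the IncP-9 oriV-rep system: 21-mer degenerate primers,
    a 12 bp perfect 3' anchor with at most 4 mismatches 5' of it per template,
    and a 610-637 bp product.  ``max_gap_fraction`` 0 restricts design windows
    to indel-free alignment columns; ``f_min`` 0 makes the window consensus
    cover every observed base.  The Wallace-rule Tm window spans 50-62 °C,
    wide enough to admit both published primers (60 and 61 °C).
    """

    primer_length: int = 21
    max_degeneracy: int = 8
    anchor_len: int = 12
    max_mismatch: int = 4
    amplicon_min: int = 610
    amplicon_max: int = 637
    max_gap_fraction: float = 0.0
    f_min: float = 0.0
    tm_min: float = 50.0
    tm_max: float = 62.0

    def __post_init__(self) -> None:
        if self.anchor_len > self.primer_length:
            raise ValueError("anchor_len must not exceed primer_length")
        if self.amplicon_min < 2 * self.primer_length:
            raise ValueError("amplicon_min must be at least twice the primer length")
        for name in ("primer_length", "max_degeneracy", "anchor_len",
                     "amplicon_min", "amplicon_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_mismatch < 0 or self.max_gap_fraction < 0 or self.f_min < 0:
            raise ValueError("negative constraint value")
        if self.amplicon_max < self.amplicon_min:
            raise ValueError("amplicon_max < amplicon_min")
        if self.tm_max < self.tm_min:
            raise ValueError("tm_max < tm_min")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrimerConstraints":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
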