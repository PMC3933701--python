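"""Built-in primer systems and reference bookkeeping.

The registry ships exactly one built-in system: the degenerate IncP-9
oriV-rep pair.  Other replicon-typing systems (IncP-1 trfA, IncP-7 rep,
16S rRNA) are supported only as user-supplied registry entries, since
their sequences belong to other publications.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .seqio import Primer, SequenceError

#: Nine IncP-9 subgroup labels (Greek letters, spelled out for ASCII-safe ids).
SUBGROUP_LABELS: tuple[str, ...] = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta", "iota",
)

#: Reference plasmids defining the subgroup vocabulary.
SUBGROUP_REFERENCE_PLASMIDS: dict[str, str] = {
    "alpha": "pM3",
    "beta": "pBS2",
    "gamma": "pSN11",
    "delta": "pSN11",
    "epsilon": "pMG18",
    "zeta": "pNL60",
    "eta": "pNL15",
    "theta": "pSVS15",
    "iota": "pNL22",
}


def clean_primer_sequence(text: str) -> str:
    """Strip publication formatting from a printed primer string.

    Accepts forms like ``5-GAG GGT TTG GAG ATC ATW AGA-3`` or
    ``5'-GAGGGT...-3'`` and returns the bare 5'→3' sequence.
    """
    s = text.strip().upper()
    s = re.sub(r"^5'?\s*-?", "", s)
    s = re.sub(r"-?\s*3'?$", "", s)
    s = re.sub(r"[\s\-]", "", s)
    if not s:
        raise SequenceError(f"no sequence found in {text!r}")
    return s


#: The IncP-9 oriV-rep endpoint PCR system: 21-mer degenerate pair,
#: expected product 610-637 bp across the nine subgroups.
INCP9_FORWARD = Primer(
    name="IncP9-oriV-rep-F",
    sequence5to3=clean_primer_sequence("5-GAG GGT TTG GAG ATC ATW AGA-3"),
    role="forward",
)
INCP9_REVERSE = Primer(
    name="IncP9-oriV-rep-R",
    sequence5to3=clean_primer_sequence("5-GGT CTG TAT CCA GTT RTG CTT-3"),
    role="reverse",
)
INCP9_AMPLICON_RANGE: tuple[int, int] = (610, 637)

#: GenBank accession lists for the reference alignments behind the IncP-9
#: system (oriV and rep regions of the nine subgroups; ranges are inclusive).
ORIV_ACCESSION_SPEC: tuple[str, ...] = (
    "EU499619-EU499641", "AF078924", "AB237655", "AJ344068", "AB257759", "AF491307",
)
REP_ACCESSION_SPEC: tuple[str, ...] = (
    "EU499644-EU499666", "AF078924", "AB237655", "AJ344068", "AB257760", "AF491307",
)

_ACC_RE = re.compile(r"^([A-Z]+)(\d+)$")


def expand_accessions(items: list[str] | tuple[str, ...]) -> list[str]:
    """Expand accession range notation ``PREFIXnnn-PREFIXmmm`` into a flat list.

    Singletons pass through; ranges are inclusive and must share a prefix and
    digit width.  Zero padding is preserved.
    """
    out: list[str] = []
    for item in items:
        item = item.strip()
        if "-" not in item:
            out.append(item)
            continue
        lo, hi = item.split("-", 1)
        mlo, mhi = _ACC_RE.match(lo), _ACC_RE.match(hi)
        if not mlo or not mhi:
            raise ValueError(f"cannot parse accession range {item!r}")
        if mlo.group(1) != mhi.group(1) or len(mlo.group(2)) != len(mhi.group(2)):
            raise ValueError(f"mismatched prefixes in accession range {item!r}")
        prefix, width = mlo.group(1), len(mlo.group(2))
        a, b = int(mlo.group(2)), int(mhi.group(2))
        if b < a:
            raise ValueError(f"descending accession range {item!r}")
        out.extend(f"{prefix}{n:0{width}d}" for n in range(a, b + 1))
    return out


@dataclass
class RegistryEntry:
    """A user-defined primer system: name, primer, and optional product size."""

    primer: Primer
    expected_product_size: Optional[tuple[int, int]] = None


def load_registry(path: str | Path) -> dict[str, RegistryEntry]:
    """Load a flat key-value primer registry (YAML).

    Each entry maps a name to ``sequence``, ``role`` and optionally
    ``expected-product-size`` (a ``[min, max]`` pair or single length).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    entries: dict[str, RegistryEntry] = {}
    for name, spec in raw.items():
        if not isinstance(spec, dict) or "sequence" not in spec or "role" not in spec:
            raise ValueError(f"registry entry {name!r} needs 'sequence' and 'role'")
        size = spec.get("expected-product-size") or spec.get("expected_product_size")
        if size is not None:
            if isinstance(size, (int, float)):
                size = (int(size), int(size))
            else:
                size = (int(size[0]), int(size[1]))
        entries[name] = RegistryEntry(
            primer=Primer(name=name, sequence5to3=clean_primer_sequence(str(spec["sequence"])),
                          role=str(spec["role"])),
            expected_product_size=size,
        )
    return entries


def builtin_registry() -> dict[str, RegistryEntry]:
    """The shipped registry: only the IncP-9 oriV-rep pair."""
    return {
        INCP9_FORWARD.name: RegistryEntry(INCP9_FORWARD, INCP9_AMPLICON_RANGE),
        INCP9_REVERSE.name: RegistryEntry(INCP9_REVERSE, INCP9_AMPLICON_RANGE),
    }
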