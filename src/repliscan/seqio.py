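"""Sequence and primer data model, IUPAC degenerate-alphabet algebra, FASTA I/O.

Nucleotide sequences are plain Python strings over the IUPAC alphabet
(``ACGT`` plus the eleven ambiguity codes and ``-`` for alignment gaps).
Every ambiguity code denotes a *set* of concrete bases; a degenerate primer
is the equimolar mixture of all concrete expansions of its sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_SETS)
ALPHABET = IUPAC_CODES | {GAP}

#: Complement table extended over ambiguity codes (W and S are self-complementary).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

# 4-bit mask encoding (A=1, C=2, G=4, T=8); gap encodes to 0.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
MASK: dict[str, int] = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
MASK[GAP] = 0
CODE_FROM_MASK: dict[int, str] = {v: k for k, v in MASK.items()}

_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in MASK.items():
    _ENCODE_LUT[ord(_c)] = _m
_VALID_LUT = np.zeros(256, dtype=bool)
for _c in ALPHABET:
    _VALID_LUT[ord(_c)] = True


class SequenceError(ValueError):
    """Raised for malformed sequences, primers or FASTA input."""


def normalize(seq: str) -> str:
    """Uppercase, map U to T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise SequenceError(f"illegal residue(s) {sorted(bad)} in sequence")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as an array of 4-bit base masks."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if not _VALID_LUT[arr].all():
        bad = sorted({chr(c) for c in arr[~_VALID_LUT[arr]]})
        raise SequenceError(f"illegal residue(s) {bad} in sequence")
    return _ENCODE_LUT[arr]


def expansion(code: str) -> frozenset[str]:
    """The set of concrete bases an IUPAC code stands for."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise SequenceError(f"not an ungapped IUPAC code: {code!r}") from None


def expand(seq: str) -> Iterator[str]:
    """Iterate over all concrete (ACGT-only) expansions of a degenerate string."""
    sets = [sorted(expansion(c)) for c in seq]
    for combo in product(*sets):
        yield "".join(combo)


def degeneracy(seq: str) -> int:
    """Number of concrete oligos in the degenerate mixture (product of set sizes)."""
    n = 1
    for c in seq:
        n *= len(expansion(c))
    return n


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet. Involution; gaps rejected."""
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq))
    except KeyError:
        bad = sorted(set(seq) - set(COMPLEMENT))
        raise SequenceError(f"cannot complement {bad}") from None


def base_match(primer_base: str, target_base: str) -> bool:
    """Subset match rule used for primer-template comparison.

    True iff every concretization of the (possibly ambiguous) template base is
    covered by the primer base: ``expansion(target) ⊆ expansion(primer)``.
    The rule is deliberately asymmetric — an N in the template only matches a
    primer N, so ambiguity in public records never silently satisfies the
    3′ anchor.
    """
    return expansion(target_base) <= expansion(primer_base)


@dataclass
class SequenceRecord:
    """A labelled nucleotide sequence over the IUPAC alphabet."""

    id: str
    residues: str
    description: str = ""
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        self.residues = normalize(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            description=self.description,
            group_label=self.group_label,
        )


@dataclass
class Primer:
    """A degenerate oligo, written 5'→3', with its PCR orientation."""

    name: str
    sequence5to3: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        self.sequence5to3 = normalize(self.sequence5to3)
        if not self.sequence5to3:
            raise SequenceError(f"primer {self.name!r} is empty")
        if GAP in self.sequence5to3:
            raise SequenceError(f"primer {self.name!r} contains gap characters")
        if self.role not in ("forward", "reverse"):
            raise SequenceError(f"primer role must be forward/reverse, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence5to3)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence5to3)


@dataclass
class ReferencePanel:
    """Labelled target replicons plus non-target plasmids for specificity screens."""

    targets: list[SequenceRecord]
    nontargets: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.targets] + [r.id for r in self.nontargets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceError(f"duplicate record ids across panel: {sorted(dupes)}")
        missing = [r.id for r in self.targets if not r.group_label]
        if missing:
            raise SequenceError(f"targets without group_label: {missing}")

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for r in self.targets:
            if r.group_label not in seen:
                seen.append(r.group_label)  # type: ignore[arg-type]
        return seen


_GROUP_RE = re.compile(r"group=(\S+)")


def _line_of_illegal_residue(path: Path, record_id: str) -> int:
    """Locate the first line of a record's body carrying an illegal character."""
    in_record = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
            continue
        if in_record:
            residues = line.strip().upper().replace("U", "T")
            if set(residues) - ALPHABET:
                return lineno
    return -1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gapped) multi-FASTA into SequenceRecords.

    Residues are uppercased and U is mapped to T.  A ``group=<label>`` token in
    the header is parsed into ``group_label``.  Illegal characters raise a
    parse error naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _GROUP_RE.search(rec.description)
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    description=rec.description[len(rec.id):].strip(),
                    group_label=m.group(1) if m else None,
                )
            )
        except SequenceError as exc:
            lineno = _line_of_illegal_residue(path, rec.id)
            raise SequenceError(f"{path}:{lineno}: {exc} (record {rec.id!r})") from None
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA; group labels go into the header."""
    path = Path(path)
    seqrecords = []
    for r in records:
        desc = r.description
        if r.group_label and f"group={r.group_label}" not in desc:
            desc = (desc + f" group={r.group_label}").strip()
        seqrecords.append(SeqRecord(Seq(r.residues), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), in °C.

    For degenerate strings the A+T and G+C counts are expectations over the
    equimolar expansion mixture, which by linearity equals the per-position
    fraction of each code's base set falling in {A,T} vs {G,C}.
    """
    at = gc = 0.0
    for c in seq:
        s = expansion(c)
        at += len(s & {"A", "T"}) / len(s)
        gc += len(s & {"G", "C"}) / len(s)
    return 2.0 * at + 4.0 * gc
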