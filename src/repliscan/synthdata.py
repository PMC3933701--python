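"""Synthetic nine-subgroup replicon panels with planted primer sites.

The generator emulates the structure of a grouped replicon reference set: a
random root sequence carries a forward primer site, a variable-length insert
and a reverse primer site at fixed panel-wide coordinates; subgroup
ancestors diverge from the root by substitutions at the between-subgroup
rate, members from their ancestor at the within-subgroup rate.  Each member
receives a fresh random concrete expansion of the planted degenerate pair,
and its insert is truncated at the 3' end to a per-member length drawn from
the configured range — so expected product sizes span exactly the target
window (insert + both primer footprints) while all sequences stay homologous
and alignable.  Decoy non-targets are site-free random sequences.  Full
ground truth (site coordinates, subgroup memberships, expected amplicon
lengths) is returned for recovery tests; everything is reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import ispcr
from .design_constraints import PrimerConstraints
from .registry import INCP9_FORWARD, INCP9_REVERSE, SUBGROUP_LABELS
from .seqio import (
    Primer,
    ReferencePanel,
    SequenceError,
    SequenceRecord,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic panel.

    Nine subgroups of three members each mirror the scale of the real
    reference alignment (28 replicon sequences across nine subgroups).
    Within-subgroup divergence 0.02 and between-subgroup divergence 0.15
    substitutions/site give clearly separated families that still align; the
    insert range 568-595 plus two 21-mer footprints spans products of
    610-637 bp.  ``anchor_protect`` keeps planted primer footprints free of
    mutations (guaranteeing intact 3' anchors); disabling it lets the
    within-subgroup rate erode the footprints, anchors included.
    """

    n_subgroups: int = 9
    seqs_per_subgroup: int = 3
    seq_length: int = 800
    within_divergence: float = 0.02
    between_divergence: float = 0.15
    insert_length_range: tuple[int, int] = (568, 595)
    n_nontargets: int = 6
    anchor_protect: bool = True
    forward_primer: Primer = field(default_factory=lambda: INCP9_FORWARD)
    reverse_primer: Primer = field(default_factory=lambda: INCP9_REVERSE)
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.within_divergence < self.between_divergence <= 0.75):
            raise ValueError("need 0 <= within < between <= 0.75")
        lo, hi = self.insert_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("insert_length_range must be positive and ordered")
        if self.n_subgroups < 1 or self.seqs_per_subgroup < 1:
            raise ValueError("panel dimensions must be positive")


@dataclass(frozen=True)
class RecordTruth:
    """Ground truth for one simulated target."""

    record_id: str
    subgroup: str
    forward_site: tuple[int, int]  # [start, end) plus strand
    reverse_site: tuple[int, int]
    insert_length: int
    expected_amplicon_length: int
    amplicon_sequence: str


@dataclass
class PanelTruth:
    """Planted primer pair, per-record coordinates/memberships, and the seed."""

    pair: tuple[Primer, Primer]
    records: dict[str, RecordTruth]
    config: SimConfig

    def by_subgroup(self) -> dict[str, list[RecordTruth]]:
        out: dict[str, list[RecordTruth]] = {}
        for rt in self.records.values():
            out.setdefault(rt.subgroup, []).append(rt)
        return out


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator,
    protected: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Substitute each position with probability `rate` to a different base."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if protected is not None:
        hit &= ~protected
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _subgroup_label(k: int) -> str:
    return SUBGROUP_LABELS[k] if k < len(SUBGROUP_LABELS) else f"sg{k + 1}"


def _random_expansion(primer: Primer, rng: np.random.Generator) -> str:
    from .seqio import expansion

    return "".join(
        sorted(expansion(c))[rng.integers(0, len(expansion(c)))]
        for c in primer.sequence5to3
    )


def simulate_panel(cfg: SimConfig) -> tuple[ReferencePanel, PanelTruth]:
    """Generate a grouped target panel plus decoys, with full ground truth.

    Raises when ``seq_length`` cannot host both primer footprints plus the
    maximum insert.  Byte-identical output for identical configs.
    """
    fwd, rev = cfg.forward_primer, cfg.reverse_primer
    Lf, Lr = len(fwd), len(rev)
    insert_max = cfg.insert_length_range[1]
    flank_total = cfg.seq_length - Lf - Lr - insert_max
    if flank_total < 0:
        raise SequenceError(
            f"seq_length {cfg.seq_length} too short for two primer sites plus "
            f"a {insert_max} bp insert"
        )
    rng = np.random.default_rng(cfg.seed)
    root = _random_seq(rng, cfg.seq_length)
    f5 = int(rng.integers(0, flank_total + 1))  # one placement per panel
    fwd_start = f5
    insert_start = f5 + Lf

    targets: list[SequenceRecord] = []
    truth: dict[str, RecordTruth] = {}
    for g in range(cfg.n_subgroups):
        label = _subgroup_label(g)
        ancestor = _mutate(root, cfg.between_divergence, rng)
        for m in range(cfg.seqs_per_subgroup):
            backbone = _mutate(ancestor, cfg.within_divergence, rng)
            ins_len = int(
                rng.integers(cfg.insert_length_range[0], cfg.insert_length_range[1] + 1)
            )
            fwd_exp = _random_expansion(fwd, rng)
            rev_exp = _random_expansion(rev, rng)
            rev_site_seq = reverse_complement(rev_exp)
            # per-member length variation is a deletion in the middle of the
            # insert, keeping both primer footprints embedded in long
            # homologous context so alignments stay clean around them
            head = ins_len // 2
            tail = ins_len - head
            insert_seq = (
                backbone[insert_start:insert_start + head].tobytes().decode()
                + backbone[insert_start + insert_max - tail:
                           insert_start + insert_max].tobytes().decode()
            )
            parts = [
                backbone[:fwd_start].tobytes().decode(),
                fwd_exp,
                insert_seq,
                rev_site_seq,
                backbone[insert_start + insert_max:].tobytes().decode(),
            ]
            seq = "".join(parts)
            rev_start = fwd_start + Lf + ins_len
            if not cfg.anchor_protect:
                # a within-rate substitution pass over the footprints; the 3'
                # anchors are only safe when anchor_protect is on
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                foot = np.zeros(len(arr), dtype=bool)
                foot[fwd_start:fwd_start + Lf] = True
                foot[rev_start:rev_start + Lr] = True
                arr = _mutate(arr, cfg.within_divergence, rng, protected=~foot)
                seq = arr.tobytes().decode()
            rec_id = f"{label}_{m + 1}"
            targets.append(
                SequenceRecord(
                    id=rec_id, residues=seq,
                    description=f"simulated {label} replicon", group_label=label,
                )
            )
            truth[rec_id] = RecordTruth(
                record_id=rec_id,
                subgroup=label,
                forward_site=(fwd_start, fwd_start + Lf),
                reverse_site=(rev_start, rev_start + Lr),
                insert_length=ins_len,
                expected_amplicon_length=ins_len + Lf + Lr,
                amplicon_sequence=seq[fwd_start:rev_start + Lr],
            )

    constraints = PrimerConstraints()
    nontargets: list[SequenceRecord] = []
    for k in range(cfg.n_nontargets):
        for _ in range(100):
            cand = SequenceRecord(
                id=f"decoy_{k + 1}",
                residues=_random_seq(rng, cfg.seq_length).tobytes().decode(),
                description="simulated non-target plasmid",
            )
            no_f = not ispcr.find_binding_sites(fwd, cand, constraints)
            no_r = not ispcr.find_binding_sites(rev, cand, constraints)
            if no_f and no_r:
                nontargets.append(cand)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SequenceError("could not draw a site-free decoy in 100 attempts")

    panel = ReferencePanel(targets=targets, nontargets=nontargets)
    return panel, PanelTruth(pair=(fwd, rev), records=truth, config=cfg)


def simulate_queries(
    truth: PanelTruth,
    n_per_subgroup: int = 1,
    divergence: float = 0.02,
    seed: int = 42,
) -> list[SequenceRecord]:
    """Mutated amplicon subsequences standing in for a cloned amplicon library.

    Each query is the planted amplicon of a panel member (both primer
    footprints inclusive) mutated at the given substitution rate, labelled
    with its generating subgroup as ground truth.
    """
    if not (0 <= divergence < 0.75):
        raise ValueError("divergence must be in [0, 0.75)")
    if n_per_subgroup < 0:
        raise ValueError("n_per_subgroup must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    for label, members in truth.by_subgroup().items():
        for q in range(n_per_subgroup):
            src = members[q % len(members)]
            arr = np.frombuffer(src.amplicon_sequence.encode(), dtype=np.uint8).copy()
            arr = _mutate(arr, divergence, rng)
            out.append(
                SequenceRecord(
                    id=f"clone_{label}_{q + 1}",
                    residues=arr.tobytes().decode(),
                    description=f"simulated clone from {src.record_id}",
                    group_label=label,
                )
            )
    return out


def truth_to_tsv(truth: PanelTruth, path: str | Path) -> None:
    """Ground-truth table as TSV (1-based inclusive coordinates)."""
    rows = [
        dict(
            record_id=rt.record_id,
            subgroup=rt.subgroup,
            fwd_start=rt.forward_site[0] + 1,
            fwd_end=rt.forward_site[1],
            rev_start=rt.reverse_site[0] + 1,
            rev_end=rt.reverse_site[1],
            insert_length=rt.insert_length,
            expected_amplicon_length=rt.expected_amplicon_length,
        )
        for rt in truth.records.values()
    ]
    df = pd.DataFrame(rows)
    df.insert(0, "seed", truth.config.seed)
    df.to_csv(path, sep="\t", index=False)
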