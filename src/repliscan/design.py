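"""Degenerate primer design from grouped multiple alignments.

The designer profiles column conservation, slides fixed-length windows over
runs of indel-free columns, turns each window's minimal IUPAC cover into a
candidate primer, and keeps candidates that stay within the degeneracy and
Tm budgets and bind every target under the anchor/mismatch rules.  Forward
and reverse candidates are then paired subject to the product-size window
and ranked deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ispcr
from .design_constraints import PrimerConstraints
from .msa import Alignment
from .seqio import (
    CODE_FROM_MASK,
    GAP,
    IUPAC_SETS,
    MASK,
    Primer,
    SequenceError,
    SequenceRecord,
    degeneracy,
    reverse_complement,
    wallace_tm,
)

__all__ = [
    "PrimerConstraints",
    "ConservationProfile",
    "CandidatePrimer",
    "PrimerPairDesign",
    "conservation_profile",
    "enumerate_candidates",
    "validate_candidate",
    "pair_and_rank",
    "tm_estimate",
    "design_pairs",
]


def tm_estimate(primer: Primer | str) -> float:
    """Wallace-rule Tm (2(A+T)+4(G+C)) with expected counts over expansions."""
    seq = primer.sequence5to3 if isinstance(primer, Primer) else primer
    return wallace_tm(seq)


@dataclass
class ConservationProfile:
    """Per-column base frequencies, gap fractions and minimal IUPAC cover."""

    counts: np.ndarray  # (n_cols, 4) fractional base counts over A,C,G,T
    gap_fraction: np.ndarray  # (n_cols,)
    consensus: str  # minimal IUPAC cover of bases with frequency >= f_min
    f_min: float
    n_rows: int

    @property
    def column_count(self) -> int:
        return len(self.consensus)


_ORDER = "ACGT"


def conservation_profile(a: Alignment, f_min: float = 0.0) -> ConservationProfile:
    """Column-wise conservation of an alignment.

    Base counts spread ambiguity codes uniformly over their sets.  The
    consensus code of a column is the minimal IUPAC superset of every base
    whose frequency among non-gap residues reaches ``f_min`` (every observed
    base when ``f_min`` is 0).  All-gap columns get consensus N.
    """
    n_rows = len(a)
    n_cols = a.column_count
    counts = np.zeros((n_cols, 4))
    gaps = np.zeros(n_cols)
    for row in a.rows:
        for i, c in enumerate(row.residues):
            if c == GAP:
                gaps[i] += 1
            else:
                bases = IUPAC_SETS[c]
                w = 1.0 / len(bases)
                for b in bases:
                    counts[i, _ORDER.index(b)] += w
    gap_fraction = gaps / n_rows
    consensus = []
    for i in range(n_cols):
        nongap = n_rows - gaps[i]
        if nongap == 0:
            consensus.append("N")
            continue
        freqs = counts[i] / nongap
        if f_min > 0:
            cover = freqs >= f_min
            if not cover.any():
                cover = freqs == freqs.max()
        else:
            cover = freqs > 0
        mask = sum(MASK[_ORDER[k]] for k in np.flatnonzero(cover))
        consensus.append(CODE_FROM_MASK[mask])
    return ConservationProfile(
        counts=counts, gap_fraction=gap_fraction, consensus="".join(consensus),
        f_min=f_min, n_rows=n_rows,
    )


@dataclass
class CandidatePrimer:
    """A validated design candidate anchored to an alignment window."""

    window: tuple[int, int]  # [start, end) alignment columns
    primer: Primer
    per_target: dict[str, ispcr.BindingSite]
    tm: float

    @property
    def sequence5to3(self) -> str:
        return self.primer.sequence5to3

    @property
    def degeneracy(self) -> int:
        return self.primer.degeneracy

    @property
    def total_mismatches(self) -> int:
        return sum(s.n_mismatch for s in self.per_target.values())


@dataclass
class ValidationRow:
    """Per-target outcome of a candidate check."""

    target_id: str
    anchor_run: int
    n_mismatch: int
    passed: bool
    reason: str
    site: Optional[ispcr.BindingSite]


def validate_candidate(
    primer: Primer,
    targets: Sequence[SequenceRecord],
    constraints: PrimerConstraints,
) -> list[ValidationRow]:
    """Check a candidate against every (ungapped) target.

    The best binding site — fewest mismatches, then longest anchor, then
    leftmost — is evaluated per target; it passes when the anchor run reaches
    ``anchor_len`` and mismatches stay within ``max_mismatch``.
    """
    rows = []
    for t in targets:
        if len(t) < len(primer):
            rows.append(ValidationRow(t.id, 0, len(primer), False, "too short", None))
            continue
        site = ispcr.best_binding_site(primer, t)
        assert site is not None
        ok_anchor = site.anchor_run >= constraints.anchor_len
        ok_mm = site.n_mismatch <= constraints.max_mismatch
        reason = ""
        if not ok_anchor:
            reason = f"anchor_run {site.anchor_run} < {constraints.anchor_len}"
        elif not ok_mm:
            reason = f"{site.n_mismatch} mismatches > {constraints.max_mismatch}"
        rows.append(
            ValidationRow(t.id, site.anchor_run, site.n_mismatch,
                          ok_anchor and ok_mm, reason, site)
        )
    return rows


def enumerate_candidates(
    profile: ConservationProfile,
    a: Alignment,
    constraints: PrimerConstraints,
    role: str,
) -> list[CandidatePrimer]:
    """All admissible primer candidates of one orientation.

    Windows are ``primer_length`` consecutive columns whose gap fraction stays
    within ``max_gap_fraction``; the candidate sequence is the window's
    consensus (reverse complemented for reverse-role candidates).  Candidates
    must satisfy the degeneracy and Tm budgets and validate against every
    target.  An empty result is a valid outcome, not an error.
    """
    if role not in ("forward", "reverse"):
        raise SequenceError(f"role must be forward/reverse, got {role!r}")
    L = constraints.primer_length
    admissible = profile.gap_fraction <= constraints.max_gap_fraction
    targets = a.degapped()
    out: list[CandidatePrimer] = []
    for start in range(profile.column_count - L + 1):
        if not admissible[start:start + L].all():
            continue
        consensus = profile.consensus[start:start + L]
        seq = consensus if role == "forward" else reverse_complement(consensus)
        if degeneracy(seq) > constraints.max_degeneracy:
            continue
        tm = wallace_tm(seq)
        if not (constraints.tm_min <= tm <= constraints.tm_max):
            continue
        primer = Primer(name=f"{role[0]}_{start}", sequence5to3=seq, role=role)
        report = validate_candidate(primer, targets, constraints)
        if not all(r.passed for r in report):
            continue
        out.append(
            CandidatePrimer(
                window=(start, start + L),
                primer=primer,
                per_target={r.target_id: r.site for r in report},  # type: ignore[misc]
                tm=tm,
            )
        )
    return out


@dataclass
class PrimerPairDesign:
    """A forward/reverse candidate pair whose products all fit the size window."""

    forward: CandidatePrimer
    reverse: CandidatePrimer
    amplicon_lengths: dict[str, int]

    @property
    def rank_key(self) -> tuple:
        return (
            max(self.forward.degeneracy, self.reverse.degeneracy),
            self.forward.total_mismatches + self.reverse.total_mismatches,
            abs(self.forward.tm - self.reverse.tm),
            self.forward.window[0],
            self.reverse.window[0],
        )


def pair_and_rank(
    fwd: Sequence[CandidatePrimer],
    rev: Sequence[CandidatePrimer],
    targets: Sequence[SequenceRecord],
    constraints: PrimerConstraints,
) -> list[PrimerPairDesign]:
    """Pair candidates and rank deterministically.

    A pair is kept only when, on every target, the reverse site lies downstream
    of the forward site and the product length falls inside
    ``[amplicon_min, amplicon_max]``.  Ranking: smaller pair degeneracy, fewer
    total mismatches, closer Tms, leftmost windows.
    """
    pairs = []
    for f in fwd:
        Lf = len(f.primer)
        for r in rev:
            Lr = len(r.primer)
            lengths: dict[str, int] = {}
            for t in targets:
                fs = f.per_target.get(t.id)
                rs = r.per_target.get(t.id)
                if fs is None or rs is None or rs.start < fs.start + Lf:
                    lengths = {}
                    break
                length = rs.start + Lr - fs.start
                if not (constraints.amplicon_min <= length <= constraints.amplicon_max):
                    lengths = {}
                    break
                lengths[t.id] = length
            if lengths:
                pairs.append(PrimerPairDesign(forward=f, reverse=r,
                                              amplicon_lengths=lengths))
    pairs.sort(key=lambda p: p.rank_key)
    return pairs


def design_pairs(
    a: Alignment, constraints: PrimerConstraints = PrimerConstraints()
) -> list[PrimerPairDesign]:
    """Full design pipeline on an alignment: profile, enumerate, pair, rank."""
    profile = conservation_profile(a, f_min=constraints.f_min)
    fwd = enumerate_candidates(profile, a, constraints, "forward")
    rev = enumerate_candidates(profile, a, constraints, "reverse")
    return pair_and_rank(fwd, rev, a.degapped(), constraints)


def design_report_tsv(
    pairs: Sequence[PrimerPairDesign], path: str | Path
) -> None:
    """Ranked pair report as TSV."""
    rows = []
    for rank, p in enumerate(pairs, start=1):
        rows.append(
            dict(
                rank=rank,
                fwd_window=f"{p.forward.window[0] + 1}-{p.forward.window[1]}",
                fwd_sequence=p.forward.sequence5to3,
                fwd_degeneracy=p.forward.degeneracy,
                fwd_tm=round(p.forward.tm, 2),
                rev_window=f"{p.reverse.window[0] + 1}-{p.reverse.window[1]}",
                rev_sequence=p.reverse.sequence5to3,
                rev_degeneracy=p.reverse.degeneracy,
                rev_tm=round(p.reverse.tm, 2),
                total_mismatches=p.forward.total_mismatches + p.reverse.total_mismatches,
                amplicon_min=min(p.amplicon_lengths.values()),
                amplicon_max=max(p.amplicon_lengths.values()),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
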