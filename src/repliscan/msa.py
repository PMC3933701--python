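"""Multiple alignment of replicon reference sets.

Global pairwise alignment uses Needleman-Wunsch with linear gap costs and
IUPAC-intersection matching (two possibly-degenerate residues score as a
match iff their base sets intersect — matching here, unlike primer-template
comparison, is symmetric).  Multiple alignments are built progressively
along a neighbor-joining guide tree computed from pairwise mismatch
fractions; profiles are merged leaf-to-root.  The whole procedure is
deterministic given the input order: the DP tie-break is fixed
(diagonal > up > left) and no randomness is involved.

Pre-aligned gapped FASTA can be ingested directly instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import nw_fill, profile_nw_fill, traceback
from .seqio import (
    GAP,
    IUPAC_SETS,
    SequenceError,
    SequenceRecord,
    encode,
    read_fasta,
    write_fasta,
)


@dataclass(frozen=True)
class AlignScores:
    """Linear-gap scoring: defaults suit closely related replicon backbones."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


DEFAULT_SCORES = AlignScores()


@dataclass
class Alignment:
    """Equal-length gapped rows; stripping gaps recovers the input records."""

    rows: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            offender = max(self.rows, key=lambda r: len(r.residues))
            raise SequenceError(
                f"ragged alignment: record {offender.id!r} has deviating length"
            )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SequenceError("duplicate ids in alignment")

    @property
    def column_count(self) -> int:
        return len(self.rows[0].residues)

    def __len__(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """Rows as a (n_rows, n_cols) array of 4-bit masks (gap = 0)."""
        return np.vstack([encode(r.residues) for r in self.rows])

    def degapped(self) -> list[SequenceRecord]:
        return [r.degapped() for r in self.rows]

    def column_to_row_position(self, row_index: int) -> np.ndarray:
        """Map each row's ungapped positions to alignment columns."""
        res = self.rows[row_index].residues
        return np.array([i for i, c in enumerate(res) if c != GAP], dtype=np.int64)


def pairwise_align(
    a: str, b: str, scores: AlignScores = DEFAULT_SCORES
) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped sequences.

    Returns the two gapped strings and the alignment score.  Raises if both
    sequences are empty; a single empty sequence yields an all-gap partner.
    """
    if not a and not b:
        raise SequenceError("cannot align two empty sequences")
    if GAP in a or GAP in b:
        raise SequenceError("pairwise_align expects ungapped input")
    if not a:
        return GAP * len(b), b, scores.gap * len(b)
    if not b:
        return a, GAP * len(a), scores.gap * len(a)
    score, P = nw_fill(encode(a), encode(b), scores.match, scores.mismatch, scores.gap)
    out_a, out_b = [], []
    i = j = 0
    for take_a, take_b in traceback(P):
        out_a.append(a[i] if take_a else GAP)
        out_b.append(b[j] if take_b else GAP)
        i += take_a
        j += take_b
    return "".join(out_a), "".join(out_b), float(score)


def _mismatch_fraction(ga: str, gb: str) -> float:
    """Fraction of differing sites over columns where both rows are ungapped."""
    ma, mb = encode(ga), encode(gb)
    both = (ma != 0) & (mb != 0)
    n = int(both.sum())
    if n == 0:
        return 1.0
    return float(((ma[both] & mb[both]) == 0).sum() / n)


def _profile_frequencies(rows: list[str]) -> np.ndarray:
    """Per-column base frequencies (cols, 4); ambiguity spread uniformly, gaps drop."""
    ncols = len(rows[0])
    freq = np.zeros((ncols, 4), dtype=np.float64)
    order = "ACGT"
    for row in rows:
        for i, c in enumerate(row):
            if c == GAP:
                continue
            bases = IUPAC_SETS[c]
            w = 1.0 / len(bases)
            for b in bases:
                freq[i, order.index(b)] += w
    return freq / len(rows)


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scores: AlignScores
) -> tuple[list[str], list[str]]:
    fa = _profile_frequencies(rows_a)
    fb = _profile_frequencies(rows_b)
    occ_a = fa.sum(axis=1)
    occ_b = fb.sum(axis=1)
    _, P = profile_nw_fill(fa, fb, occ_a, occ_b, scores.match, scores.mismatch, scores.gap)
    steps = traceback(P)
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    i = j = 0
    cols_a, cols_b = [], []
    for take_a, take_b in steps:
        cols_a.append(i if take_a else -1)
        cols_b.append(j if take_b else -1)
        i += take_a
        j += take_b
    for k, row in enumerate(rows_a):
        new_a[k] = "".join(row[c] if c >= 0 else GAP for c in cols_a)
    for k, row in enumerate(rows_b):
        new_b[k] = "".join(row[c] if c >= 0 else GAP for c in cols_b)
    return new_a, new_b


def progressive_align(
    records: list[SequenceRecord], scores: AlignScores = DEFAULT_SCORES
) -> Alignment:
    """Progressive multiple alignment along an NJ guide tree.

    Pairwise mismatch fractions (from global pairwise alignments) feed a
    neighbor-joining guide tree; profiles are merged leaf-to-root with
    profile-profile Needleman-Wunsch.  Output rows preserve input order.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate ids in input records")
    if len(records) < 2:
        raise SequenceError("progressive alignment needs at least 2 records")
    seqs = {r.id: r.residues.replace(GAP, "") for r in records}
    if len(records) == 2:
        ga, gb, _ = pairwise_align(seqs[ids[0]], seqs[ids[1]], scores)
        aligned = {ids[0]: ga, ids[1]: gb}
    else:
        n = len(records)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ga, gb, _ = pairwise_align(seqs[ids[i]], seqs[ids[j]], scores)
                dist[i, j] = dist[j, i] = _mismatch_fraction(ga, gb)

        from .phylo import nj  # deferred: phylo imports msa at top level
        from skbio import DistanceMatrix

        guide = nj(DistanceMatrix(dist, ids))

        def merge(node) -> tuple[list[str], list[str]]:
            """Returns (row ids, gapped rows) for the subtree under node."""
            if node.is_tip():
                return [node.name], [seqs[node.name]]
            child_profiles = [merge(ch) for ch in node.children]
            acc_ids, acc_rows = child_profiles[0]
            for nxt_ids, nxt_rows in child_profiles[1:]:
                acc_rows, nxt_rows = _merge_profiles(acc_rows, nxt_rows, scores)
                acc_ids = acc_ids + nxt_ids
                acc_rows = acc_rows + nxt_rows
            return acc_ids, acc_rows

        out_ids, out_rows = merge(guide)
        aligned = dict(zip(out_ids, out_rows))
    by_id = {r.id: r for r in records}
    return Alignment(
        rows=[
            SequenceRecord(
                id=i,
                residues=aligned[i],
                description=by_id[i].description,
                group_label=by_id[i].group_label,
            )
            for i in ids
        ]
    )


def ingest_alignment(path: str | Path) -> Alignment:
    """Read a pre-aligned gapped FASTA, enforcing equal row lengths."""
    records = read_fasta(path)
    return Alignment(rows=records)


def write_alignment(a: Alignment, path: str | Path) -> None:
    """Write a gapped FASTA; round-trips through ingest_alignment."""
    write_fasta(a.rows, path)
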