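"""In-silico PCR: binding-site search, amplicon prediction, specificity screens.

A primer binds a template window when every template base is covered by the
corresponding (possibly degenerate) primer base, the perfect-match run from
the primer's 3' terminus reaches the anchor length, and the number of
mismatches (necessarily 5' of the anchor) stays within the budget.  The
defaults — 12 bp 3' anchor, at most 4 mismatches — mirror how the IncP-9
oriV-rep system was validated against its reference replicons.

Coordinates are 0-based half-open on the plus strand internally and 1-based
inclusive in TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design_constraints import PrimerConstraints
from .seqio import (
    GAP,
    Primer,
    ReferencePanel,
    SequenceError,
    SequenceRecord,
    encode,
    reverse_complement,
)


@dataclass(frozen=True)
class BindingSite:
    """A primer hit on the plus strand of a template."""

    record_id: str
    strand: str  # '+' for forward-role hits, '-' for reverse-role hits
    start: int  # 0-based, plus strand
    end: int  # half-open
    n_mismatch: int
    anchor_run: int  # perfect-match run from the primer 3' terminus
    mismatch_positions: tuple[int, ...]  # primer-relative, 0 = 5' end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Amplicon:
    """Predicted PCR product between a forward and a reverse site."""

    record_id: str
    start: int  # forward-site start, plus strand
    end: int  # reverse-site end (j + reverse primer length)
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, record: SequenceRecord) -> str:
        return record.residues[self.start:self.end]


def _window_stats(ok: np.ndarray, from_left: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mismatch counts and anchor runs from a (windows, L) match matrix."""
    L = ok.shape[1]
    n_mm = L - ok.sum(axis=1)
    run_dir = ok if from_left else ok[:, ::-1]
    bad = ~run_dir
    anchor = np.where(bad.any(axis=1), bad.argmax(axis=1), L)
    return n_mm.astype(np.int64), anchor.astype(np.int64)


def _scan(
    site_masks: np.ndarray, target_masks: np.ndarray, anchor_from_left: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-window comparison under the subset rule.

    Returns (match matrix, mismatch counts, anchor runs) over every window.
    `anchor_from_left` selects where on the plus strand the primer 3' end lies.
    """
    L = len(site_masks)
    windows = np.lib.stride_tricks.sliding_window_view(target_masks, L)
    ok = (windows & ~site_masks) == 0
    n_mm, anchor = _window_stats(ok, anchor_from_left)
    return ok, n_mm, anchor


def _site_from_window(
    primer: Primer, record_id: str, pos: int, ok_row: np.ndarray,
    n_mm: int, anchor: int,
) -> BindingSite:
    L = len(primer)
    if primer.role == "forward":
        mm = tuple(int(k) for k in np.flatnonzero(~ok_row))
        strand = "+"
    else:
        # plus-strand window k corresponds to primer position L-1-k
        mm = tuple(sorted(int(L - 1 - k) for k in np.flatnonzero(~ok_row)))
        strand = "-"
    return BindingSite(
        record_id=record_id, strand=strand, start=pos, end=pos + L,
        n_mismatch=int(n_mm), anchor_run=int(anchor), mismatch_positions=mm,
    )


def _all_window_sites(
    primer: Primer, record: SequenceRecord
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Mismatch counts and anchor runs of every window (no thresholds applied)."""
    if GAP in record.residues:
        raise SequenceError(f"record {record.id!r} contains gaps; degap first")
    L = len(primer)
    if len(record) < L:
        return np.empty(0, np.int64), np.empty(0, np.int64), []
    if primer.role == "forward":
        site_seq = primer.sequence5to3
        from_left = False  # 3' end of a forward primer is the window's right edge
    else:
        site_seq = reverse_complement(primer.sequence5to3)
        from_left = True  # reverse primer 3' end maps to the window's left edge
    ok, n_mm, anchor = _scan(encode(site_seq), encode(record.residues), from_left)
    return n_mm, anchor, [ok]  # ok kept for mismatch-position extraction


def find_binding_sites(
    primer: Primer, record: SequenceRecord, constraints: PrimerConstraints
) -> list[BindingSite]:
    """Accepted binding sites of a primer on a record's plus strand.

    Forward-role primers are compared directly against each window; reverse-role
    primers are compared via their reverse complement (the site as it appears on
    the plus strand).  A site is accepted when anchor_run >= anchor_len and
    n_mismatch <= max_mismatch.  Sorted by position.
    """
    n_mm, anchor, oks = _all_window_sites(primer, record)
    if len(n_mm) == 0:
        return []
    ok = oks[0]
    keep = (anchor >= constraints.anchor_len) & (n_mm <= constraints.max_mismatch)
    return [
        _site_from_window(primer, record.id, int(pos), ok[pos], n_mm[pos], anchor[pos])
        for pos in np.flatnonzero(keep)
    ]


def best_binding_site(
    primer: Primer, record: SequenceRecord
) -> Optional[BindingSite]:
    """The best-scoring window regardless of thresholds.

    Ordering: fewest mismatches, then longest anchor, then leftmost.  Returns
    None when the record is shorter than the primer.  Used by the designer to
    report anchor/mismatch statistics even for failing candidates.
    """
    n_mm, anchor, oks = _all_window_sites(primer, record)
    if len(n_mm) == 0:
        return None
    order = np.lexsort((np.arange(len(n_mm)), -anchor, n_mm))
    pos = int(order[0])
    return _site_from_window(primer, record.id, pos, oks[0][pos], n_mm[pos], anchor[pos])


def _mirror_amplicon(amp: Amplicon, n: int) -> tuple[int, int]:
    return n - amp.end, n - amp.start


def predict_amplicons(
    forward: Primer,
    reverse: Primer,
    record: SequenceRecord,
    constraints: PrimerConstraints,
    size_window: Optional[tuple[int, int]] = None,
) -> list[Amplicon]:
    """All predicted products of a primer pair on a (linear) template.

    Every forward-site/reverse-site combination with the reverse site at or
    downstream of the forward site's end yields a product; the opposite
    orientation is captured by re-scanning the reverse complement and
    mirroring coordinates, with duplicates removed by interval.  Products are
    optionally filtered to a size window and sorted by (start, length).
    """
    if forward.role != "forward" or reverse.role != "reverse":
        raise SequenceError("predict_amplicons expects a forward/reverse pair")
    Lf, Lr = len(forward), len(reverse)

    def orientation(rec: SequenceRecord) -> list[Amplicon]:
        f_sites = find_binding_sites(forward, rec, constraints)
        r_sites = find_binding_sites(reverse, rec, constraints)
        out = []
        for fs in f_sites:
            for rs in r_sites:
                if rs.start >= fs.start + Lf:
                    out.append(
                        Amplicon(
                            record_id=record.id,
                            start=fs.start,
                            end=rs.start + Lr,
                            forward_site=fs,
                            reverse_site=rs,
                        )
                    )
        return out

    amps = {(a.start, a.end): a for a in orientation(record)}
    rc = SequenceRecord(
        id=record.id, residues=reverse_complement(record.residues),
        description=record.description, group_label=record.group_label,
    )
    n = len(record)
    for a in orientation(rc):
        s, e = n - a.end, n - a.start
        amps.setdefault((s, e), Amplicon(
            record_id=record.id, start=s, end=e,
            forward_site=a.forward_site, reverse_site=a.reverse_site,
        ))
    result = list(amps.values())
    if size_window is not None:
        lo, hi = size_window
        result = [a for a in result if lo <= a.length <= hi]
    result.sort(key=lambda a: (a.start, a.length))
    return result


@dataclass
class SpecificityReport:
    """Per-record amplification outcomes plus panel-level summary counts."""

    rows: pd.DataFrame  # record_id, is_target, group_label, amplified, n_amplicons, lengths
    amplicons: dict[str, list[Amplicon]]
    targets_amplified: int
    targets_total: int
    nontargets_amplified: int
    nontargets_total: int
    min_target_amplicon: Optional[int]
    max_target_amplicon: Optional[int]

    @property
    def fully_specific(self) -> bool:
        return (
            self.targets_amplified == self.targets_total
            and self.nontargets_amplified == 0
        )


def specificity_screen(
    forward: Primer,
    reverse: Primer,
    panel: ReferencePanel,
    constraints: PrimerConstraints,
    size_window: Optional[tuple[int, int]] = None,
) -> SpecificityReport:
    """Screen a reference panel: every target should amplify, no non-target.

    "Amplified" means at least one predicted product of any size unless a size
    window is supplied — a gel would reveal off-size products anyway, so size
    filtering is opt-in.
    """
    if not panel.targets and not panel.nontargets:
        raise SequenceError("empty panel")
    rows = []
    amplicons: dict[str, list[Amplicon]] = {}
    lengths: list[int] = []
    t_amp = nt_amp = 0
    for rec, is_target in [(r, True) for r in panel.targets] + [
        (r, False) for r in panel.nontargets
    ]:
        amps = predict_amplicons(forward, reverse, rec, constraints, size_window)
        amplicons[rec.id] = amps
        amplified = len(amps) > 0
        if amplified:
            if is_target:
                t_amp += 1
                lengths.extend(a.length for a in amps)
            else:
                nt_amp += 1
        rows.append(
            dict(
                record_id=rec.id,
                is_target=is_target,
                group_label=rec.group_label or "",
                amplified=amplified,
                n_amplicons=len(amps),
                amplicon_lengths=",".join(str(a.length) for a in amps),
            )
        )
    return SpecificityReport(
        rows=pd.DataFrame(rows),
        amplicons=amplicons,
        targets_amplified=t_amp,
        targets_total=len(panel.targets),
        nontargets_amplified=nt_amp,
        nontargets_total=len(panel.nontargets),
        min_target_amplicon=min(lengths) if lengths else None,
        max_target_amplicon=max(lengths) if lengths else None,
    )


def extract_amplicon_records(
    forward: Primer,
    reverse: Primer,
    records: Sequence[SequenceRecord],
    constraints: PrimerConstraints,
    size_window: Optional[tuple[int, int]] = None,
) -> list[SequenceRecord]:
    """Amplicon sequences as records (inputs to phylogenetic classification).

    Group labels are inherited from the template; ids get an ``_amp<k>`` suffix
    when a template yields more than one product.
    """
    out = []
    for rec in records:
        amps = predict_amplicons(forward, reverse, rec, constraints, size_window)
        for k, a in enumerate(amps, start=1):
            suffix = f"_amp{k}" if len(amps) > 1 else "_amp"
            out.append(
                SequenceRecord(
                    id=f"{rec.id}{suffix}",
                    residues=a.sequence(rec),
                    description=f"amplicon {a.start + 1}..{a.end} of {rec.id}",
                    group_label=rec.group_label,
                )
            )
    return out


def sites_to_tsv(sites: Sequence[BindingSite], path: str | Path) -> None:
    """Binding sites as TSV; coordinates 1-based inclusive."""
    df = pd.DataFrame(
        dict(
            record_id=[s.record_id for s in sites],
            strand=[s.strand for s in sites],
            start=[s.start + 1 for s in sites],
            end=[s.end for s in sites],
            n_mismatch=[s.n_mismatch for s in sites],
            anchor_run=[s.anchor_run for s in sites],
            mismatch_positions=[
                ",".join(map(str, s.mismatch_positions)) for s in sites
            ],
        )
    )
    df.to_csv(path, sep="\t", index=False)


def amplicons_to_tsv(amps: Sequence[Amplicon], path: str | Path) -> None:
    """Amplicons as TSV; coordinates 1-based inclusive."""
    df = pd.DataFrame(
        dict(
            record_id=[a.record_id for a in amps],
            start=[a.start + 1 for a in amps],
            end=[a.end for a in amps],
            length=[a.length for a in amps],
            fwd_mismatches=[a.forward_site.n_mismatch for a in amps],
            rev_mismatches=[a.reverse_site.n_mismatch for a in amps],
        )
    )
    df.to_csv(path, sep="\t", index=False)
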