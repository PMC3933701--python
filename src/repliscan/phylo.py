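"""Distance phylogenetics and subgroup classification of amplicons.

Pairwise distances are proportions of differing sites over pairwise-deleted
columns (literal character inequality after normalization), optionally
Jukes-Cantor corrected.  Trees are built by Saitou-Nei neighbor joining with
the Studier-Keppler Q criterion; ties in Q are resolved by the lowest
(row, column) index pair and negative branch lengths are clamped to zero, so
tree construction is fully deterministic.  Bootstrap supports come from
column resampling; classification assigns each query amplicon the subgroup
of its nearest labelled reference, declaring queries beyond a distance
ceiling "unaffiliated" — the signal used to flag novel replicon types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .msa import DEFAULT_SCORES, Alignment, AlignScores, progressive_align
from .seqio import GAP, SequenceError, SequenceRecord

PhyloTree = TreeNode

UNAFFILIATED = "unaffiliated"


def _char_matrix(a: Alignment) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8) for r in a.rows]
    )


_GAP_CODE = ord(GAP)


def p_distance(a: Alignment) -> DistanceMatrix:
    """Proportion of differing sites under pairwise deletion.

    Columns where either row carries a gap are skipped for that pair; remaining
    residues are compared literally (an N differs from an A even though their
    expansions intersect).  A pair sharing zero comparable columns is an error.
    """
    chars = _char_matrix(a)
    n = len(a)
    ids = [r.id for r in a.rows]
    d = np.zeros((n, n))
    nongap = chars != _GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise SequenceError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = (chars[i, both] != chars[j, both]).sum() / m
    return DistanceMatrix(d, ids)


def jc_correct(p):
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3), in substitutions/site.

    Valid for 0 <= p < 0.75; saturated proportions raise rather than being
    silently clamped, because infinite distances corrupt neighbor joining.
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative proportion")
    if (arr >= 0.75).any():
        raise ValueError("saturated distance: p >= 0.75 has no Jukes-Cantor correction")
    out = -0.75 * np.log1p(-4.0 * arr / 3.0)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def distance_matrix(a: Alignment, model: str = "jc") -> DistanceMatrix:
    """Alignment distances under the chosen model ('jc' default, or 'p')."""
    pm = p_distance(a)
    if model == "p":
        return pm
    if model == "jc":
        return DistanceMatrix(jc_correct(pm.data), list(pm.ids))
    raise ValueError(f"unknown distance model {model!r}")


def nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei) producing an unrooted tree.

    The returned TreeNode has a trifurcating root standing in for the unrooted
    topology.  Q-ties break to the lowest (row, column) pair in current matrix
    order; negative branch lengths are clamped to 0 without redistribution.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(Q[iu]))  # row-major scan => lowest (i, j) on ties
        i, j = int(iu[0][k]), int(iu[1][k])
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        gi, gj = active[i], active[j]
        nodes[gi].length = max(li, 0.0)
        nodes[gj].length = max(lj, 0.0)
        parent = TreeNode()
        parent.append(nodes[gi])
        parent.append(nodes[gj])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for idx, g in enumerate(active):
            if g in (gi, gj):
                continue
            new_row[g] = 0.5 * (D[gi, g] + D[gj, g] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # resolve the final three nodes with the three-point formulas
    x, y, z = active
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    nodes[x].length = max(0.5 * (dxy + dxz - dyz), 0.0)
    nodes[y].length = max(0.5 * (dxy + dyz - dxz), 0.0)
    nodes[z].length = max(0.5 * (dxz + dyz - dxy), 0.0)
    root = TreeNode()
    for g in (x, y, z):
        root.append(nodes[g])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as normalized tip sets.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest tip name is kept, so the representation is
    independent of rooting.  Trivial splits (single tip or its complement)
    are excluded.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    n = len(all_tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def bootstrap_support(
    a: Alignment,
    n_reps: int = 1000,
    seed: Optional[int] = 42,
    model: str = "jc",
) -> TreeNode:
    """NJ tree of an alignment with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate (the column-index
    stream depends only on the seed and replicate number, never on row order);
    each replicate tree is rebuilt by NJ and a split's support is the
    percentage of replicates containing it, stored as ``node.support``.
    """
    if len(a) < 4:
        raise ValueError("bootstrap needs an alignment with at least 4 rows")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj(distance_matrix(a, model))
    orig = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    ncols = a.column_count
    ids = [r.id for r in a.rows]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = Alignment(
            rows=[
                SequenceRecord(id=r.id, residues="".join(r.residues[c] for c in cols),
                               group_label=r.group_label)
                for r in a.rows
            ]
        )
        rep_bps = bipartitions(nj(distance_matrix(rep, model)))
        for bp in orig:
            if bp in rep_bps:
                orig[bp] += 1
    all_tips = frozenset(ids)
    ref = min(all_tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if side in orig:
            node.support = 100.0 * orig[side] / n_reps
    return tree


@dataclass
class SubgroupAssignment:
    """Classification of one query amplicon against the labelled references."""

    query_id: str
    label: str  # subgroup label, or "unaffiliated"
    nearest_reference: str
    distance: float  # substitutions/site to the nearest reference
    support: float  # % of bootstrap replicates agreeing on the label


def classify_amplicons(
    queries: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    tau: float = 0.10,
    n_reps: int = 100,
    seed: Optional[int] = 42,
    scores: AlignScores = DEFAULT_SCORES,
    model: str = "jc",
) -> list[SubgroupAssignment]:
    """Assign each query the subgroup of its nearest labelled reference.

    Queries and references are co-aligned; each query takes the label of its
    nearest reference by (JC-corrected) distance under pairwise deletion, with
    ties resolved toward the earliest reference in input order.  A query whose
    nearest distance exceeds ``tau`` is "unaffiliated" (a candidate novel
    type).  Support is the percentage of column-resampling replicates in which
    the nearest reference carries the same label; within replicates, saturated
    or incomparable pairs are treated as infinitely distant.
    """
    if not queries:
        raise SequenceError("no queries")
    labels = [r.group_label for r in references]
    if any(lbl is None for lbl in labels):
        raise SequenceError("every reference needs a group_label")
    if len(set(labels)) < 2:
        raise SequenceError("references must cover at least 2 distinct labels")
    combined = list(references) + list(queries)
    aln = progressive_align(combined, scores)
    chars = _char_matrix(aln)
    nongap = chars != _GAP_CODE
    R = len(references)
    ncols = aln.column_count

    def query_distances(cols: Optional[np.ndarray], qi: int) -> np.ndarray:
        """JC distances of query row qi to all references; inf when undefined."""
        c = chars if cols is None else chars[:, cols]
        ng = nongap if cols is None else nongap[:, cols]
        d = np.full(R, np.inf)
        for ri in range(R):
            both = ng[ri] & ng[qi]
            m = int(both.sum())
            if m == 0:
                continue
            p = (c[ri, both] != c[qi, both]).sum() / m
            if model == "jc":
                if p >= 0.75:
                    continue
                d[ri] = -0.75 * np.log1p(-4.0 * p / 3.0)
            else:
                d[ri] = p
        return d

    rng = np.random.default_rng(seed)
    replicate_cols = [rng.integers(0, ncols, size=ncols) for _ in range(max(n_reps, 0))]

    out: list[SubgroupAssignment] = []
    for k, q in enumerate(queries):
        qi = R + k
        d = query_distances(None, qi)
        if not np.isfinite(d).any():
            raise SequenceError(
                f"query {q.id!r} shares no comparable columns with any reference"
            )
        best = int(np.argmin(d))  # argmin takes the lowest index on ties
        dist = float(d[best])
        label = references[best].group_label if dist <= tau else UNAFFILIATED
        agree = 0
        for cols in replicate_cols:
            db = query_distances(cols, qi)
            if not np.isfinite(db).any():
                continue
            b = int(np.argmin(db))
            rep_label = (
                references[b].group_label if db[b] <= tau else UNAFFILIATED
            )
            if rep_label == label:
                agree += 1
        support = 100.0 * agree / len(replicate_cols) if replicate_cols else 100.0
        out.append(
            SubgroupAssignment(
                query_id=q.id,
                label=label,  # type: ignore[arg-type]
                nearest_reference=references[best].id,
                distance=dist,
                support=support,
            )
        )
    return out


def assignments_to_tsv(
    assignments: Sequence[SubgroupAssignment], path: str | Path
) -> None:
    pd.DataFrame(
        dict(
            query_id=[a.query_id for a in assignments],
            label=[a.label for a in assignments],
            nearest_reference=[a.nearest_reference for a in assignments],
            distance=[round(a.distance, 6) for a in assignments],
            support=[round(a.support, 1) for a in assignments],
        )
    ).to_csv(path, sep="\t", index=False)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick with branch lengths and integer bootstrap supports as labels.

    Labels with spaces follow the Newick underscore convention (written as
    underscores, read back as spaces), so ``read_newick(write_newick(t))``
    preserves labels, topology, lengths and supports.
    """
    t = tree.copy()
    for node in t.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.support = int(round(sup))  # skbio serializes this as the label
    t.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Read Newick; numeric internal labels are interpreted as supports."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
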