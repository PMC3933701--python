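"""Distances, neighbor joining, bootstrap supports and amplicon classification."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from repliscan.msa import Alignment
from repliscan.phylo import (
    UNAFFILIATED,
    bipartitions,
    bootstrap_support,
    classify_amplicons,
    distance_matrix,
    jc_correct,
    nj,
    p_distance,
    read_newick,
    write_newick,
)
from repliscan.seqio import SequenceError, SequenceRecord


def _aln(pairs):
    return Alignment(rows=[SequenceRecord(id=i, residues=s) for i, s in pairs])


def _supports(tree):
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        out[side] = getattr(node, "support", None)
    return out


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        dm = p_distance(_aln([("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")]))
        assert dm["a", "b"] == 0

    def test_one_difference_over_ten_columns(self):
        dm = p_distance(_aln([("a", "ACGTACGTAC"), ("b", "ACGTACGTAT")]))
        assert dm["a", "b"] == pytest.approx(0.1)

    def test_pairwise_deletion_skips_gap_columns(self):
        dm = p_distance(_aln([("a", "AC-T"), ("b", "ACGT")]))
        assert dm["a", "b"] == 0

    def test_literal_comparison_counts_compatible_codes_as_different(self):
        dm = p_distance(_aln([("a", "WAAA"), ("b", "AAAA")]))
        assert dm["a", "b"] == pytest.approx(0.25)

    def test_zero_comparable_columns_is_an_error(self):
        with pytest.raises(SequenceError, match="comparable"):
            p_distance(_aln([("a", "AC--"), ("b", "--GT")]))


class TestJukesCantor:
    def test_closed_form_spot_values(self):
        assert jc_correct(0.0) == 0.0
        assert jc_correct(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert jc_correct(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_is_an_error_not_a_clamp(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_correct(0.75)

    def test_strictly_increasing_and_at_least_p(self):
        ps = np.linspace(0, 0.74, 200)
        ds = jc_correct(ps)
        assert (np.diff(ds) > 0).all()
        assert (ds >= ps).all()


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree as (edge dict, leaf names, bipartitions)."""
    # adjacency: node -> list of (neighbor, length); leaves are 'L0'..'L{n-1}'
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"I{next_internal[0]}"

    adj = {}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def remove_edge(u, v):
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]

    blen = lambda: float(rng.uniform(0.1, 1.0))
    center = new_internal()
    for k in range(3):
        add_edge(center, f"L{k}", blen())
    for k in range(3, n_leaves):
        edges = sorted(
            {tuple(sorted((u, v))) for u in adj for v, _ in adj[u]}
        )
        u, v = edges[rng.integers(0, len(edges))]
        w = dict(adj[u])[v]
        mid = new_internal()
        remove_edge(u, v)
        add_edge(u, mid, w / 2)
        add_edge(mid, v, w / 2)
        add_edge(mid, f"L{k}", blen())
    leaves = [f"L{k}" for k in range(n_leaves)]

    def path_lengths(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(leaves):
        d = path_lengths(a)
        for j, b in enumerate(leaves):
            D[i, j] = d[b]
    D = (D + D.T) / 2  # exact symmetry despite float summation order
    np.fill_diagonal(D, 0.0)

    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    bps = set()
    for u in adj:
        for v, _ in adj[u]:
            if u > v:
                continue
            # leaves on v's side after cutting (u, v)
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x.startswith("L"):
                    side.add(x)
                for y, _ in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            fz = frozenset(side)
            if ref in fz:
                fz = all_leaves - fz
            if 2 <= len(fz) <= n_leaves - 2:
                bps.add(fz)
    return D, leaves, bps


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = nj(DistanceMatrix(d, list("ABCD")))
        assert bipartitions(tree) == {frozenset({"C", "D"})}  # the AB|CD split
        lengths = {t.name: t.length for t in tree.tips()}
        assert all(l == pytest.approx(1.0) for l in lengths.values())
        (internal,) = list(tree.non_tips(include_self=False))
        assert internal.length == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj(DistanceMatrix(d, list("ABC")))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.5 * (3 + 4 - 5))
        assert lengths["B"] == pytest.approx(0.5 * (3 + 5 - 4))
        assert lengths["C"] == pytest.approx(0.5 * (4 + 5 - 3))

    def test_all_equal_distances_join_lowest_pair_first(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj(DistanceMatrix(d, list("ABCD")))
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_topology_from_additive_distances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        D, leaves, true_bps = random_additive_tree(rng, n)
        tree = nj(DistanceMatrix(D, leaves))
        assert bipartitions(tree) == true_bps

    def test_agrees_with_independent_nj_implementation(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(123)
        D, leaves, _ = random_additive_tree(rng, 7)
        # perturb slightly so the matrix is generic but still tree-like
        noise = rng.uniform(-0.01, 0.01, size=D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(D, leaves)
        assert bipartitions(nj(dm)) == bipartitions(skbio_nj(dm))


class TestBootstrap:
    def _split_alignment(self):
        return _aln(
            [
                ("a", "AAAAAAAAAAAAAAAAAAAA"),
                ("b", "AAAAAAAAAAAAAAAAAAAT"),
                ("c", "TTTTTTTTTTTTTTTTTTTA"),
                ("d", "TTTTTTTTTTTTTTTTTTTT"),
            ]
        )

    def test_perfectly_split_alignment_gets_full_support(self):
        tree = bootstrap_support(self._split_alignment(), n_reps=50, seed=0, model="p")
        sup = _supports(tree)
        assert sup[frozenset({"c", "d"})] == 100.0

    def test_single_replicate_supports_are_all_or_nothing(self):
        tree = bootstrap_support(self._split_alignment(), n_reps=1, seed=3, model="p")
        assert set(_supports(tree).values()) <= {0.0, 100.0}

    def test_seeded_runs_are_identical(self):
        t1 = bootstrap_support(self._split_alignment(), n_reps=30, seed=9, model="p")
        t2 = bootstrap_support(self._split_alignment(), n_reps=30, seed=9, model="p")
        assert _supports(t1) == _supports(t2)

    def test_supports_invariant_to_row_order(self):
        # hierarchically mutated random sequences: generic distances, so
        # no replicate ever hits a Q-matrix tie and row order cannot matter
        rng = np.random.default_rng(17)
        bases = "ACGT"

        def mutate(s, k):
            s = list(s)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = bases[(bases.index(s[pos]) + rng.integers(1, 4)) % 4]
            return "".join(s)

        root = "".join(bases[i] for i in rng.integers(0, 4, size=160))
        left, right = mutate(root, 30), mutate(root, 45)
        rows = [
            ("a", mutate(left, 2)), ("b", mutate(left, 8)), ("c", mutate(left, 16)),
            ("d", mutate(right, 3)), ("e", mutate(right, 11)),
        ]
        t1 = bootstrap_support(_aln(rows), n_reps=40, seed=5, model="p")
        t2 = bootstrap_support(_aln(rows[::-1]), n_reps=40, seed=5, model="p")
        assert _supports(t1) == _supports(t2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_support(self._split_alignment(), n_reps=0)
        with pytest.raises(ValueError, match="4 rows"):
            bootstrap_support(_aln([("a", "AA"), ("b", "AT"), ("c", "TT")]))


class TestNewick:
    def test_three_leaf_form_and_round_trip(self, tmp_path):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj(DistanceMatrix(d, ["A", "B", "C"]))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text.startswith("(") and text.endswith(";")
        back = read_newick(path)
        assert {t.name for t in back.tips()} == {"A", "B", "C"}
        assert {t.name: round(t.length, 6) for t in back.tips()} == {
            t.name: round(t.length, 6) for t in tree.tips()
        }

    def test_labels_with_spaces_survive_round_trip(self, tmp_path):
        aln = _aln(
            [
                ("taxon one", "AAAAAAAAAA"),
                ("b", "AAAAAAAAAT"),
                ("c", "TTTTTTTTTA"),
                ("d", "TTTTTTTTTT"),
            ]
        )
        tree = bootstrap_support(aln, n_reps=10, seed=1, model="p")
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert "taxon one" in {t.name for t in back.tips()}
        assert bipartitions(back) == bipartitions(tree)
        assert _supports(back) == {k: float(int(round(v))) for k, v in _supports(tree).items()}


class TestClassification:
    def _references(self):
        rng = np.random.default_rng(0)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        return [
            SequenceRecord(id="ref_x", residues=base, group_label="X"),
            SequenceRecord(id="ref_y", residues=other, group_label="Y"),
        ]

    def test_identical_query_gets_label_distance_zero_full_support(self):
        refs = self._references()
        q = SequenceRecord(id="q", residues=refs[0].residues)
        (a,) = classify_amplicons([q], refs, n_reps=30, seed=1)
        assert a.label == "X" and a.distance == 0.0 and a.support == 100.0
        assert a.nearest_reference == "ref_x"

    def test_equidistant_query_breaks_tie_to_first_reference(self):
        rng = np.random.default_rng(4)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))

        def mutate_at(s, positions):
            return "".join(
                ("ACGT"[("ACGT".index(c) + 1) % 4] if k in positions else c)
                for k, c in enumerate(s)
            )

        # query differs from each reference at 10 disjoint positions
        r1 = SequenceRecord(id="r1", residues=mutate_at(base, set(range(0, 20, 2))),
                            group_label="X")
        r2 = SequenceRecord(id="r2", residues=mutate_at(base, set(range(21, 41, 2))),
                            group_label="Y")
        q = SequenceRecord(id="q", residues=base)
        (a,) = classify_amplicons([q], [r1, r2], n_reps=200, seed=2)
        assert a.label == "X" and a.nearest_reference == "r1"
        assert 35 < a.support < 75  # a coin flip plus the deterministic tie-break

    def test_distant_query_is_unaffiliated(self):
        refs = self._references()
        rng = np.random.default_rng(99)
        q = SequenceRecord(
            id="q", residues="".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        )
        (a,) = classify_amplicons([q], refs, tau=0.05, n_reps=10, seed=3)
        assert a.label == UNAFFILIATED

    def test_synthetic_queries_classify_to_their_subgroup(self, default_panel):
        from repliscan.design_constraints import PrimerConstraints
        from repliscan.ispcr import extract_amplicon_records
        from repliscan.registry import INCP9_FORWARD, INCP9_REVERSE
        from repliscan.synthdata import simulate_queries

        panel, truth = default_panel
        queries = simulate_queries(truth, n_per_subgroup=1, divergence=0.02, seed=5)
        refs = extract_amplicon_records(
            INCP9_FORWARD, INCP9_REVERSE, panel.targets, PrimerConstraints()
        )
        assignments = classify_amplicons(queries, refs, n_reps=20, seed=6)
        for q, a in zip(queries, assignments):
            assert a.label == q.group_label
            assert a.distance <= 0.10

    def test_no_queries_is_an_error(self):
        with pytest.raises(SequenceError, match="no queries"):
            classify_amplicons([], self._references())

    def test_references_need_two_labels(self):
        refs = self._references()
        refs[1].group_label = "X"
        q = SequenceRecord(id="q", residues=refs[0].residues)
        with pytest.raises(SequenceError, match="2 distinct"):
            classify_amplicons([q], refs)
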