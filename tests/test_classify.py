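"""Helix parsing, tails, Dps signature, NJ and bootstrap consensus."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpsevolve import classify
from dpsevolve.records import ProteinRecord


def _segments_from_lengths(lengths, loop=4, n_tail=0):
    """Build an SS string with helices of the given lengths."""
    parts = ["C" * n_tail]
    for i, h in enumerate(lengths):
        parts.append("H" * h)
        if i < len(lengths) - 1:
            parts.append("C" * loop)
    return "".join(parts)


class TestHelixAndTails:
    @pytest.mark.parametrize("ss,min_len,expected", [
        ("HHHCCHHH", 3, [(0, 3), (5, 8)]),
        ("CCCC", 3, []),
        ("HHCHH", 3, []),
    ])
    def test_helix_segments(self, ss, min_len, expected):
        segs = classify.helix_segments(ss, min_len)
        assert [(s.start, s.end) for s in segs] == expected

    def test_illegal_state_rejected(self):
        with pytest.raises(ValueError, match="illegal SS state"):
            classify.helix_segments("HHXH")

    @pytest.mark.parametrize("ss,expected", [
        ("CCCHHHHC", (3, 1)),
        ("HHHH", (0, 0)),
    ])
    def test_tail_lengths(self, ss, expected):
        assert classify.tail_lengths(ss) == expected

    def test_no_helix_error(self):
        with pytest.raises(ValueError, match="not helical"):
            classify.tail_lengths("CCCCEEE")

    def test_partition_identity(self):
        # n_tail + helix/loop interior + c_tail spans the whole string
        ss = "CC" + "HHHH" + "CCC" + "HHHHH" + "C"
        n, c = classify.tail_lengths(ss)
        segs = classify.helix_segments(ss)
        interior = segs[-1].end - segs[0].start
        assert n + interior + c == len(ss)

    @pytest.mark.parametrize("n,c,cat", [
        (2, 1, "short/short"),
        (15, 2, "long-N"),
        (2, 15, "long-C"),
        (12, 12, "long/long"),
        (10, 9, "long-N"),  # boundary: >= threshold is long
    ])
    def test_classify_tails(self, n, c, cat):
        assert classify.classify_tails(n, c, long_threshold=10) == cat

    def test_planted_tails_recovered(self, small_cohort):
        for g in small_cohort.genomes:
            for pid, (ss, _conf) in g.ss.items():
                assert classify.tail_lengths(ss) == \
                    tuple(small_cohort.truth.planted_tails[pid])


class TestSignature:
    @pytest.mark.parametrize("lengths,expected", [
        ([18, 16, 6, 17, 15], (True, True)),    # five helices, middle shortest
        ([18, 16, 17, 15], (False, False)),     # ferritin-like: four helices
        ([18, 16, 20, 17, 15], (False, False)),  # middle not shortest
        ([18, 16, 16, 17, 15], (False, False)),  # ties are not strictly shortest
    ])
    def test_is_dps_signature(self, lengths, expected):
        segs = classify.helix_segments(_segments_from_lengths(lengths))
        assert classify.is_dps_signature(segs) == expected

    def test_bc_helix_max_length(self):
        segs = classify.helix_segments(
            _segments_from_lengths([20, 19, 16, 18, 17]))
        # middle strictly shortest but longer than bc_max_len
        assert classify.is_dps_signature(segs, bc_max_len=15) == (False, False)


class TestConfidenceFilter:
    def _rec(self, conf):
        return ProteinRecord(f"p{conf}", "MKL", ss="HHH", ss_confidence=conf)

    def test_strict_threshold(self):
        kept = classify.filter_by_confidence([self._rec(39), self._rec(40)])
        assert [r.ss_confidence for r in kept] == [40]

    def test_empty_input(self):
        assert classify.filter_by_confidence([]) == []

    def test_idempotent(self):
        recs = [self._rec(c) for c in (10, 40, 90)]
        once = classify.filter_by_confidence(recs)
        assert classify.filter_by_confidence(once) == once


class TestPDistance:
    def test_identical_rows_zero(self):
        D, _ = classify.p_distance_matrix([("a", "AAAA"), ("b", "AAAA")])
        assert D[0, 1] == 0.0

    def test_quarter_mismatch(self):
        D, _ = classify.p_distance_matrix([("a", "AAAA"), ("b", "AAAT")])
        assert D[0, 1] == 0.25

    def test_gap_columns_excluded(self):
        D, _ = classify.p_distance_matrix([("a", "AA-A"), ("b", "AATA")])
        assert D[0, 1] == 0.0

    def test_no_comparable_columns_error(self):
        with pytest.raises(ValueError, match="comparable"):
            classify.p_distance_matrix([("a", "AA--"), ("b", "--AA")])


def _topology_splits(tree):
    """Non-trivial splits as frozensets of leaf labels (smaller side)."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(labels) - 1:
            splits.add(min(below, labels - below, key=sorted))
    return splits


def _random_additive(rng, n_taxa):
    """A random unrooted binary tree and its exact leaf distance matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    # build random topology by sequential attachment
    import random as _random
    pyr = _random.Random(int(rng.integers(2**31)))
    nodes = {t: dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa}
    root = dendropy.Node()
    for t in taxa[:3]:
        root.add_child(nodes[t])
        nodes[t].edge.length = rng.uniform(0.1, 1.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    for t in taxa[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        e = pyr.choice(edges)
        head, tail = e.head_node, e.tail_node
        mid = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(mid)
        mid.add_child(head)
        split = rng.uniform(0.2, 0.8) * e.length
        mid.edge.length = e.length - split
        head.edge.length = split
        leaf = nodes[t]
        mid.add_child(leaf)
        leaf.edge.length = rng.uniform(0.1, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    D = np.array([[pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in taxa]
                  for a in taxa])
    return tree, D, taxa


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = classify.nj_tree(D, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(ValueError):
            classify.nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_quartet_matches_least_squares_bruteforce(self):
        from .oracles import best_quartet_topology
        taxa = ["A", "B", "C", "D"]
        D = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                     float)
        tree = classify.nj_tree(D, taxa)
        got = _topology_splits(tree)
        d = {frozenset((taxa[i], taxa[j])): D[i, j]
             for i in range(4) for j in range(i + 1, 4)}
        (p, q), _ = best_quartet_topology(d, taxa)
        assert got == {frozenset((p, q))}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_additive_matrix_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        src, D, taxa = _random_additive(rng, n)
        est = classify.nj_tree(D, taxa)
        assert _topology_splits(est) == _topology_splits(src)
        pdm = est.phylogenetic_distance_matrix()
        tns = est.taxon_namespace
        for i, a in enumerate(taxa):
            for j in range(i + 1, n):
                d = pdm.distance(tns.get_taxon(a), tns.get_taxon(taxa[j]))
                assert d == pytest.approx(D[i, j], abs=1e-9)


class TestBootstrapConsensus:
    ROWS = [("A", "AAAAAAAAAAGGGGG"), ("B", "AAAAAAAAAACCCCC"),
            ("C", "TTTTTTTTTTGGGGG"), ("D", "TTTTTTTTTTCCCCC"),
            ("E", "TTTTTTTTTAGGGGG")]

    def test_saturated_clades_full_support(self):
        rows = [("A", "AAAAAAAAAA"), ("B", "AAAAAAAAAA"),
                ("C", "TTTTTTTTTT"), ("D", "TTTTTTTTTT")]
        tree = classify.bootstrap_consensus(rows, n_reps=20, seed=0)
        supports = [float(n.label) for n in tree.preorder_node_iter()
                    if n.label is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_degenerate(self):
        tree = classify.bootstrap_consensus(self.ROWS, n_reps=1, seed=5)
        supports = [float(n.label) for n in tree.preorder_node_iter()
                    if n.label is not None]
        assert set(supports) <= {100.0}

    def test_same_seed_identical(self):
        t1 = classify.bootstrap_consensus(self.ROWS, n_reps=25, seed=9)
        t2 = classify.bootstrap_consensus(self.ROWS, n_reps=25, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_invariant_under_taxon_permutation(self):
        # saturated pairs: every replicate recovers the same three cherries
        # whatever the agglomeration tie-breaks, so supports must match
        rows = [("A", "AAAAAAAAGGGGGGGGTTTTTTTT"),
                ("B", "AAAAAAAAGGGGGGGGTTTTTTTT"),
                ("C", "CCCCCCCCGGGGGGGGTTTTTTTT"),
                ("D", "CCCCCCCCGGGGGGGGTTTTTTTT"),
                ("E", "CCCCCCCCAAAAAAAATTTTTTTT"),
                ("F", "CCCCCCCCAAAAAAAATTTTTTTT")]
        perm = rows[::-1]
        t1 = classify.bootstrap_consensus(rows, n_reps=40, seed=2)
        # the column draws are taxon-independent, so the same seed resamples
        # the same columns for the permuted input
        t2 = classify.bootstrap_consensus(perm, n_reps=40, seed=2)

        def support_map(tree):
            labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
            out = {}
            for node in tree.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None or node.label is None:
                    continue
                below = frozenset(lf.taxon.label for lf in node.leaf_iter())
                out[min(below, labels - below, key=sorted)] = float(node.label)
            return out

        assert support_map(t1) == support_map(t2)


class TestBfrExclusion:
    def _tree(self):
        return dendropy.Tree.get(
            data="((dps1:0.1,dps2:0.1):0.8,((bfr_ref:0.1,impostor:0.1):0.1,dps3:0.6):0.8);",
            schema="newick", preserve_underscores=True)

    def _rec(self, rid, five_helix=True):
        if five_helix:
            ss = _segments_from_lengths([18, 16, 6, 17, 15])
        else:
            ss = _segments_from_lengths([18, 16, 17, 15])
        return ProteinRecord(rid, "M" * len(ss), ss=ss, ss_confidence=90)

    def test_conjunction_required(self):
        tree = self._tree()
        records = [
            self._rec("dps1"), self._rec("dps2"),
            self._rec("impostor", five_helix=False),  # in clade, no BC helix
            self._rec("dps3", five_helix=True),       # outside clade
        ]
        kept = classify.exclude_bacterioferritins(records, tree, ["bfr_ref"])
        assert [r.id for r in kept] == ["dps1", "dps2", "dps3"]

    def test_in_clade_with_signature_retained(self):
        tree = self._tree()
        records = [self._rec("impostor", five_helix=True)]
        kept = classify.exclude_bacterioferritins(records, tree, ["bfr_ref"])
        assert [r.id for r in kept] == ["impostor"]

    def test_outside_clade_without_bc_retained(self):
        tree = self._tree()
        records = [self._rec("dps3", five_helix=False)]
        kept = classify.exclude_bacterioferritins(records, tree, ["bfr_ref"])
        assert [r.id for r in kept] == ["dps3"]

    def test_missing_reference_error(self):
        with pytest.raises(ValueError, match="absent"):
            classify.exclude_bacterioferritins([], self._tree(), ["nope"])
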