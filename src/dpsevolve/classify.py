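"""Dps structural validation and distance-based phylogenetics.

Dps mini-ferritins carry five alpha helices, the third being the short
central "BC helix" that ferritins and bacterioferritins lack; N- and
C-terminal tails are the residues before the first and after the last helix.
Secondary-structure state strings (H/E/C, one state per residue) are consumed
as input, together with an overall prediction confidence used to drop poorly
predicted records (default: confidence below 40% removed).

The discrimination tree is neighbor joining (Saitou-Nei) on p-distances, with
majority-rule bootstrap consensus; sequences are excluded as bacterioferritin
only when they both fall in the bacterioferritin reference clade (under
midpoint rooting) and lack the BC-helix signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .records import SS_STATES, ProteinRecord

# structural thresholds: the source analysis never quantifies "short" vs
# "long"; these reproduce the qualitative classes and are config-exposed
MIN_HELIX_LEN = 3
BC_MAX_LEN = 15
LONG_TAIL_THRESHOLD = 10
DEFAULT_MIN_CONFIDENCE = 40.0

TAIL_CATEGORIES = ("short/short", "long-N", "long-C", "long/long")


@dataclass(frozen=True)
class HelixSegment:
    """A maximal helix run, 0-based half-open residue indices."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TailProfile:
    n_tail: int
    c_tail: int
    category: str


def helix_segments(ss: str, min_len: int = MIN_HELIX_LEN) -> list[HelixSegment]:
    """Maximal runs of H with length >= min_len, in N->C order."""
    for i, c in enumerate(ss):
        if c not in SS_STATES:
            raise ValueError(f"illegal SS state {c!r} at position {i}")
    segments = []
    i = 0
    n = len(ss)
    while i < n:
        if ss[i] == "H":
            j = i
            while j < n and ss[j] == "H":
                j += 1
            if j - i >= min_len:
                segments.append(HelixSegment(i, j))
            i = j
        else:
            i += 1
    return segments


def tail_lengths(ss: str, min_len: int = MIN_HELIX_LEN) -> tuple[int, int]:
    """Residue counts before the first and after the last helix."""
    segs = helix_segments(ss, min_len)
    if not segs:
        raise ValueError("not helical: no helix segment of minimum length")
    return segs[0].start, len(ss) - segs[-1].end


def classify_tails(n_tail: int, c_tail: int,
                   long_threshold: int = LONG_TAIL_THRESHOLD) -> str:
    if n_tail < 0 or c_tail < 0:
        raise ValueError("tail lengths must be non-negative")
    long_n = n_tail >= long_threshold
    long_c = c_tail >= long_threshold
    if long_n and long_c:
        return "long/long"
    if long_n:
        return "long-N"
    if long_c:
        return "long-C"
    return "short/short"


def tail_profile(ss: str, long_threshold: int = LONG_TAIL_THRESHOLD,
                 min_len: int = MIN_HELIX_LEN) -> TailProfile:
    n_tail, c_tail = tail_lengths(ss, min_len)
    return TailProfile(n_tail, c_tail, classify_tails(n_tail, c_tail, long_threshold))


def is_dps_signature(segments: Sequence[HelixSegment],
                     bc_max_len: int = BC_MAX_LEN) -> tuple[bool, bool]:
    """(is Dps, has BC helix): five helices with the middle strictly shortest.

    The BC-helix condition is that the third of five segments is strictly the
    shortest and at most ``bc_max_len`` residues; ``has_bc_helix`` reports
    that condition on its own (it is False whenever there are not five
    helices, since "the middle of five" is then undefined).
    """
    if len(segments) != 5:
        return False, False
    lengths = [s.length for s in segments]
    mid = lengths[2]
    others = lengths[:2] + lengths[3:]
    has_bc = mid <= bc_max_len and all(mid < o for o in others)
    return has_bc, has_bc


def filter_by_confidence(records: Sequence[ProteinRecord],
                         min_conf: float = DEFAULT_MIN_CONFIDENCE) -> list[ProteinRecord]:
    """Drop records whose SS confidence is strictly below ``min_conf``."""
    out = []
    for r in records:
        if r.ss_confidence is None:
            raise ValueError(f"protein {r.id!r} lacks ss_confidence")
        if r.ss_confidence >= min_conf:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def p_distance_matrix(rows: Sequence[tuple[str, str]]) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances from an ungapped-or-gapped alignment.

    ``rows`` are (taxon, aligned sequence) pairs of equal length. For each
    pair, columns where either sequence has a gap ('-') are ignored;
    d = mismatches / compared columns. A pair with zero comparable columns is
    an error.
    """
    taxa = [t for t, _ in rows]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels in alignment")
    seqs = [s for _, s in rows]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("aligned rows have unequal lengths")
    X = np.array([list(s) for s in seqs])
    valid = X != "-"
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            ncomp = int(comp.sum())
            if ncomp == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}")
            D[i, j] = D[j, i] = np.count_nonzero(X[i][comp] != X[j][comp]) / ncomp
    return D, taxa


def nj_tree(dist, taxa: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Standard agglomeration with the Studier-Keppler Q criterion; negative
    branch lengths are clamped to zero. Returns an unrooted dendropy tree
    whose seed node is the final trifurcation. Requires >= 3 taxa and a
    symmetric, non-negative matrix.
    """
    D = np.asarray(dist, dtype=float).copy()
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")

    tns = dendropy.TaxonNamespace([str(t) for t in taxa])
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(str(t))) for i, t in enumerate(taxa)
    }
    active = list(range(n))
    next_idx = n
    # grow D as nodes are added
    full = np.zeros((2 * n, 2 * n))
    full[:n, :n] = D

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = full[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: smallest (i, j) in current active order
        amin = np.unravel_index(np.argmin(Q), Q.shape)
        a, b = sorted((int(amin[0]), int(amin[1])))
        i, j = idx[a], idx[b]
        d_ij = full[i, j]
        li = 0.5 * d_ij + (r[a] - r[b]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = dendropy.Node()
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes[next_idx] = u
        for k in active:
            if k != i and k != j:
                duk = 0.5 * (full[i, k] + full[j, k] - d_ij)
                full[next_idx, k] = full[k, next_idx] = duk
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    # final trifurcation: three-point formulas
    x, y, z = active
    dxy, dxz, dyz = full[x, y], full[x, z], full[y, z]
    root = dendropy.Node()
    for node, length in (
        (nodes[x], 0.5 * (dxy + dxz - dyz)),
        (nodes[y], 0.5 * (dxy + dyz - dxz)),
        (nodes[z], 0.5 * (dxz + dyz - dxy)),
    ):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap and majority-rule consensus


def _bipartitions(tree: dendropy.Tree, ref_taxon: str) -> dict[frozenset, None]:
    """Non-trivial bipartitions as leaf-label sets on the side away from a
    fixed reference taxon (canonical form for an unrooted tree)."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_taxa - below if ref_taxon in below else below
        if 1 < len(side) < len(all_taxa) - 1:
            splits[side] = None
    return splits


def majority_rule_consensus(trees: Sequence[dendropy.Tree],
                            taxa: Sequence[str]) -> dendropy.Tree:
    """Strict-majority (>50%) consensus; internal node labels carry support %.

    Bipartitions occurring in more than half the input trees are mutually
    compatible, so the consensus is built by greedy insertion in order of
    decreasing frequency.
    """
    taxa = [str(t) for t in taxa]
    ref = taxa[0]
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in _bipartitions(t, ref):
            counts[split] = counts.get(split, 0) + 1
    n_reps = len(trees)
    kept = sorted(
        ((s, c) for s, c in counts.items() if c * 2 > n_reps),
        key=lambda sc: (-sc[1], len(sc[0]), sorted(sc[0])),
    )

    tns = dendropy.TaxonNamespace(taxa)
    root = dendropy.Node()
    leaf_nodes = {}
    for t in taxa:
        lf = dendropy.Node(taxon=tns.get_taxon(t))
        root.add_child(lf)
        leaf_nodes[t] = lf

    def leafset(node: dendropy.Node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    for split, count in kept:
        # deepest node whose leaf set contains the split
        host = root
        descended = True
        while descended:
            descended = False
            for ch in host.child_nodes():
                ls = leafset(ch)
                if split <= ls and len(ls) > len(split):
                    host = ch
                    descended = True
                    break
        movers = [ch for ch in host.child_nodes() if leafset(ch) <= split]
        if frozenset().union(*(leafset(ch) for ch in movers)) != split:
            continue  # incompatible with tree built so far (<=50% ties)
        new = dendropy.Node()
        new.label = f"{100.0 * count / n_reps:g}"
        for ch in movers:
            host.remove_child(ch)
            new.add_child(ch)
        host.add_child(new)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def bootstrap_consensus(rows: Sequence[tuple[str, str]], n_reps: int = 500,
                        seed: int = 0) -> dendropy.Tree:
    """Column-bootstrap NJ trees and their strict-majority consensus.

    Columns are resampled with replacement ``n_reps`` times; an NJ tree is
    built from p-distances per pseudoreplicate; bipartitions with frequency
    strictly above 50% are retained, labelled with their percentage support.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = [t for t, _ in rows]
    seqs = [s for _, s in rows]
    L = len(seqs[0])
    X = np.array([list(s) for s in seqs])
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        Xi = X[:, cols]
        rep_rows = [(t, "".join(Xi[i])) for i, t in enumerate(taxa)]
        D, _ = p_distance_matrix(rep_rows)
        trees.append(nj_tree(D, taxa))
    return majority_rule_consensus(trees, taxa)


# ---------------------------------------------------------------------------
# Bacterioferritin exclusion


def bfr_clade_members(tree: dendropy.Tree, bfr_reference_ids: Sequence[str]) -> set[str]:
    """Leaves of the smallest clade containing all bacterioferritin references,
    after midpoint rooting a clone of the tree."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [b for b in bfr_reference_ids if b not in labels]
    if missing:
        raise ValueError(f"bacterioferritin reference(s) absent from tree: {missing}")
    rooted = tree.clone(depth=1)
    rooted.is_rooted = True
    for edge in rooted.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0  # consensus trees carry supports, not lengths
    rooted.reroot_at_midpoint(update_bipartitions=True)
    node = rooted.mrca(taxon_labels=list(bfr_reference_ids))
    refs = set(bfr_reference_ids)
    # "grouped together with" the references means the smallest clade joining
    # them with at least one other taxon (the MRCA of a single reference is
    # its own leaf, which groups nothing)
    while node.parent_node is not None and \
            {lf.taxon.label for lf in node.leaf_iter()} <= refs:
        node = node.parent_node
    return {lf.taxon.label for lf in node.leaf_iter()}


def exclude_bacterioferritins(records: Sequence[ProteinRecord],
                              tree: dendropy.Tree,
                              bfr_reference_ids: Sequence[str],
                              bc_max_len: int = BC_MAX_LEN,
                              min_helix_len: int = MIN_HELIX_LEN,
                              ) -> list[ProteinRecord]:
    """Drop records that group with the bacterioferritin references AND lack
    the Dps BC-helix signature; both conditions are required."""
    clade = bfr_clade_members(tree, bfr_reference_ids)
    retained = []
    for r in records:
        if r.id in clade and r.ss is not None:
            segs = helix_segments(r.ss, min_helix_len)
            ok, _ = is_dps_signature(segs, bc_max_len)
            if not ok:
                continue
        retained.append(r)
    return retained
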