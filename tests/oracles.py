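"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most transparent method available
(quadratic dynamic programming, exhaustive enumeration) and never shares code
with the implementation it checks.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Local alignment: plain Gotoh DP, gap of length k costs open + k * extend


def sw_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Optimal Smith-Waterman score under BLOSUM62 with affine gaps."""
    n, m = len(a), len(b)
    NEG = -1e18
    first = gap_open + gap_extend
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def ka_evalue(score: float, m: int, n: int,
              lam: float = 0.267, K: float = 0.041) -> float:
    return K * m * n * math.exp(-lam * score)


def exhaustive_best_hits(queries, subjects, evalue_max: float):
    """All-vs-all best-hit map computed from the DP oracle.

    Mirrors the documented selection rule: max bit score, ties to lower
    E-value then lexicographically smaller subject id.
    """
    out = {}
    for q in queries:
        candidates = []
        for s in subjects:
            sc = sw_score(q.sequence, s.sequence)
            ev = ka_evalue(sc, len(q.sequence), len(s.sequence))
            if ev <= evalue_max:
                bit = (0.267 * sc - math.log(0.041)) / math.log(2.0)
                candidates.append((-bit, ev, s.id))
        if candidates:
            candidates.sort()
            out[q.id] = candidates[0][2]
    return out


def exhaustive_rbh(proteome_a, proteome_b, evalue_max: float):
    fwd = exhaustive_best_hits(proteome_a, proteome_b, evalue_max)
    rev = exhaustive_best_hits(proteome_b, proteome_a, evalue_max)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


# ---------------------------------------------------------------------------
# Motif scanning: try every start x every spacer length, character by character


def exhaustive_scan(seq: str, left: str, spacer_min: int, spacer_max: int,
                    right: str, strand_mode: str = "both"):
    """Every (start, end, strand, spacer) motif match, forward coordinates."""
    hits = set()

    def match_at(s: str, pos: int, block: str) -> bool:
        for off, sym in enumerate(block):
            if s[pos + off] not in IUPAC_SETS[sym]:
                return False
        return True

    def scan_one(s: str):
        found = []
        L = len(s)
        for k in range(spacer_min, spacer_max + 1):
            total = len(left) + k + len(right)
            for start in range(0, L - total + 1):
                if not match_at(s, start, left):
                    continue
                spacer_ok = all(s[start + len(left) + i] in "ACGT" for i in range(k))
                if spacer_ok and match_at(s, start + len(left) + k, right):
                    found.append((start, start + total, k))
        return found

    L = len(seq)
    if strand_mode in ("+", "both"):
        for s0, e0, k in scan_one(seq):
            hits.add((s0, e0, "+", k))
    if strand_mode in ("-", "both"):
        for s0, e0, k in scan_one(revcomp(seq)):
            hits.add((L - e0, L - s0, "-", k))
    return hits


# ---------------------------------------------------------------------------
# Quartet topology by least squares over the three resolutions


def best_quartet_topology(d, taxa):
    """Least-squares best of the 3 unrooted quartet topologies.

    ``d`` is a dict keyed by frozenset pairs of taxon labels. Returns the
    pair grouping, e.g. (("A","B"),("C","D")), with minimal residual
    sum-of-squares under non-negative least squares on the 5 branch lengths.
    """
    import itertools

    import numpy as np
    from scipy.optimize import nnls

    a, b, c, e = taxa
    topologies = [((a, b), (c, e)), ((a, c), (b, e)), ((a, e), (b, c))]
    pairs = list(itertools.combinations(taxa, 2))
    best = None
    for topo in topologies:
        (p, q), (r, s) = topo
        # branches: p, q, r, s, internal
        rows = []
        y = []
        for (u, v) in pairs:
            row = [0.0] * 5
            for idx, t in enumerate((p, q, r, s)):
                if t in (u, v):
                    row[idx] = 1.0
            # internal branch used iff u, v on opposite sides
            same_side = ({u, v} <= {p, q}) or ({u, v} <= {r, s})
            row[4] = 0.0 if same_side else 1.0
            rows.append(row)
            y.append(d[frozenset((u, v))])
        sol, rnorm = nnls(np.array(rows), np.array(y))
        if best is None or rnorm < best[0]:
            best = (rnorm, topo)
    return best[1]
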