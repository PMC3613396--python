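"""Reciprocal-best-hit orthology against reference Dps families.

Pairwise protein comparison uses optimal local (Smith-Waterman) alignment
under BLOSUM62 with BLAST-style affine gaps (a gap of length k costs
open + k * extend). Expectation values come from the Karlin-Altschul formula
E = K * m * n * exp(-lambda * S) with fixed gapped constants; they are an
approximation used only to reproduce the thresholding behaviour of a BLASTP
search at a relaxed cutoff (1e-3), not calibrated statistics.

Cluster building follows the back-best-hit logic of the original search
strategy: homologs retrieved below the E-value cutoff are kept in the cluster
of reference family R when their best hit among the references is R. This
admits both members of a recent within-genome duplication (in-paralogs),
whereas the strict one-to-one ``reciprocal_best_hits`` necessarily picks a
single partner per query; both views are exposed.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord

# Karlin-Altschul gapped constants (approximate, BLOSUM62 / gap 10+k)
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_EVALUE_MAX = 1e-3
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment hit."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    identity: float  # percent over aligned columns (gaps included)
    evalue: float


@dataclass
class OrthologCluster:
    """Members assigned to one reference Dps family, with in-paralog pairs."""

    reference_id: str
    members: list[str] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def _make_aligner(matrix: str = "BLOSUM62",
                  gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_alphabet(seq: str, label: str, aligner: Align.PairwiseAligner) -> None:
    allowed = set(aligner.substitution_matrix.alphabet)
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"{label}: residue {c!r} at position {i} not in matrix alphabet")


def karlin_altschul(raw_score: float, m: int, n: int,
                    lam: float = KA_LAMBDA, K: float = KA_K) -> tuple[float, float]:
    """Return (bit score, E-value) for a raw score over an m x n search space."""
    bit = (lam * raw_score - math.log(K)) / math.log(2.0)
    evalue = K * m * n * math.exp(-lam * raw_score)
    return bit, evalue


def align_pair(a, b, matrix: str = "BLOSUM62",
               gap_open: float = DEFAULT_GAP_OPEN,
               gap_extend: float = DEFAULT_GAP_EXTEND,
               _aligner: Optional[Align.PairwiseAligner] = None) -> AlignmentHit:
    """Optimal local alignment of two protein sequences.

    ``a`` and ``b`` may be ProteinRecord objects or raw strings. Identity is
    the percentage of identical columns over the full local alignment length
    (gap columns included in the denominator).
    """
    qa = a if isinstance(a, ProteinRecord) else ProteinRecord("query", a)
    sb = b if isinstance(b, ProteinRecord) else ProteinRecord("subject", b)
    aligner = _aligner if _aligner is not None else _make_aligner(matrix, gap_open, gap_extend)
    _check_alphabet(qa.sequence, qa.id, aligner)
    _check_alphabet(sb.sequence, sb.id, aligner)
    aln = aligner.align(qa.sequence, sb.sequence)
    score = aln.score
    best = aln[0]
    counts = best.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / ncols if ncols else 0.0
    bit, evalue = karlin_altschul(score, len(qa.sequence), len(sb.sequence))
    return AlignmentHit(qa.id, sb.id, score, bit, identity, evalue)


def best_hits(queries: Sequence[ProteinRecord], subjects: Sequence[ProteinRecord],
              evalue_max: float = DEFAULT_EVALUE_MAX,
              **aln_kwargs) -> dict[str, AlignmentHit]:
    """Best qualifying subject per query (max bit score, E <= evalue_max).

    Ties on bit score break to the lower E-value, then the lexicographically
    smaller subject id, so results are deterministic. Queries with no
    qualifying hit are absent from the map.
    """
    if not queries or not subjects:
        raise ValueError("best_hits requires non-empty proteomes")
    aligner = _make_aligner(
        aln_kwargs.get("matrix", "BLOSUM62"),
        aln_kwargs.get("gap_open", DEFAULT_GAP_OPEN),
        aln_kwargs.get("gap_extend", DEFAULT_GAP_EXTEND),
    )
    out: dict[str, AlignmentHit] = {}
    for q in queries:
        best: Optional[AlignmentHit] = None
        for s in subjects:
            hit = align_pair(q, s, _aligner=aligner)
            if hit.evalue > evalue_max:
                continue
            if best is None or _hit_key(hit) > _hit_key(best):
                best = hit
        if best is not None:
            out[q.id] = best
    return out


def _hit_key(hit: AlignmentHit) -> tuple:
    # higher bit, then lower evalue, then smaller subject id
    return (hit.bit_score, -hit.evalue, _NegStr(hit.subject_id))


class _NegStr(str):
    """str whose ordering is reversed, so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def reciprocal_best_hits(proteome_a: Sequence[ProteinRecord],
                         proteome_b: Sequence[ProteinRecord],
                         evalue_max: float = DEFAULT_EVALUE_MAX,
                         **aln_kwargs) -> list[tuple[str, str]]:
    """Mutual-best-hit pairs between two proteomes.

    (a, b) is retained iff b is a's best hit in B and a is b's best hit in A.
    """
    fwd = best_hits(proteome_a, proteome_b, evalue_max, **aln_kwargs)
    rev = best_hits(proteome_b, proteome_a, evalue_max, **aln_kwargs)
    pairs = []
    for a_id, hit in sorted(fwd.items()):
        back = rev.get(hit.subject_id)
        if back is not None and back.subject_id == a_id:
            pairs.append((a_id, hit.subject_id))
    return pairs


def assign_families(proteome: Sequence[ProteinRecord],
                    references: Sequence[ProteinRecord],
                    evalue_max: float = DEFAULT_EVALUE_MAX,
                    **aln_kwargs) -> dict[str, str]:
    """Map each protein to its best reference family, back-blast style.

    A protein is assigned to reference R iff R is its best hit among the
    references with E <= evalue_max; proteins with no qualifying hit are
    unassigned (absent).
    """
    hits = best_hits(proteome, references, evalue_max, **aln_kwargs)
    return {pid: h.subject_id for pid, h in hits.items()}


def build_clusters(proteomes: Mapping[str, Sequence[ProteinRecord]],
                   references: Sequence[ProteinRecord],
                   evalue_max: float = DEFAULT_EVALUE_MAX,
                   paralog_identity_min: float = 80.0,
                   **aln_kwargs) -> dict[str, OrthologCluster]:
    """RBH-anchored ortholog clusters for every reference family.

    ``proteomes`` maps genome id -> protein records. Within each genome,
    cluster members are screened for in-paralog pairs (pairwise identity >=
    ``paralog_identity_min``).
    """
    clusters = {r.id: OrthologCluster(reference_id=r.id) for r in references}
    per_genome_members: dict[str, dict[str, list[ProteinRecord]]] = defaultdict(
        lambda: defaultdict(list))
    for genome_id in sorted(proteomes):
        fams = assign_families(proteomes[genome_id], references, evalue_max, **aln_kwargs)
        by_id = {p.id: p for p in proteomes[genome_id]}
        for pid in sorted(fams):
            ref = fams[pid]
            clusters[ref].members.append(pid)
            per_genome_members[ref][genome_id].append(by_id[pid])
    for ref, by_genome in per_genome_members.items():
        for genome_id in sorted(by_genome):
            members = by_genome[genome_id]
            clusters[ref].paralog_pairs.extend(
                detect_paralog_pairs(members, identity_min=paralog_identity_min,
                                     **aln_kwargs))
    return clusters


def detect_paralog_pairs(members: Sequence[ProteinRecord],
                         identity_min: float = 80.0,
                         **aln_kwargs) -> list[tuple[str, str, float]]:
    """All unordered member pairs with pairwise identity >= identity_min."""
    out = []
    ordered = sorted(members, key=lambda p: p.id)
    for i, x in enumerate(ordered):
        for y in ordered[i + 1:]:
            hit = align_pair(x, y, **aln_kwargs)
            if hit.identity >= identity_min:
                out.append((x.id, y.id, hit.identity))
    return out
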