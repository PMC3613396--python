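"""Degenerate promoter-motif scanning with a bounded variable spacer.

The motif of interest is the SigB-dependent promoter consensus
``GNNTN(N)14-16GGGYAY`` — a -35 block and a -10 block separated by a spacer of
14 to 16 unconstrained nucleotides. Patterns are written in IUPAC nucleotide
code with the spacer as ``(N)min-max`` between the two blocks.

Scanning reports every admissible (start, spacer length) combination, so one
genomic position can yield up to three overlapping hits. An ``N`` in the
*subject* sequence matches nothing (conservative: masked regions cannot
produce hits). Reverse-strand hits are found on the reverse complement and
reported in forward-strand coordinates as the matched span [start, end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import GeneLocus, Replicon

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SIGB_PATTERN_SPEC = "GNNTN(N)14-16GGGYAY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """Two IUPAC blocks separated by a bounded unconstrained spacer."""

    left_block: str
    spacer_min: int
    spacer_max: int
    right_block: str

    @property
    def min_length(self) -> int:
        return len(self.left_block) + self.spacer_min + len(self.right_block)

    @property
    def max_length(self) -> int:
        return len(self.left_block) + self.spacer_max + len(self.right_block)


@dataclass(frozen=True)
class MotifHit:
    """A motif match, always in forward-strand coordinates of its sequence.

    ``start``/``end`` delimit the matched span; ``matched`` is the matched
    sequence read in pattern orientation (reverse-complemented for - hits).
    """

    start: int
    end: int
    strand: str
    spacer_len: int
    matched: str
    replicon_id: str = ""


@dataclass
class SigBCall:
    """Per-gene promoter verdict: the closest qualifying hit, if any."""

    gene_id: str
    positive: bool
    distance_to_orf: Optional[int] = None
    hit: Optional[MotifHit] = None


_SPEC_RE = re.compile(
    r"^(?P<left>[ACGTRYSWKMBDHVN]+)\(N\)(?P<min>\d+)-(?P<max>\d+)"
    r"(?P<right>[ACGTRYSWKMBDHVN]+)$"
)


def compile_pattern(spec: str) -> MotifPattern:
    """Parse a pattern spec like ``"GNNTN(N)14-16GGGYAY"``."""
    s = spec.strip().upper().replace(" ", "")
    for i, c in enumerate(s):
        if c not in "()0123456789-" and c not in IUPAC:
            raise ValueError(f"pattern {spec!r}: illegal IUPAC symbol {c!r} at position {i}")
    m = _SPEC_RE.match(s)
    if not m:
        raise ValueError(f"malformed pattern spec {spec!r} "
                         "(expected LEFT(N)min-maxRIGHT in IUPAC code)")
    lo, hi = int(m.group("min")), int(m.group("max"))
    if lo > hi:
        raise ValueError(f"pattern {spec!r}: spacer min {lo} > max {hi}")
    return MotifPattern(m.group("left"), lo, hi, m.group("right"))


def _block_regex(block: str) -> str:
    # subject N matches nothing: classes never include N
    return "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in block
    )


def _compiled(pattern: MotifPattern) -> list[tuple[int, re.Pattern]]:
    """One fixed-length lookahead regex per spacer length (overlap-safe)."""
    left = _block_regex(pattern.left_block)
    right = _block_regex(pattern.right_block)
    out = []
    for k in range(pattern.spacer_min, pattern.spacer_max + 1):
        out.append((k, re.compile(f"(?=({left}[ACGT]{{{k}}}{right}))")))
    return out


def scan(seq: str, pattern: MotifPattern, strand_mode: str = "both",
         replicon_id: str = "") -> list[MotifHit]:
    """All motif hits in ``seq``; ``strand_mode`` in {"+", "-", "both"}."""
    if strand_mode not in ("+", "-", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = seq.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    compiled = _compiled(pattern)
    if strand_mode in ("+", "both"):
        for k, rx in compiled:
            m_len = pattern.min_length - pattern.spacer_min + k
            for m in rx.finditer(seq):
                s = m.start()
                hits.append(MotifHit(s, s + m_len, "+", k, m.group(1), replicon_id))
    if strand_mode in ("-", "both"):
        rc = revcomp(seq)
        for k, rx in compiled:
            m_len = pattern.min_length - pattern.spacer_min + k
            for m in rx.finditer(rc):
                s = m.start()
                # span on forward strand
                hits.append(MotifHit(L - s - m_len, L - s, "-", k, m.group(1), replicon_id))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def upstream_window(gene: GeneLocus, replicon: Replicon, max_dist: int = 200,
                    intergenic_truncate: bool = True) -> tuple[str, int, int]:
    """The up-to-``max_dist`` bases immediately 5' of a gene's start codon.

    Returns ``(subsequence on the coding strand, fwd_start, fwd_end)`` where
    [fwd_start, fwd_end) is the window's forward-strand interval. With
    ``intergenic_truncate`` the window stops at the nearest neighbouring gene
    boundary; it is also truncated at the replicon edge. A zero-length window
    yields an empty sequence.
    """
    if gene.strand == "+":
        lo, hi = max(0, gene.start - max_dist), gene.start
        if intergenic_truncate:
            for g in replicon.genes:
                if g.id != gene.id and g.end <= gene.start:
                    lo = max(lo, g.end)
    else:
        lo, hi = gene.end, min(replicon.length, gene.end + max_dist)
        if intergenic_truncate:
            for g in replicon.genes:
                if g.id != gene.id and g.start >= gene.end:
                    hi = min(hi, g.start)
    if lo >= hi:
        return "", lo, lo
    sub = replicon.sequence[lo:hi]
    if gene.strand == "-":
        sub = revcomp(sub)
    return sub, lo, hi


def _is_intergenic(replicon: Replicon, start: int, end: int) -> bool:
    """True iff [start, end) overlaps no annotated gene span on either strand."""
    return all(g.end <= start or g.start >= end for g in replicon.genes)


def sigb_call(gene: GeneLocus, replicon: Replicon, pattern: MotifPattern,
              max_dist: int = 200, intergenic_only: bool = True,
              scan_window: Optional[int] = None) -> SigBCall:
    """Per-gene SigB promoter verdict.

    Positive iff at least one motif hit lies on the gene's coding strand with
    every base intergenic (when ``intergenic_only``) and with its 3' end
    within ``max_dist`` nt of the ORF start. The closest qualifying hit is
    reported. The scanned window extends ``scan_window`` nt upstream (default
    2 x max_dist) so that too-distant motifs are seen and rejected by the
    distance filter rather than silently missed.
    """
    window = scan_window if scan_window is not None else 2 * max_dist
    sub, lo, hi = upstream_window(gene, replicon, window, intergenic_truncate=False)
    best: Optional[tuple[int, MotifHit]] = None
    # scan the coding strand only: a promoter must be co-oriented with its ORF
    for h in scan(sub, pattern, strand_mode="+", replicon_id=replicon.id):
        # distance from motif 3' end to ORF start, along the coding strand
        dist = len(sub) - h.end
        if dist > max_dist:
            continue
        if gene.strand == "+":
            f_start, f_end = lo + h.start, lo + h.end
        else:
            f_start, f_end = hi - h.end, hi - h.start
        if intergenic_only and not _is_intergenic(replicon, f_start, f_end):
            continue
        fwd_hit = MotifHit(f_start, f_end, gene.strand, h.spacer_len, h.matched,
                           replicon.id)
        if best is None or dist < best[0]:
            best = (dist, fwd_hit)
    if best is None:
        return SigBCall(gene.id, False)
    return SigBCall(gene.id, True, best[0], best[1])


def scan_genome(replicon: Replicon, pattern: MotifPattern, max_dist: int = 200,
                intergenic_only: bool = True,
                families: Optional[Sequence[str]] = None) -> list[SigBCall]:
    """SigB calls for every gene (or for the given families) on a replicon."""
    calls = []
    for g in replicon.genes_sorted():
        if families is not None and g.family not in families:
            continue
        calls.append(sigb_call(g, replicon, pattern, max_dist, intergenic_only))
    return calls
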