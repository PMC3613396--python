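"""Chromosome orientation, core/arm compartments, synteny and GC checks.

Linear *Streptomyces* chromosomes are oriented by the strand of the
replication initiator gene *dnaA*: if it lies on the minus strand the whole
replicon is mirrored (sequence reverse-complemented, coordinates reflected,
strands flipped) so that all genomes are comparable. Genes are then placed in
a core/arm compartment by the distance of their midpoint to the nearest
chromosome end (arm when strictly inside the terminal regions, default 2 Mb),
and local gene-neighbourhood conservation is summarised as a per-offset
consensus across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .promoters import revcomp
from .records import GeneLocus, Replicon

ARM_THRESHOLD_BP = 2_000_000
ABSENT = "absent"


@dataclass(frozen=True)
class ChromLocation:
    gene_id: str
    position_mb: float
    compartment: str  # "core" | "arm"
    distance_to_nearest_end: float


@dataclass
class SyntenyProfile:
    """Per-offset modal family and its frequency (%) around a focal family."""

    focal_family: str
    offsets: dict[int, tuple[str, float]] = field(default_factory=dict)
    n_genomes: int = 0


def orient_replicon(replicon: Replicon) -> Replicon:
    """Return the replicon oriented so dnaA is on the plus strand.

    Mirroring maps a gene [s, e) to [L-e, L-s) with its strand flipped and
    reverse-complements the sequence; a plus-strand dnaA returns the input
    unchanged (so the operation is idempotent after one application).
    """
    dnaa = replicon.dnaa  # raises if absent/ambiguous via Replicon invariant
    if dnaa.strand == "+":
        return replicon
    L = replicon.length
    flipped = [
        GeneLocus(
            id=g.id,
            start=L - g.end,
            end=L - g.start,
            strand="+" if g.strand == "-" else "-",
            family=g.family,
            replicon_id=g.replicon_id,
        )
        for g in replicon.genes
    ]
    return Replicon(id=replicon.id, sequence=revcomp(replicon.sequence), genes=flipped)


def core_arm(gene: GeneLocus, replicon: Replicon,
             arm_threshold_bp: int = ARM_THRESHOLD_BP) -> ChromLocation:
    """Compartment call from the gene midpoint's distance to the nearest end.

    Arm iff distance < threshold (strict: a midpoint exactly at the threshold
    is core). Position is reported in Mb of the oriented chromosome.
    """
    mid = gene.midpoint
    dist = min(mid, replicon.length - mid)
    compartment = "arm" if dist < arm_threshold_bp else "core"
    return ChromLocation(gene.id, mid / 1e6, compartment, dist)


def neighbourhood(gene: GeneLocus, replicon: Replicon, k: int = 3) -> dict[int, str]:
    """Family labels of the k genes on each side, in gene-rank order.

    Offsets run -k..+k (0 excluded) in the focal gene's reading direction:
    for a minus-strand focal gene the rank order is reversed so that -1 is
    always the upstream neighbour. Positions past the chromosome edge are
    labelled ``"absent"``.
    """
    ranked = replicon.genes_sorted()
    pos = next(i for i, g in enumerate(ranked) if g.id == gene.id)
    out: dict[int, str] = {}
    sign = 1 if gene.strand == "+" else -1
    for off in range(-k, k + 1):
        if off == 0:
            continue
        idx = pos + sign * off
        out[off] = ranked[idx].family if 0 <= idx < len(ranked) else ABSENT
    return out


def synteny_consensus(neighbourhoods: Sequence[Mapping[int, str]],
                      focal_family: str = "",
                      min_freq: float = 0.0) -> SyntenyProfile:
    """Modal family and frequency per offset across genomes.

    Frequencies are percentages among genomes with a defined (non-absent)
    entry at that offset; offsets whose modal frequency falls below
    ``min_freq`` are omitted from the profile (display cutoff). Requires
    neighbourhoods from at least two genomes.
    """
    if len(neighbourhoods) < 2:
        raise ValueError("synteny consensus requires >= 2 genomes")
    profile = SyntenyProfile(focal_family=focal_family, n_genomes=len(neighbourhoods))
    offsets = sorted({o for nb in neighbourhoods for o in nb})
    for off in offsets:
        labels = [nb[off] for nb in neighbourhoods if nb.get(off, ABSENT) != ABSENT]
        if not labels:
            continue
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        modal = min(counts, key=lambda f: (-counts[f], f))
        freq = 100.0 * counts[modal] / len(labels)
        if freq >= min_freq:
            profile.offsets[off] = (modal, freq)
    return profile


def mean_consensus_frequency(profile: SyntenyProfile) -> float:
    """Mean modal frequency over the profile's reported offsets (0 if none)."""
    if not profile.offsets:
        return 0.0
    return sum(f for _, f in profile.offsets.values()) / len(profile.offsets)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    return gc / len(seq)


def gc_consistency(gene: GeneLocus, replicon: Replicon,
                   flank_n_genes: int = 3) -> tuple[float, float, float, float]:
    """(gene GC %, neighbourhood GC %, genome GC %, |gene - neighbourhood| pp).

    Neighbourhood GC pools the spans of up to ``flank_n_genes`` annotated
    genes on each side of the focal gene in rank order.
    """
    ranked = replicon.genes_sorted()
    pos = next(i for i, g in enumerate(ranked) if g.id == gene.id)
    gene_gc = 100.0 * gc_fraction(replicon.sequence[gene.start:gene.end])
    flank = []
    for idx in range(max(0, pos - flank_n_genes), min(len(ranked), pos + flank_n_genes + 1)):
        if idx != pos:
            g = ranked[idx]
            flank.append(replicon.sequence[g.start:g.end])
    nb_gc = 100.0 * gc_fraction("".join(flank)) if flank else float("nan")
    genome_gc = 100.0 * gc_fraction(replicon.sequence)
    return gene_gc, nb_gc, genome_gc, abs(gene_gc - nb_gc)
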