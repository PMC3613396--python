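"""Core domain types shared across the pipeline.

Coordinate convention: all in-memory gene coordinates are 0-based half-open
intervals on the forward strand of their replicon. GFF3 files on disk use the
standard 1-based inclusive convention; :mod:`dpsevolve.io` converts at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
SS_STATES = set("HEC")


@dataclass
class ProteinRecord:
    """An amino-acid sequence with organism tag and optional secondary structure.

    ``ss`` is a per-residue state string over {H, E, C} (helix, strand, coil)
    of the same length as ``sequence``; ``ss_confidence`` is the overall
    prediction confidence in percent (0-100), used to drop poorly predicted
    structures before tail counting.
    """

    id: str
    sequence: str
    organism: str = ""
    ss: Optional[str] = None
    ss_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in PROTEIN_ALPHABET]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"protein {self.id!r}: illegal residue {c!r} at position {i}"
            )
        if self.ss is not None:
            if len(self.ss) != len(self.sequence):
                raise ValueError(
                    f"protein {self.id!r}: ss length {len(self.ss)} != "
                    f"sequence length {len(self.sequence)}"
                )
            bad_ss = [(i, c) for i, c in enumerate(self.ss) if c not in SS_STATES]
            if bad_ss:
                i, c = bad_ss[0]
                raise ValueError(
                    f"protein {self.id!r}: illegal SS state {c!r} at position {i}"
                )
        if self.ss_confidence is not None and not 0 <= self.ss_confidence <= 100:
            raise ValueError(
                f"protein {self.id!r}: ss_confidence {self.ss_confidence} outside [0,100]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneLocus:
    """An annotated gene on a linear replicon (0-based half-open)."""

    id: str
    start: int
    end: int
    strand: str
    family: str = "other"
    replicon_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: unknown strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Replicon:
    """A linear chromosome: nucleotide sequence plus gene annotations.

    Exactly one gene must carry family ``dnaA``; it calibrates chromosome
    orientation downstream.
    """

    id: str
    sequence: str
    genes: list[GeneLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        dnaa = [g for g in self.genes if g.family == "dnaA"]
        if len(dnaa) != 1:
            raise ValueError(
                f"replicon {self.id!r}: expected exactly one dnaA gene, found {len(dnaa)}"
            )
        for g in self.genes:
            if g.end > L:
                raise ValueError(
                    f"gene {g.id!r} extends past replicon end ({g.end} > {L})"
                )
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"replicon {self.id!r}: duplicate gene id {dup!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def dnaa(self) -> GeneLocus:
        return next(g for g in self.genes if g.family == "dnaA")

    @property
    def dnaa_id(self) -> str:
        return self.dnaa.id

    def genes_sorted(self) -> list[GeneLocus]:
        return sorted(self.genes, key=lambda g: (g.start, g.end, g.id))

    def gene(self, gene_id: str) -> GeneLocus:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"no gene {gene_id!r} on replicon {self.id!r}")


@dataclass
class QpcrRecord:
    """One qPCR well: gene, condition, biological replicate, Ct, efficiency.

    ``reference_flag`` marks rows of the endogenous reference gene (hrdB);
    ``efficiency`` is the amplification efficiency E in [1, 2] (2 = perfect
    doubling per cycle).
    """

    gene: str
    condition: str
    replicate: int
    ct: float
    efficiency: float
    reference_flag: bool = False

    CONDITIONS = ("control", "stress")

    def __post_init__(self) -> None:
        if self.condition not in self.CONDITIONS:
            raise ValueError(
                f"{self.gene!r} rep {self.replicate}: condition {self.condition!r} "
                f"not in {self.CONDITIONS}"
            )
        if self.replicate < 1:
            raise ValueError(f"{self.gene!r}: replicate must be >= 1")
        if not self.ct > 0:
            raise ValueError(f"{self.gene!r} rep {self.replicate}: ct must be > 0")
        if not 1.0 <= self.efficiency <= 2.0:
            raise ValueError(
                f"{self.gene!r} rep {self.replicate}: efficiency "
                f"{self.efficiency} outside [1, 2]"
            )
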