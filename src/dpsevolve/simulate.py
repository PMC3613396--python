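"""Synthetic *Streptomyces*-like cohorts with planted ground truth.

The generator emulates the world the downstream analysis assumes:

* linear ~8 Mb replicons at 70% GC with a centrally located *dnaA*;
* a multi-family *dps* complement per genome (orthologs of dpsA/dpsB/dpsC,
  plus a dpsB2 in-paralog in some genomes at ~97% +/- 1.5 pairwise identity);
* SigB-like promoter motifs planted on the coding strand, fully intergenic,
  with the motif 3' end within 200 nt of designated ORF starts, the spacer
  drawn uniformly from {14,15,16} and each degenerate position sampled
  uniformly from its IUPAC set;
* motif-bearing *dps* copies placed in the chromosome arms (terminal 2 Mb)
  with per-genome shuffled gene neighbourhoods, the motif-free core dpsB
  placed centrally with a conserved neighbourhood;
* secondary-structure strings encoding the five-helix Dps signature (short
  central BC helix) and family-specific N-/C-terminal tails;
* an ungapped protein "alignment" (all sequences evolve by substitutions
  only from a common root, so the stacked sequences are the alignment) that
  also contains the reference Dps proteins and a bacterioferritin outgroup;
* qPCR Ct tables in which induction (true ratio 8) is planted exactly for
  the motif-bearing genes, with Gaussian Ct noise.

Scanned upstream windows are kept free of chance motif hits by rejection
sampling, so within-window sensitivity/false-positive statements are exact
by construction. Everything is a pure function of (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import io as dio
from . import orthology
from .promoters import (IUPAC, SIGB_PATTERN_SPEC, MotifPattern, compile_pattern,
                        revcomp, scan, upstream_window)
from .records import GeneLocus, ProteinRecord, QpcrRecord, Replicon

AA = "ACDEFGHIKLMNPQRSTVWY"

DPS_FAMILIES = ("dpsA", "dpsB", "dpsB2", "dpsC")
CLUSTER_OF = {"dpsA": "dpsA_Sc", "dpsB": "dpsB_Sc", "dpsB2": "dpsB_Sc",
              "dpsC": "dpsC_Sc"}
REFERENCE_IDS = ("dpsA_Sc", "dpsB_Sc", "dpsC_Sc")
BFR_ID = "bfr_Sc"

PROTEIN_LEN = 170          # all aligned proteins share this length (no indels)
DPS_HELICES = (18, 16, 6, 17, 15)   # third = short BC helix
BFR_HELICES = (18, 16, 17, 15)      # no BC helix, ferritin-like
# family base tails (n, c): dpsA long-C, dpsB short/short, dpsC long-N
FAMILY_TAILS = {"dpsA": (4, 20), "dpsB": (3, 2), "dpsB2": (3, 2),
                "dpsC": (22, 3), "bfr": (3, 3)}

GC_CONTENT = 0.70
REPLICON_LENGTH = 8_000_000
N_GENES = 50
ARM_THRESHOLD = 2_000_000
MAX_DIST = 200
TRUE_INDUCED_RATIO = 8.0

PARALOG_IDENTITY_MEAN = 97.0
PARALOG_IDENTITY_SD = 1.5
PARALOG_IDENTITY_BOUNDS = (85.0, 100.0)

FAMILY_DIVERGENCE = 30.0   # ancestor vs root, % substituted
MEMBER_DIVERGENCE = 10.0   # member vs family ancestor, % substituted
BFR_DIVERGENCE = 40.0

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_NT_P = (0.15, 0.35, 0.35, 0.15)  # 70% GC


@dataclass
class TruthSet:
    """Everything the generator planted, keyed so downstream recovery is exact.

    ``planted_motifs`` maps gene id -> dict with keys ``distance`` (motif 3'
    end to ORF start, nt), ``spacer_len``, ``start``/``end`` (forward-strand
    span in the oriented frame) and ``decoy`` (True for negative controls that
    must NOT be called). ``planted_families`` maps dps gene id -> reference
    cluster id. Fold changes are true control->stress expression ratios.
    """

    planted_motifs: dict = field(default_factory=dict)
    planted_tails: dict = field(default_factory=dict)
    planted_families: dict = field(default_factory=dict)
    planted_paralog_pairs: list = field(default_factory=list)
    planted_fold_changes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def merge(self, other: "TruthSet") -> None:
        self.planted_motifs.update(other.planted_motifs)
        self.planted_tails.update(other.planted_tails)
        self.planted_families.update(other.planted_families)
        self.planted_paralog_pairs.extend(other.planted_paralog_pairs)
        self.planted_fold_changes.update(other.planted_fold_changes)
        self.seeds.update(other.seeds)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Protein-level generators


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate_to_identity(seq: str, target_identity: float, seed=None,
                       rng: Optional[np.random.Generator] = None) -> str:
    """Substitution-only mutant at the requested ungapped pairwise identity.

    The number of substituted positions is round(L * (1 - target/100)); if
    the achievable identity differs from the target by more than one
    percentage point (short sequences), a granularity error is raised.
    """
    if not 0 < target_identity <= 100:
        raise ValueError(f"target identity {target_identity} outside (0, 100]")
    L = len(seq)
    n_sub = round(L * (1.0 - target_identity / 100.0))
    achieved = 100.0 * (1.0 - n_sub / L)
    if abs(achieved - target_identity) > 1.0:
        raise ValueError(
            f"target identity {target_identity}% unreachable for length {L} "
            f"(closest achievable {achieved:.1f}%)")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_sub == 0:
        return seq
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [a for a in AA if a != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_ss(family: str, n_tail: int, c_tail: int) -> str:
    """SS string of total length PROTEIN_LEN for the given family and tails.

    Helix lengths are fixed per family; interior loops flex to absorb the
    length budget left over by the tails.
    """
    helices = BFR_HELICES if family == "bfr" else DPS_HELICES
    n_loops = len(helices) - 1
    budget = PROTEIN_LEN - sum(helices) - n_tail - c_tail
    if budget < n_loops:
        raise ValueError(f"tails ({n_tail},{c_tail}) leave no room for loops")
    base, extra = divmod(budget, n_loops)
    loops = [base + (1 if i < extra else 0) for i in range(n_loops)]
    parts = ["C" * n_tail]
    for h, l in zip(helices[:-1], loops):
        parts.append("H" * h)
        parts.append("C" * l)
    parts.append("H" * helices[-1])
    parts.append("C" * c_tail)
    ss = "".join(parts)
    assert len(ss) == PROTEIN_LEN
    return ss


def _jitter_tails(family: str, rng: np.random.Generator) -> tuple[int, int]:
    base_n, base_c = FAMILY_TAILS[family]
    n = max(0, base_n + int(rng.integers(-2, 3)))
    c = max(0, base_c + int(rng.integers(-2, 3)))
    return n, c


def make_ancestors(seed: int) -> dict[str, str]:
    """Root-derived family ancestors (the reference proteins) plus bfr."""
    rng = np.random.default_rng([seed, 0xA11CE])
    root = random_protein(PROTEIN_LEN, rng)
    out = {}
    for ref in REFERENCE_IDS:
        out[ref] = mutate_to_identity(root, 100.0 - FAMILY_DIVERGENCE, rng=rng)
    out[BFR_ID] = mutate_to_identity(root, 100.0 - BFR_DIVERGENCE, rng=rng)
    return out


# ---------------------------------------------------------------------------
# Replicon generator


def _random_dna(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_NT, size=length, p=_NT_P)


def _sample_motif(pattern: MotifPattern, rng: np.random.Generator) -> tuple[str, int]:
    """A concrete motif instance: degenerate positions sampled uniformly,
    spacer length uniform over the allowed range."""
    k = int(rng.integers(pattern.spacer_min, pattern.spacer_max + 1))
    bases = []
    for c in pattern.left_block:
        bases.append(IUPAC[c][rng.integers(len(IUPAC[c]))])
    for _ in range(k):
        bases.append("ACGT"[rng.integers(4)])
    for c in pattern.right_block:
        bases.append(IUPAC[c][rng.integers(len(IUPAC[c]))])
    return "".join(bases), k


@dataclass
class _GenePlan:
    id: str
    family: str
    length: int
    strand: str
    plant_motif: bool = False
    decoy_spacer: Optional[int] = None   # e.g. 17: spacer outside bounds
    far_distance: Optional[int] = None   # e.g. 250: beyond max_dist


def generate_replicon(
    genome_id: str,
    dps_complement: Sequence[str] = ("dpsA", "dpsB", "dpsB2"),
    plant_motif_for: Iterable[str] = ("dpsA", "dpsB2", "dpsC"),
    decoy_spacer_for: Iterable[str] = (),
    far_motif_for: Iterable[str] = (),
    length: int = REPLICON_LENGTH,
    n_genes: int = N_GENES,
    arm_threshold: int = ARM_THRESHOLD,
    max_dist: int = MAX_DIST,
    pattern_spec: str = SIGB_PATTERN_SPEC,
    conserved_neighbours: Optional[Sequence[str]] = None,
    shuffle_pool_size: int = 20,
    seed: int = 0,
    max_attempts: int = 100,
) -> tuple[Replicon, TruthSet]:
    """One linear replicon with planted dps genes, motifs and neighbourhoods.

    dnaA lands in the central 10% of the chromosome; motif-bearing dps genes
    go to the arms (strictly inside ``arm_threshold`` of an end) and the
    motif-free dpsB to the core. ``decoy_spacer_for``/``far_motif_for`` plant
    negative controls (spacer 17 nt / motif 250 nt upstream) that a correct
    scanner must reject. The emitted replicon is mirrored with probability
    1/2 (dnaA on the minus strand) to exercise orientation calibration;
    the TruthSet always refers to the oriented (dnaA plus strand) frame.
    """
    unknown = set(dps_complement) - set(DPS_FAMILIES)
    if unknown:
        raise ValueError(f"unknown dps families: {sorted(unknown)}")
    name_tag = sum(genome_id.encode()) % (2 ** 16)  # stable across sessions
    rng = np.random.default_rng([seed, name_tag])
    pattern = compile_pattern(pattern_spec)
    plant_motif_for = set(plant_motif_for)
    decoy_spacer_for = set(decoy_spacer_for)
    far_motif_for = set(far_motif_for)
    if conserved_neighbours is None:
        conserved_neighbours = [f"coreNb{i}" for i in range(1, 7)]
    truth = TruthSet(seeds={genome_id: seed})

    dps_len = 3 * PROTEIN_LEN + 3
    gap_lo, gap_hi = 300, 450  # intergenic gaps inside gene blocks

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # --- plan gene blocks (contiguous runs of genes) -----------------------
    blocks: list[tuple[float, list[_GenePlan]]] = []  # (anchor bp, plans)
    shuffle_pool = [f"shufNb{i:02d}" for i in range(1, shuffle_pool_size + 1)]

    def neighbour_plans(kind: str, side: str,
                        focal_strand: str = "+") -> list[_GenePlan]:
        """Three neighbour genes for one side of a focal gene, in coordinate
        order. Conserved neighbourhoods are laid out in the focal gene's
        reading direction (upstream families before it, downstream after),
        so the rank-offset profile is identical across genomes regardless of
        the focal strand."""
        if kind == "conserved":
            up, down = conserved_neighbours[:3], conserved_neighbours[3:]
            if focal_strand == "+":
                fams = up if side == "L" else down
            else:
                fams = list(reversed(down)) if side == "L" else list(reversed(up))
        else:
            fams = [shuffle_pool[rng.integers(len(shuffle_pool))]
                    for _ in range(3)]
        plans = []
        for i, fam in enumerate(fams):
            plans.append(_GenePlan(
                id=f"{genome_id}_{fam}_{side}{i}_{rng.integers(10**6)}",
                family=fam,
                length=int(rng.integers(400, 900)),
                strand=rand_strand(),
            ))
        return plans

    n_used = 1  # dnaA
    arm_sides = ["L", "R"]
    rng.shuffle(arm_sides)
    side_iter = iter(arm_sides * 4)
    for fam in dps_complement:
        focal = _GenePlan(
            id=f"{genome_id}_{fam}",
            family=fam,
            length=dps_len,
            strand=rand_strand(),
            plant_motif=fam in plant_motif_for,
            decoy_spacer=17 if fam in decoy_spacer_for else None,
            far_distance=(max_dist + 50) if fam in far_motif_for else None,
        )
        in_core = fam == "dpsB"
        kind = "conserved" if in_core else "shuffled"
        plans = (neighbour_plans(kind, "L", focal.strand) + [focal] +
                 neighbour_plans(kind, "R", focal.strand))
        if in_core:
            # strictly inside the core: comfortably past the arm boundary
            if not arm_threshold < length / 2:
                raise ValueError("arm_threshold must be below half the "
                                 "replicon length to leave a core region")
            pad = 0.1 * (length / 2 - arm_threshold)
            anchor = rng.uniform(arm_threshold + pad, length / 2 - pad)
        else:
            side = next(side_iter)
            d = rng.uniform(0.15 * arm_threshold, 0.75 * arm_threshold)
            anchor = d if side == "L" else length - d
        blocks.append((anchor, plans))
        n_used += 7

    # dnaA block, central 10%
    dnaa_plan = _GenePlan(id=f"{genome_id}_dnaA", family="dnaA",
                          length=int(rng.integers(1300, 1600)), strand="+")
    blocks.append((length / 2 + rng.uniform(-0.04, 0.04) * length, [dnaa_plan]))

    # filler genes in their own single-gene blocks
    n_fillers = max(0, n_genes - n_used)
    for i in range(n_fillers):
        plan = _GenePlan(id=f"{genome_id}_fill{i:03d}",
                         family=f"fill{i:03d}",
                         length=int(rng.integers(400, 900)),
                         strand=rand_strand())
        blocks.append((rng.uniform(0.05e6, length - 0.05e6), [plan]))

    # --- place blocks without overlap --------------------------------------
    placed: list[tuple[int, int]] = []
    genes: list[GeneLocus] = []
    plan_by_gene: dict[str, _GenePlan] = {}
    for anchor, plans in sorted(blocks, key=lambda b: b[0]):
        span = sum(p.length for p in plans) + (len(plans) + 1) * gap_hi
        for attempt in range(max_attempts):
            start = int(min(max(0, anchor - span / 2), length - span))
            if attempt:
                start = int(rng.uniform(0, length - span))
            if all(start + span <= s or start >= e for s, e in placed):
                break
        else:
            raise RuntimeError(f"could not place gene block near {anchor:.0f} bp")
        placed.append((start, start + span))
        pos = start + int(rng.integers(gap_lo, gap_hi))
        for p in plans:
            genes.append(GeneLocus(id=p.id, start=pos, end=pos + p.length,
                                   strand=p.strand, family=p.family,
                                   replicon_id=genome_id))
            plan_by_gene[p.id] = p
            pos += p.length + int(rng.integers(gap_lo, gap_hi))

    # --- sequence, motif planting, window cleaning -------------------------
    seq_arr = _random_dna(length, rng)
    replicon = Replicon(id=genome_id, sequence=seq_arr.tobytes().decode(),
                        genes=genes)

    protected: list[tuple[int, int]] = []  # forward spans never resampled

    def write_coding(gene: GeneLocus, upstream_offset: int, text: str) -> tuple[int, int]:
        """Write ``text`` on the gene's coding strand ending ``upstream_offset``
        nt before the ORF start; returns the forward-strand span."""
        if gene.strand == "+":
            e = gene.start - upstream_offset
            s = e - len(text)
            seq_arr[s:e] = np.frombuffer(text.encode(), dtype=np.uint8)
        else:
            s = gene.end + upstream_offset
            e = s + len(text)
            seq_arr[s:e] = np.frombuffer(revcomp(text).encode(), dtype=np.uint8)
        return s, e

    for g in genes:
        p = plan_by_gene[g.id]
        if p.plant_motif:
            motif, k = _sample_motif(pattern, rng)
            dist = int(rng.integers(20, max_dist - 40))
            s, e = write_coding(g, dist, motif)
            protected.append((s, e))
            truth.planted_motifs[g.id] = {
                "distance": dist, "spacer_len": k, "start": s, "end": e,
                "decoy": False,
            }
        if p.far_distance is not None:
            motif, k = _sample_motif(pattern, rng)
            s, e = write_coding(g, p.far_distance, motif)
            protected.append((s, e))
            truth.planted_motifs[g.id + "@far"] = {
                "distance": p.far_distance, "spacer_len": k, "start": s, "end": e,
                "decoy": True,
            }
        if p.decoy_spacer is not None:
            decoy_pat = MotifPattern(pattern.left_block, p.decoy_spacer,
                                     p.decoy_spacer, pattern.right_block)
            motif, k = _sample_motif(decoy_pat, rng)
            dist = int(rng.integers(20, max_dist - 40))
            s, e = write_coding(g, dist, motif)
            protected.append((s, e))
            truth.planted_motifs[g.id + "@spacer17"] = {
                "distance": dist, "spacer_len": k, "start": s, "end": e,
                "decoy": True,
            }

    _clean_windows(seq_arr, replicon, pattern, 2 * max_dist, protected,
                   rng, max_attempts)
    replicon.sequence = seq_arr.tobytes().decode()

    # --- truth bookkeeping --------------------------------------------------
    for fam in dps_complement:
        truth.planted_families[f"{genome_id}_{fam}"] = CLUSTER_OF[fam]
    for g in genes:
        fam = plan_by_gene[g.id].family
        if fam in DPS_FAMILIES:
            ratio = TRUE_INDUCED_RATIO if plan_by_gene[g.id].plant_motif else 1.0
            truth.planted_fold_changes[g.id] = ratio

    # --- randomly mirror so that orientation calibration is exercised -------
    if rng.random() < 0.5:
        L = replicon.length
        mirrored = [GeneLocus(id=g.id, start=L - g.end, end=L - g.start,
                              strand="+" if g.strand == "-" else "-",
                              family=g.family, replicon_id=g.replicon_id)
                    for g in replicon.genes]
        replicon = Replicon(id=genome_id, sequence=revcomp(replicon.sequence),
                            genes=mirrored)
    return replicon, truth


def _clean_windows(seq_arr: np.ndarray, replicon: Replicon,
                   pattern: MotifPattern, window: int,
                   protected: Sequence[tuple[int, int]],
                   rng: np.random.Generator, max_attempts: int) -> None:
    """Rejection-sample away chance motif hits in every gene's scanned
    upstream window, leaving planted spans untouched."""
    prot = sorted(protected)

    def is_protected(s: int, e: int) -> bool:
        return any(not (e <= ps or s >= pe) for ps, pe in prot)

    for _ in range(max_attempts):
        replicon.sequence = seq_arr.tobytes().decode()
        dirty = False
        for g in replicon.genes:
            sub, lo, hi = upstream_window(g, replicon, window,
                                          intergenic_truncate=False)
            if not sub:
                continue
            for h in scan(sub, pattern, strand_mode="+"):
                if g.strand == "+":
                    fs, fe = lo + h.start, lo + h.end
                else:
                    fs, fe = hi - h.end, hi - h.start
                if is_protected(fs, fe):
                    continue
                # resample the unprotected bases of the offending span
                for pos in range(fs, fe):
                    if not is_protected(pos, pos + 1):
                        seq_arr[pos] = _NT[rng.choice(4, p=_NT_P)]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("window cleaning did not converge "
                       f"within {max_attempts} passes")


# ---------------------------------------------------------------------------
# Cohort generator


DEFAULT_COMPLEMENTS: tuple[tuple[str, ...], ...] = (
    # emulates the 17-genome comparison: dpsB nearly ubiquitous, six genomes
    # with a dpsB paralog pair, dpsA and dpsC sparsely distributed
    ("dpsB", "dpsB2"), ("dpsB", "dpsB2"), ("dpsB", "dpsB2"),
    ("dpsB", "dpsB2"), ("dpsB", "dpsB2"), ("dpsB", "dpsB2"),
    ("dpsA", "dpsB"), ("dpsA", "dpsB"),
    ("dpsB", "dpsC"), ("dpsB", "dpsC"), ("dpsB", "dpsC"),
    ("dpsB", "dpsC"), ("dpsB", "dpsC"),
    ("dpsB",), ("dpsB",), ("dpsB",), ("dpsB",),
)


@dataclass
class Genome:
    """One synthetic genome: replicon + proteome + SS annotations."""

    id: str
    replicon: Replicon
    proteome: list[ProteinRecord]
    ss: dict[str, tuple[str, float]]


@dataclass
class Cohort:
    genomes: list[Genome]
    references: list[ProteinRecord]        # dpsA_Sc, dpsB_Sc, dpsC_Sc
    bfr: ProteinRecord
    reference_ss: dict[str, tuple[str, float]]
    msa: list[tuple[str, str]]             # dps members + refs + bfr, ungapped
    ct_records: list[QpcrRecord]
    truth: TruthSet


def generate_cohort(
    n_genomes: int = 17,
    complements: Optional[Sequence[Sequence[str]]] = None,
    plant_motif_for: Iterable[str] = ("dpsA", "dpsB2", "dpsC"),
    decoy_spacer_for: Iterable[str] = (),
    far_motif_for: Iterable[str] = (),
    length: int = REPLICON_LENGTH,
    n_genes: int = N_GENES,
    arm_threshold: int = ARM_THRESHOLD,
    noise_sd: float = 0.2,
    n_reps: int = 3,
    efficiency: float = 2.0,
    evalue_max: float = orthology.DEFAULT_EVALUE_MAX,
    seed: int = 0,
) -> Cohort:
    """A full cohort of genomes, proteomes, SS, alignment, Ct table and truth."""
    if n_genomes < 2:
        raise ValueError("a cohort needs at least 2 genomes")
    if complements is None:
        complements = [DEFAULT_COMPLEMENTS[i % len(DEFAULT_COMPLEMENTS)]
                       for i in range(n_genomes)]
    if len(complements) != n_genomes:
        raise ValueError("complements must have one entry per genome")
    for comp in complements:
        if "dpsB2" in comp and "dpsB" not in comp:
            raise ValueError("dpsB2 is a duplication of dpsB: a complement "
                             "with dpsB2 must also contain dpsB")

    ancestors = make_ancestors(seed)
    refs = [ProteinRecord(rid, ancestors[rid], organism="S.coelicolor")
            for rid in REFERENCE_IDS]
    bfr = ProteinRecord(BFR_ID, ancestors[BFR_ID], organism="S.coelicolor")
    ref_ss: dict[str, tuple[str, float]] = {}
    for rid, fam in (("dpsA_Sc", "dpsA"), ("dpsB_Sc", "dpsB"), ("dpsC_Sc", "dpsC")):
        n, c = FAMILY_TAILS[fam]
        ref_ss[rid] = (make_ss(fam, n, c), 90.0)
    ref_ss[BFR_ID] = (make_ss("bfr", *FAMILY_TAILS["bfr"]), 90.0)

    truth = TruthSet(seeds={"cohort": seed})
    genomes: list[Genome] = []
    msa: list[tuple[str, str]] = []

    for gi in range(n_genomes):
        genome_id = f"g{gi + 1:02d}"
        rng = np.random.default_rng([seed, 1000 + gi])
        complement = tuple(complements[gi])
        replicon, g_truth = generate_replicon(
            genome_id, dps_complement=complement,
            plant_motif_for=plant_motif_for,
            decoy_spacer_for=decoy_spacer_for,
            far_motif_for=far_motif_for,
            length=length, n_genes=n_genes, arm_threshold=arm_threshold,
            seed=int(np.random.default_rng([seed, 2000 + gi]).integers(2 ** 31)),
        )
        truth.merge(g_truth)

        proteome: list[ProteinRecord] = []
        ss_map: dict[str, tuple[str, float]] = {}
        dps_seqs: dict[str, str] = {}
        # dps proteins: mutated family ancestors; dpsB2 duplicates dpsB
        for fam in complement:
            pid = f"{genome_id}_{fam}"
            if fam == "dpsB2":
                continue  # derived from the sibling dpsB copy below
            anc = ancestors[CLUSTER_OF[fam]]
            ident = 100.0 - rng.uniform(0.5 * MEMBER_DIVERGENCE, MEMBER_DIVERGENCE)
            dps_seqs[pid] = mutate_to_identity(anc, ident, rng=rng)
        if "dpsB2" in complement:
            target = float(np.clip(
                rng.normal(PARALOG_IDENTITY_MEAN, PARALOG_IDENTITY_SD),
                *PARALOG_IDENTITY_BOUNDS))
            pid = f"{genome_id}_dpsB2"
            sib = f"{genome_id}_dpsB"
            dps_seqs[pid] = mutate_to_identity(dps_seqs[sib], target, rng=rng)
            truth.planted_paralog_pairs.append([sib, pid, target])

        for g in replicon.genes_sorted():
            fam = g.family
            if fam in DPS_FAMILIES:
                pid = g.id
                seq = dps_seqs[pid]
                n, c = _jitter_tails(fam, rng)
                ss = make_ss(fam, n, c)
                conf = float(np.round(rng.uniform(55, 95), 1))
                proteome.append(ProteinRecord(pid, seq, organism=genome_id,
                                              ss=ss, ss_confidence=conf))
                ss_map[pid] = (ss, conf)
                truth.planted_tails[pid] = [n, c]
                msa.append((pid, seq))
            else:
                seq = _background_protein(rng, refs, evalue_max)
                proteome.append(ProteinRecord(g.id, seq, organism=genome_id))
        genomes.append(Genome(genome_id, replicon, proteome, ss_map))

    msa.extend((r.id, r.sequence) for r in refs)
    msa.append((bfr.id, bfr.sequence))

    ct_records = generate_ct_table(
        truth.planted_fold_changes, efficiency=efficiency, noise_sd=noise_sd,
        n_reps=n_reps, seed=seed)

    return Cohort(genomes=genomes, references=refs, bfr=bfr,
                  reference_ss=ref_ss, msa=msa, ct_records=ct_records,
                  truth=truth)


def _background_protein(rng: np.random.Generator,
                        refs: Sequence[ProteinRecord],
                        evalue_max: float, max_tries: int = 50) -> str:
    """A random protein with no qualifying hit against the Dps references.

    Background genes model loci unrelated to dps; the occasional chance
    local-alignment hit below the relaxed E-value cutoff is rejected so that
    family membership stays recoverable by construction.
    """
    for _ in range(max_tries):
        seq = random_protein(int(rng.integers(150, 320)), rng)
        if all(orthology.align_pair(seq, r.sequence).evalue > evalue_max
               for r in refs):
            return seq
    raise RuntimeError("could not draw a background protein without a "
                       "spurious reference hit")


# ---------------------------------------------------------------------------
# Ct table generator


def generate_ct_table(true_ratios: Mapping[str, float],
                      efficiency: float = 2.0,
                      noise_sd: float = 0.2,
                      n_reps: int = 3,
                      seed: int = 0,
                      reference_gene: str = "hrdB",
                      base_ct: float = 22.0,
                      ref_ct: float = 20.0) -> list[QpcrRecord]:
    """Ct rows realising the given true control->stress expression ratios.

    Stress Ct of a target gene is shifted by -log_E(ratio) relative to its
    control Ct; the reference gene (hrdB) has identical control and stress
    baselines, so its fold change is 1 by construction. Independent
    Normal(0, noise_sd) noise is added to every Ct.
    """
    if not 1.0 <= efficiency <= 2.0:
        raise ValueError(f"efficiency {efficiency} outside [1, 2]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng([seed, 0xC7])
    rows: list[QpcrRecord] = []

    def noisy(x: float) -> float:
        return float(x + rng.normal(0.0, noise_sd)) if noise_sd > 0 else float(x)

    for rep in range(1, n_reps + 1):
        rows.append(QpcrRecord(reference_gene, "control", rep, noisy(ref_ct),
                               efficiency, reference_flag=True))
        rows.append(QpcrRecord(reference_gene, "stress", rep, noisy(ref_ct),
                               efficiency, reference_flag=True))
        for gene in sorted(true_ratios):
            ratio = true_ratios[gene]
            if ratio <= 0:
                raise ValueError(f"gene {gene!r}: true ratio must be > 0")
            shift = np.log(ratio) / np.log(efficiency) if efficiency > 1 else 0.0
            rows.append(QpcrRecord(gene, "control", rep, noisy(base_ct),
                                   efficiency))
            rows.append(QpcrRecord(gene, "stress", rep, noisy(base_ct - shift),
                                   efficiency))
    return rows


# ---------------------------------------------------------------------------
# On-disk cohort


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write FASTA/GFF3/SS/Ct/truth files; returns a manifest dict."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"genomes": [], "seed": cohort.truth.seeds.get("cohort")}
    for g in cohort.genomes:
        fna = out / f"{g.id}.fna"
        gff = out / f"{g.id}.gff3"
        faa = out / f"{g.id}.faa"
        ssf = out / f"{g.id}.ss.fasta"
        dio.write_fasta(fna, {g.id: g.replicon.sequence})
        dio.write_gff(gff, {g.id: g.replicon.genes})
        dio.write_fasta(faa, g.proteome)
        dio.write_ss(ssf, g.ss)
        manifest["genomes"].append(
            {"id": g.id, "fasta": fna.name, "gff": gff.name,
             "proteome": faa.name, "ss": ssf.name})
    dio.write_fasta(out / "references.faa", cohort.references + [cohort.bfr])
    dio.write_ss(out / "references.ss.fasta", cohort.reference_ss)
    dio.write_fasta(out / "msa.afa", cohort.msa)
    dio.write_ct_table(out / "ct.tsv", cohort.ct_records)
    (out / "truth.json").write_text(cohort.truth.to_json())
    manifest.update(references="references.faa", reference_ss="references.ss.fasta",
                    msa="msa.afa", ct="ct.tsv", truth="truth.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
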