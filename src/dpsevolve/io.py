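"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils, Ct tables through pandas.
The secondary-structure (SS) annotation file is a small FASTA-like dialect of
our own: one record per protein id, sequence letters over {H,E,C}, and the
header carrying ``conf=<0-100>`` (the overall prediction confidence).

GFF3 on disk is 1-based inclusive; everything in memory is 0-based half-open.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .records import PROTEIN_ALPHABET, SS_STATES, GeneLocus, ProteinRecord, QpcrRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")

CT_COLUMNS = ["gene", "condition", "replicate", "ct", "efficiency", "reference_flag"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = "protein"):
    """Read a FASTA file into :class:`ProteinRecord` objects or raw sequences.

    ``alphabet="protein"`` returns ProteinRecord objects (organism taken from
    the first word of the description after the id, if any);
    ``alphabet="nucleotide"`` returns a dict id -> uppercase ACGT(N) string.
    Sequences are upper-cased and gap characters stripped; use
    :func:`read_alignment` for aligned FASTA.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    seen: set[str] = set()
    out_records: list[ProteinRecord] = []
    out_nt: dict[str, str] = {}
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("-", "")
        for i, c in enumerate(seq):
            if c not in allowed:
                raise ValueError(
                    f"{path}: record {rec.id!r}: illegal character {c!r} at position {i}"
                )
        if alphabet == "protein":
            desc = rec.description[len(rec.id):].strip()
            organism = desc.split()[0] if desc else ""
            out_records.append(ProteinRecord(id=rec.id, sequence=seq, organism=organism))
        else:
            out_nt[rec.id] = seq
    return out_records if alphabet == "protein" else out_nt


def write_fasta(path, records, width: int = 70) -> None:
    """Write ProteinRecord objects, (id, seq) pairs, or an id->seq dict."""
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = [
            (r.id, r.sequence) if isinstance(r, ProteinRecord) else (r[0], r[1])
            for r in records
        ]
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_alignment(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA; returns (id, row) pairs, rows upper-cased with gaps."""
    rows = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        rows.append((rec.id, str(rec.seq).upper()))
    if rows and len({len(s) for _, s in rows}) != 1:
        raise ValueError(f"{path}: aligned rows have unequal lengths")
    return rows


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path) -> dict[str, list[GeneLocus]]:
    """Read gene features from GFF3, grouped by replicon id.

    Coordinates are converted from the on-disk 1-based inclusive convention to
    0-based half-open. The gene family is read from the ``family`` attribute;
    records lacking it get family ``"other"``.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list[GeneLocus]] = defaultdict(list)
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise ValueError(f"{path}: feature {feat.id}: end < start")
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: feature {feat.id}: unknown strand {feat.strand!r}")
        family = feat.attributes.get("family", ["other"])[0]
        gid = feat.attributes.get("ID", [feat.id])[0]
        grouped[feat.seqid].append(
            GeneLocus(
                id=gid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand,
                family=family,
                replicon_id=feat.seqid,
            )
        )
    return dict(grouped)


def write_gff(path, genes_by_replicon: dict[str, Sequence[GeneLocus]]) -> None:
    """Write gene loci to GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid in genes_by_replicon:
            for g in sorted(genes_by_replicon[rid], key=lambda g: (g.start, g.id)):
                attrs = f"ID={g.id};family={g.family}"
                fh.write(
                    f"{rid}\tdpsevolve\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# SS annotation dialect

_CONF_RE = re.compile(r"\bconf=([0-9]+(?:\.[0-9]+)?)\b")


def read_ss(path) -> dict[str, tuple[str, float]]:
    """Read the SS annotation file: id -> (state string, confidence %)."""
    out: dict[str, tuple[str, float]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        m = _CONF_RE.search(rec.description)
        if not m:
            raise ValueError(f"{path}: record {rec.id!r} header lacks conf=")
        conf = float(m.group(1))
        ss = str(rec.seq).upper()
        for i, c in enumerate(ss):
            if c not in SS_STATES:
                raise ValueError(
                    f"{path}: record {rec.id!r}: illegal SS state {c!r} at position {i}"
                )
        out[rec.id] = (ss, conf)
    return out


def write_ss(path, ss_by_id: dict[str, tuple[str, float]]) -> None:
    with open(path, "w") as fh:
        for rid, (ss, conf) in ss_by_id.items():
            fh.write(f">{rid} conf={conf:g}\n{ss}\n")


def attach_ss(records: Iterable[ProteinRecord], ss_by_id: dict[str, tuple[str, float]],
              strict: bool = True) -> list[ProteinRecord]:
    """Attach SS strings/confidences to protein records (by id)."""
    out = []
    for r in records:
        if r.id in ss_by_id:
            ss, conf = ss_by_id[r.id]
            out.append(ProteinRecord(r.id, r.sequence, r.organism, ss, conf))
        elif strict:
            raise KeyError(f"no SS annotation for protein {r.id!r}")
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Ct tables


def read_ct_table(path) -> list[QpcrRecord]:
    """Read a TSV Ct table and validate completeness.

    Requires columns gene, condition, replicate, ct, efficiency,
    reference_flag; every condition x replicate combination present in the
    table must include at least one reference (hrdB) row, and every
    non-reference gene must have both conditions for each of its replicates.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = [
        QpcrRecord(
            gene=str(row.gene),
            condition=str(row.condition),
            replicate=int(row.replicate),
            ct=float(row.ct),
            efficiency=float(row.efficiency),
            reference_flag=bool(row.reference_flag),
        )
        for row in df.itertuples()
    ]
    validate_ct_records(records, source=str(path))
    return records


def validate_ct_records(records: Sequence[QpcrRecord], source: str = "ct table") -> None:
    combos = {(r.condition, r.replicate) for r in records}
    ref_combos = {(r.condition, r.replicate) for r in records if r.reference_flag}
    lacking = sorted(combos - ref_combos)
    if lacking:
        raise ValueError(f"{source}: no reference row for condition/replicate {lacking}")
    by_gene: dict[str, set[tuple[str, int]]] = defaultdict(set)
    for r in records:
        by_gene[r.gene].add((r.condition, r.replicate))
    for gene, combos_g in by_gene.items():
        reps = {rep for _, rep in combos_g}
        want = {(c, rep) for c in QpcrRecord.CONDITIONS for rep in reps}
        lacking = sorted(want - combos_g)
        if lacking:
            raise ValueError(f"{source}: gene {gene!r} missing condition/replicate {lacking}")


def write_ct_table(path, records: Sequence[QpcrRecord]) -> None:
    df = pd.DataFrame(
        [
            (r.gene, r.condition, r.replicate, r.ct, r.efficiency, r.reference_flag)
            for r in records
        ],
        columns=CT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
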