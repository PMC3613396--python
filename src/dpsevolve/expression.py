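"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

Transcript abundance of each *dps* gene is expressed relative to the
principal sigma factor *hrdB* as

    ratio = E_target ** dCt_target / E_ref ** dCt_ref

where E is the per-amplicon amplification efficiency (1 = no amplification,
2 = perfect doubling) and dCt = Ct_control - Ct_stress. Ratios are computed
per biological replicate, then summarised as mean and sample (n-1) standard
deviation; a gene is called induced when the mean ratio reaches the fold
threshold (default 2.0).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records import QpcrRecord

INDUCTION_FOLD_THRESHOLD = 2.0


@dataclass(frozen=True)
class FoldChange:
    gene: str
    ratio_mean: float
    ratio_sd: float
    n_reps: int
    induced: bool
    per_replicate: tuple[float, ...] = ()


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio E_t^dCt_t / E_r^dCt_r."""
    for e in (e_target, e_ref):
        if not 1.0 <= e <= 2.0:
            raise ValueError(f"efficiency {e} outside [1, 2]")
    return e_target ** dct_target / e_ref ** dct_ref


def efficiency_from_dilution(log10_dilution: Sequence[float],
                             ct: Sequence[float]) -> float:
    """Amplification efficiency from a standard dilution series.

    Fits Ct against log10(template dilution) and returns
    E = 10 ** (-1 / slope); a perfect assay has slope -3.32 and E = 2.
    """
    if len(log10_dilution) != len(ct) or len(ct) < 2:
        raise ValueError("need >= 2 paired (dilution, Ct) points")
    slope = np.polyfit(np.asarray(log10_dilution, float), np.asarray(ct, float), 1)[0]
    if slope == 0:
        raise ValueError("zero slope: Ct does not respond to dilution")
    return 10.0 ** (-1.0 / slope)


def _index(records: Sequence[QpcrRecord]):
    by_gene: dict[str, dict[tuple[str, int], QpcrRecord]] = defaultdict(dict)
    ref_rows: dict[tuple[str, int], QpcrRecord] = {}
    for r in records:
        by_gene[r.gene][(r.condition, r.replicate)] = r
        if r.reference_flag:
            ref_rows[(r.condition, r.replicate)] = r
    return by_gene, ref_rows


def summarize(records: Sequence[QpcrRecord],
              induction_threshold: float = INDUCTION_FOLD_THRESHOLD,
              include_reference: bool = False) -> list[FoldChange]:
    """Per-gene Pfaffl fold changes across biological replicates.

    Each replicate needs the gene's control and stress Ct plus matching
    reference-gene rows; an unpaired replicate is an error naming the gene.
    The reference gene itself (fold change 1 by construction up to Ct noise)
    is reported only with ``include_reference``.
    """
    by_gene, ref_rows = _index(records)
    out = []
    for gene in sorted(by_gene):
        rows = by_gene[gene]
        is_ref = any(r.reference_flag for r in rows.values())
        if is_ref and not include_reference:
            continue
        reps = sorted({rep for _, rep in rows})
        ratios = []
        for rep in reps:
            try:
                ctrl = rows[("control", rep)]
                stress = rows[("stress", rep)]
            except KeyError:
                raise ValueError(f"gene {gene!r}: unpaired replicate {rep}")
            try:
                ref_c = ref_rows[("control", rep)]
                ref_s = ref_rows[("stress", rep)]
            except KeyError:
                raise ValueError(f"gene {gene!r}: no reference rows for replicate {rep}")
            dct_t = ctrl.ct - stress.ct
            dct_r = ref_c.ct - ref_s.ct
            ratios.append(pfaffl_ratio(ctrl.efficiency, dct_t, ref_c.efficiency, dct_r))
        mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
        out.append(FoldChange(gene, mean, sd, len(ratios),
                              mean >= induction_threshold, tuple(ratios)))
    return out


def induction_concordance(fold_changes: Sequence[FoldChange],
                          sigb_positive: Mapping[str, bool],
                          ) -> tuple[dict[str, int], float]:
    """2x2 agreement between promoter-motif presence and induction.

    Returns counts keyed ``motif+induced+``, ``motif+induced-``,
    ``motif-induced+``, ``motif-induced-`` plus percentage agreement
    (concordant genes / all genes). Both tables must cover the same genes.
    """
    fc_genes = {f.gene for f in fold_changes}
    sigb_genes = set(sigb_positive)
    orphans = sorted(fc_genes ^ sigb_genes)
    if orphans:
        raise ValueError(f"genes present in only one table: {orphans}")
    counts = {"motif+induced+": 0, "motif+induced-": 0,
              "motif-induced+": 0, "motif-induced-": 0}
    for f in fold_changes:
        key = ("motif+" if sigb_positive[f.gene] else "motif-") + \
              ("induced+" if f.induced else "induced-")
        counts[key] += 1
    n = len(fold_changes)
    agree = counts["motif+induced+"] + counts["motif-induced-"]
    return counts, (100.0 * agree / n if n else 100.0)
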