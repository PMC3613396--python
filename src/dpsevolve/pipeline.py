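"""End-to-end orchestration: from genomes to the per-gene dps report.

The pipeline chains every stage of the analysis — chromosome orientation,
RBH ortholog clustering against the *S. coelicolor* Dps references,
secondary-structure validation and tail taxonomy, the NJ/bootstrap
discrimination tree with bacterioferritin exclusion, SigB promoter calls,
core/arm location, neighbourhood synteny, and (when Ct data are supplied)
Pfaffl fold changes — and emits one report row per *dps* gene.

The headline predictive rule: a *dps* gene is predicted osmotically
inducible iff a SigB-like promoter motif is called upstream of its ORF.
``verify_dichotomy`` then checks, per duplicated gene pair, the expected
split into an arm-located, motif-bearing, poorly syntenic copy versus a
core-located, motif-free, well-conserved copy.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import dendropy
import pandas as pd
import yaml

from . import classify, context, expression, io as dio, orthology, promoters
from .records import ProteinRecord, Replicon
from .simulate import Cohort

log = logging.getLogger("dpsevolve")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage(name: str):
    return {"extra": {"stage": name}}


DEFAULT_PARAMS = {
    "evalue_max": 1e-3,
    "pattern": promoters.SIGB_PATTERN_SPEC,
    "max_dist": 200,
    "intergenic_only": True,
    "arm_threshold": 2_000_000,
    "min_conf": 40.0,
    "bootstrap_reps": 500,
    "induction_fold": 2.0,
    "paralog_identity_min": 80.0,
    "synteny_k": 3,
    "synteny_high_freq": 60.0,
    "seed": 0,
}

REPORT_COLUMNS = [
    "genome", "gene", "cluster", "paralog_partner", "paralog_identity",
    "n_tail", "c_tail", "tail_category", "dps_signature", "has_bc_helix",
    "position_mb", "compartment", "sigb_positive", "sigb_distance",
    "synteny_score", "fold_change_mean", "fold_change_sd", "induced",
    "predicted_osmo_inducible",
]


@dataclass
class PipelineResult:
    report: pd.DataFrame
    clusters: dict[str, orthology.OrthologCluster]
    tree: Optional[dendropy.Tree]
    retained_after_bfr: Optional[list[str]]
    synteny_profiles: dict[tuple[str, bool], context.SyntenyProfile]
    fold_changes: list[expression.FoldChange]
    concordance: Optional[tuple[dict, float]]
    params: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)


def load_cohort_dir(input_dir) -> Cohort:
    """Load a cohort previously written by :func:`dpsevolve.simulate.write_cohort`
    (or any directory following its manifest layout)."""
    from .simulate import Genome, TruthSet

    root = Path(input_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    genomes = []
    for entry in manifest["genomes"]:
        nt = dio.read_fasta(root / entry["fasta"], alphabet="nucleotide")
        genes = dio.read_gff(root / entry["gff"]).get(entry["id"], [])
        replicon = Replicon(id=entry["id"], sequence=nt[entry["id"]], genes=genes)
        proteome = dio.read_fasta(root / entry["proteome"])
        ss = dio.read_ss(root / entry["ss"])
        proteome = dio.attach_ss(proteome, ss, strict=False)
        genomes.append(Genome(entry["id"], replicon, proteome, ss))
    refs_all = dio.read_fasta(root / manifest["references"])
    ref_ss = dio.read_ss(root / manifest["reference_ss"])
    bfr = next(r for r in refs_all if r.id == "bfr_Sc")
    refs = [r for r in refs_all if r.id != "bfr_Sc"]
    msa = dio.read_alignment(root / manifest["msa"])
    ct = dio.read_ct_table(root / manifest["ct"]) if manifest.get("ct") else []
    truth = TruthSet(**json.loads((root / manifest["truth"]).read_text())) \
        if manifest.get("truth") else TruthSet()
    return Cohort(genomes=genomes, references=refs, bfr=bfr,
                  reference_ss=ref_ss, msa=msa, ct_records=ct, truth=truth)


def run_pipeline(cohort_or_dir: Union[Cohort, str, Path],
                 params: Optional[Mapping] = None,
                 out_dir=None) -> PipelineResult:
    """Run every stage on a cohort (in memory or an input directory).

    ``params`` overrides :data:`DEFAULT_PARAMS`; a string value for
    ``params`` is read as a YAML file. Artifacts (clusters.tsv, sigb.tsv,
    locations.tsv, synteny.tsv, tree.nwk, folds.tsv, report.tsv and a
    manifest with the config hash) are written when ``out_dir`` is given.
    Deterministic for fixed inputs and parameters.
    """
    if isinstance(params, (str, Path)):
        params = yaml.safe_load(Path(params).read_text())
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})

    if isinstance(cohort_or_dir, (str, Path)):
        missing = [f for f in ("manifest.json",)
                   if not (Path(cohort_or_dir) / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"input directory {cohort_or_dir} lacks {missing}")
        log.info("loading cohort from %s", cohort_or_dir, **_stage("load"))
        cohort = load_cohort_dir(cohort_or_dir)
    else:
        cohort = cohort_or_dir

    # --- orientation -------------------------------------------------------
    log.info("orienting %d replicons by dnaA strand", len(cohort.genomes),
             **_stage("orient"))
    oriented = {g.id: context.orient_replicon(g.replicon) for g in cohort.genomes}

    # --- orthology ---------------------------------------------------------
    log.info("RBH clustering against %d references (E<=%g)",
             len(cohort.references), p["evalue_max"], **_stage("orthology"))
    proteomes = {g.id: g.proteome for g in cohort.genomes}
    clusters = orthology.build_clusters(
        proteomes, cohort.references, evalue_max=p["evalue_max"],
        paralog_identity_min=p["paralog_identity_min"])
    cluster_of: dict[str, str] = {}
    for ref_id, cl in clusters.items():
        for m in cl.members:
            cluster_of[m] = ref_id
    partner: dict[str, tuple[str, float]] = {}
    for cl in clusters.values():
        for a, b, ident in cl.paralog_pairs:
            partner[a] = (b, ident)
            partner[b] = (a, ident)

    # --- structure: confidence filter, tails, signature --------------------
    log.info("structural validation (min confidence %.0f%%)", p["min_conf"],
             **_stage("classify"))
    members_with_ss = [prot for g in cohort.genomes for prot in g.proteome
                       if prot.id in cluster_of and prot.ss is not None]
    members_with_ss = classify.filter_by_confidence(members_with_ss, p["min_conf"])
    structure: dict[str, dict] = {}
    for prot in members_with_ss:
        segs = classify.helix_segments(prot.ss)
        sig, bc = classify.is_dps_signature(segs)
        n_tail, c_tail = classify.tail_lengths(prot.ss)
        structure[prot.id] = {
            "n_tail": n_tail, "c_tail": c_tail,
            "tail_category": classify.classify_tails(n_tail, c_tail),
            "dps_signature": sig, "has_bc_helix": bc,
        }

    # --- discrimination tree and bacterioferritin exclusion ----------------
    tree = None
    retained_ids = None
    if cohort.msa:
        log.info("NJ bootstrap consensus (%d pseudoreplicates)",
                 p["bootstrap_reps"], **_stage("tree"))
        tree = classify.bootstrap_consensus(cohort.msa, p["bootstrap_reps"],
                                            seed=p["seed"])
        # exclusion clades come from the full-data NJ tree, which carries
        # branch lengths for midpoint rooting; the consensus carries supports
        D, taxa = classify.p_distance_matrix(cohort.msa)
        nj = classify.nj_tree(D, taxa)
        bfr_ss, bfr_conf = cohort.reference_ss.get(cohort.bfr.id, (None, None))
        records = list(members_with_ss)
        records.append(ProteinRecord(cohort.bfr.id, cohort.bfr.sequence,
                                     ss=bfr_ss, ss_confidence=bfr_conf))
        retained = classify.exclude_bacterioferritins(records, nj,
                                                      [cohort.bfr.id])
        retained_ids = [r.id for r in retained]

    # --- promoter calls, location, neighbourhoods --------------------------
    log.info("promoter scan (%s, <=%d nt, intergenic=%s)",
             p["pattern"], p["max_dist"], p["intergenic_only"],
             **_stage("sigb"))
    pattern = promoters.compile_pattern(p["pattern"])
    rows = []
    neighbourhoods: dict[str, dict[int, str]] = {}
    sigb_of: dict[str, bool] = {}
    for g in cohort.genomes:
        replicon = oriented[g.id]
        for locus in replicon.genes_sorted():
            if locus.id not in cluster_of:
                continue
            call = promoters.sigb_call(locus, replicon, pattern,
                                       p["max_dist"], p["intergenic_only"])
            loc = context.core_arm(locus, replicon, p["arm_threshold"])
            neighbourhoods[locus.id] = context.neighbourhood(
                locus, replicon, p["synteny_k"])
            sigb_of[locus.id] = call.positive
            row = {
                "genome": g.id, "gene": locus.id,
                "cluster": cluster_of[locus.id],
                "paralog_partner": partner.get(locus.id, (None, None))[0],
                "paralog_identity": partner.get(locus.id, (None, None))[1],
                "position_mb": loc.position_mb,
                "compartment": loc.compartment,
                "sigb_positive": call.positive,
                "sigb_distance": call.distance_to_orf,
                "predicted_osmo_inducible": call.positive,
            }
            row.update(structure.get(locus.id, {}))
            rows.append(row)

    # --- synteny profiles by (cluster, promoter status) --------------------
    log.info("synteny consensus over gene-rank offsets +/-%d",
             p["synteny_k"], **_stage("synteny"))
    groups: dict[tuple[str, bool], list[str]] = {}
    for row in rows:
        groups.setdefault((row["cluster"], row["sigb_positive"]), []).append(row["gene"])
    profiles: dict[tuple[str, bool], context.SyntenyProfile] = {}
    synteny_score: dict[str, float] = {}
    for key, gene_ids in groups.items():
        if len(gene_ids) >= 2:
            prof = context.synteny_consensus(
                [neighbourhoods[gid] for gid in gene_ids], focal_family=key[0])
            profiles[key] = prof
            score = context.mean_consensus_frequency(prof)
        else:
            score = float("nan")
        for gid in gene_ids:
            synteny_score[gid] = score
    for row in rows:
        row["synteny_score"] = synteny_score.get(row["gene"], float("nan"))

    # --- expression --------------------------------------------------------
    fold_changes: list[expression.FoldChange] = []
    concordance = None
    if cohort.ct_records:
        log.info("Pfaffl fold changes (%d Ct rows)", len(cohort.ct_records),
                 **_stage("express"))
        fold_changes = expression.summarize(
            cohort.ct_records, induction_threshold=p["induction_fold"])
        fc_of = {f.gene: f for f in fold_changes}
        for row in rows:
            f = fc_of.get(row["gene"])
            row["fold_change_mean"] = f.ratio_mean if f else None
            row["fold_change_sd"] = f.ratio_sd if f else None
            row["induced"] = f.induced if f else None
        shared = [f for f in fold_changes if f.gene in sigb_of]
        if shared:
            concordance = expression.induction_concordance(
                shared, {f.gene: sigb_of[f.gene] for f in shared})

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = report.sort_values(["genome", "gene"]).reset_index(drop=True)
    result = PipelineResult(report=report, clusters=clusters, tree=tree,
                            retained_after_bfr=retained_ids,
                            synteny_profiles=profiles,
                            fold_changes=fold_changes,
                            concordance=concordance, params=p)
    if out_dir is not None:
        _write_artifacts(result, cohort, out_dir)
    return result


def verify_dichotomy(result: PipelineResult,
                     synteny_high_freq: Optional[float] = None) -> pd.DataFrame:
    """Per duplicated pair: does it split into the expected two classes?

    True iff exactly one member satisfies {arm, SigB+, low synteny} and the
    other {core, SigB-, high synteny}, with high/low synteny split at
    ``synteny_high_freq`` (default from the run's parameters). Genomes
    without a duplicated dps contribute no rows.
    """
    thr = synteny_high_freq if synteny_high_freq is not None \
        else result.params.get("synteny_high_freq", 60.0)
    rep = result.report.set_index("gene")
    out = []
    seen = set()
    for cl in result.clusters.values():
        for a, b, ident in cl.paralog_pairs:
            key = tuple(sorted((a, b)))
            if key in seen or a not in rep.index or b not in rep.index:
                continue
            seen.add(key)

            def is_inducible_type(gid):
                r = rep.loc[gid]
                return (r["compartment"] == "arm" and r["sigb_positive"]
                        and not r["synteny_score"] >= thr)

            def is_ancestral_type(gid):
                r = rep.loc[gid]
                return (r["compartment"] == "core" and not r["sigb_positive"]
                        and r["synteny_score"] >= thr)

            ok = ((is_inducible_type(a) and is_ancestral_type(b)) or
                  (is_inducible_type(b) and is_ancestral_type(a)))
            out.append({"gene_x": key[0], "gene_y": key[1],
                        "identity": ident, "dichotomy": bool(ok)})
    return pd.DataFrame(out, columns=["gene_x", "gene_y", "identity", "dichotomy"])


def _write_artifacts(result: PipelineResult, cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = {}

    cl_rows = [(ref, m, *(next(((a, b, i) for a, b, i in cl.paralog_pairs
                                if m in (a, b)), (None, None, None))[2:]))
               for ref, cl in result.clusters.items() for m in cl.members]
    pd.DataFrame(cl_rows, columns=["reference", "member", "paralog_identity"]) \
        .to_csv(out / "clusters.tsv", sep="\t", index=False)
    art["clusters"] = "clusters.tsv"

    sigb_cols = ["gene", "sigb_positive", "sigb_distance"]
    result.report[sigb_cols].to_csv(out / "sigb.tsv", sep="\t", index=False)
    art["sigb"] = "sigb.tsv"

    loc_cols = ["gene", "position_mb", "compartment", "sigb_positive"]
    result.report[loc_cols].to_csv(out / "locations.tsv", sep="\t", index=False)
    art["locations"] = "locations.tsv"

    syn_rows = [
        {"cluster": key[0], "sigb_group": key[1], "offset": off,
         "modal_family": fam, "frequency_pct": freq, "n_genomes": prof.n_genomes}
        for key, prof in result.synteny_profiles.items()
        for off, (fam, freq) in sorted(prof.offsets.items())
    ]
    pd.DataFrame(syn_rows, columns=["cluster", "sigb_group", "offset",
                                    "modal_family", "frequency_pct", "n_genomes"]) \
        .to_csv(out / "synteny.tsv", sep="\t", index=False)
    art["synteny"] = "synteny.tsv"

    if result.tree is not None:
        (out / "tree.nwk").write_text(
            result.tree.as_string(schema="newick", suppress_rooting=True))
        art["tree"] = "tree.nwk"

    if result.fold_changes:
        pd.DataFrame(
            [(f.gene, f.ratio_mean, f.ratio_sd, f.n_reps, f.induced)
             for f in result.fold_changes],
            columns=["gene", "ratio_mean", "ratio_sd", "n_reps", "induced"],
        ).to_csv(out / "folds.tsv", sep="\t", index=False)
        art["folds"] = "folds.tsv"

    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    art["report"] = "report.tsv"

    cfg_hash = hashlib.sha256(
        json.dumps(result.params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {"config_hash": cfg_hash, "seed": result.params.get("seed"),
                "params": result.params, "artifacts": art}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    result.artifacts = {k: str(out / v) for k, v in art.items()}
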