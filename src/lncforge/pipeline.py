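"""End-to-end orchestration: discover -> conserve -> DE -> modules -> eQTL.

A single YAML config names every input and threshold; the pipeline writes
per-stage tables under an output directory plus a machine-readable
``report.json`` whose per-stage record counts mirror the discovery
narrative (candidates -> criteria survivors -> cross-platform validated ->
known vs novel -> DE -> modules/hubs -> eQTL overlaps).  Reruns with the
same seed and config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import coexpression as _coex
from . import conservation as _cons
from . import discovery as _disc
from . import eqtl as _eqtl
from . import expression as _expr
from .coding import CodingModel, sequence_features, train_hexamer_table, train_logistic
from .gtf import read_gtf, write_gtf
from .models import AnnotationCatalog, TranscriptModel
from .simulate import read_fasta

logger = logging.getLogger(__name__)

_REQUIRED_INPUTS = (
    "reference", "platform_a", "platform_b", "sequences_a", "sequences_b",
    "train_coding", "train_noncoding", "counts", "tpm", "design", "biotypes",
    "conservation", "snps",
)


@dataclass
class RunConfig:
    """Validated run configuration (paths, thresholds, seed)."""

    seed: int
    inputs: Dict[str, str]
    databases: Dict[str, str]
    discovery: Dict
    de: Dict
    network: Dict
    eqtl: Dict

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=int(raw.get("seed", 0)),
            inputs=dict(raw.get("inputs", {})),
            databases=dict(raw.get("databases", {})),
            discovery=dict(raw.get("discovery", {})),
            de=dict(raw.get("de", {})),
            network=dict(raw.get("network", {})),
            eqtl=dict(raw.get("eqtl", {})),
        )


def validate_config(cfg: RunConfig) -> List[str]:
    """All problems that would prevent a run; empty iff runnable."""
    problems = []
    for key in _REQUIRED_INPUTS:
        path = cfg.inputs.get(key)
        if not path:
            problems.append(f"missing input path: {key}")
        elif not os.path.exists(path):
            problems.append(f"input file does not exist: {key} = {path}")
    for name, path in cfg.databases.items():
        if not os.path.exists(path):
            problems.append(f"database file does not exist: {name} = {path}")
    if not 0 < cfg.discovery.get("min_sample_fraction", 0.5) <= 1:
        problems.append("discovery.min_sample_fraction must lie in (0, 1]")
    if cfg.discovery.get("min_length_nt", 201) <= 0:
        problems.append("discovery.min_length_nt must be positive")
    if not 0 < cfg.de.get("max_adj_p", 0.001) < 1:
        problems.append("de.max_adj_p must lie in (0, 1)")
    if cfg.network.get("min_module_size", 30) <= 0:
        problems.append("network.min_module_size must be positive")
    beta = cfg.network.get("beta", 6)
    if beta != "auto" and (not isinstance(beta, int) or beta < 1):
        problems.append("network.beta must be a positive integer or 'auto'")
    if not 0 < cfg.eqtl.get("p_threshold", 1e-8) < 1:
        problems.append("eqtl.p_threshold must lie in (0, 1)")
    return problems


@dataclass
class RunReport:
    """Per-stage record counts plus headline statistics of one run."""

    config: Dict
    stages: Dict[str, Dict] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh,
                      indent=1, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = ["lncforge run report", "==================="]
        for stage, payload in self.stages.items():
            lines.append(f"[{stage}]")
            for k, v in sorted(payload.items()):
                lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _train_coding_model(cfg: RunConfig):
    coding = list(read_fasta(cfg.inputs["train_coding"]).values())
    noncoding = list(read_fasta(cfg.inputs["train_noncoding"]).values())
    table = train_hexamer_table(coding, noncoding)
    feats = np.array([sequence_features(s, table) for s in coding + noncoding])
    labels = [1] * len(coding) + [0] * len(noncoding)
    model = train_logistic(feats, labels)
    model.cutoff = float(cfg.discovery.get("coding_cutoff", 0.364))
    return model, table


def _discover(cfg: RunConfig, outdir: str, report: RunReport) -> AnnotationCatalog:
    ref = read_gtf(cfg.inputs["reference"])
    cands_a = read_gtf(cfg.inputs["platform_a"])
    cands_b = read_gtf(cfg.inputs["platform_b"])
    seqs_a = read_fasta(cfg.inputs["sequences_a"])
    seqs_b = read_fasta(cfg.inputs["sequences_b"])
    counts = pd.read_csv(cfg.inputs["counts"], sep="\t", index_col=0)
    model, table = _train_coding_model(cfg)

    dconf = _disc.DiscoveryConfig(
        min_sample_fraction=float(cfg.discovery.get("min_sample_fraction", 0.5)),
        min_length_nt=int(cfg.discovery.get("min_length_nt", 201)),
        allowed_codes=frozenset(cfg.discovery.get("allowed_codes",
                                                  ["u", "i", "x", "y"])),
        coding_cutoff=float(cfg.discovery.get("coding_cutoff", 0.364)),
    )

    prevalent = set(_disc.prevalence_filter(counts, dconf.min_sample_fraction))
    prevalent &= set(cands_a.transcript_ids)
    a_prevalent = cands_a.subset(
        [i for i in cands_a.transcript_ids if i in prevalent]
    )

    codes_a = _classify.classify_catalog(cands_a, ref)
    codes_a.to_csv(os.path.join(outdir, "classification_a.tsv"), sep="\t",
                   index=False)
    report_a = _disc.apply_novelty_criteria(
        a_prevalent, codes_a, seqs_a, model, table, dconf
    )
    report_a.criteria.to_csv(os.path.join(outdir, "criteria_a.tsv"), sep="\t")

    codes_b = _classify.classify_catalog(cands_b, ref)
    report_b = _disc.apply_novelty_criteria(
        cands_b, codes_b, seqs_b, model, table, dconf
    )

    surv_a = cands_a.subset(report_a.surviving)
    surv_b = cands_b.subset(report_b.surviving)
    pairs, unmatched = _disc.cross_platform_validate(surv_a, surv_b)
    validated = cands_a.subset([a for a, _ in pairs])

    dbs = [(name, read_gtf(path)) for name, path in sorted(cfg.databases.items())]
    final = _disc.annotate_against_databases(validated, dbs)
    novel = cands_a.subset(final.novel)
    write_gtf(validated, os.path.join(outdir, "validated.gtf"))
    write_gtf(novel, os.path.join(outdir, "novel.gtf"))
    pd.DataFrame(
        sorted(final.previously_annotated.items()),
        columns=["transcript_id", "database"],
    ).to_csv(os.path.join(outdir, "previously_annotated.tsv"), sep="\t",
             index=False)

    report.stages["discover"] = {
        "candidates_a": len(cands_a),
        "candidates_b": len(cands_b),
        "prevalence_pass": len(a_prevalent),
        "criteria_pass": len(report_a.surviving),
        "criteria_pass_b": len(report_b.surviving),
        "validated": len(pairs),
        "previously_annotated": len(final.previously_annotated),
        "novel": len(final.novel),
    }
    return novel


def _conserve(cfg: RunConfig, outdir: str, report: RunReport,
              novel: AnnotationCatalog) -> None:
    ref = read_gtf(cfg.inputs["reference"])
    scored = AnnotationCatalog(list(ref))
    for t in novel:
        scored.add(TranscriptModel(
            transcript_id=f"NOVEL.{t.transcript_id}",
            gene_id=f"NOVEL.{t.transcript_id}",
            exons=list(t.exons), biotype="novel",
        ))
    track = _cons.read_score_track(cfg.inputs["conservation"])
    table = _cons.exon_mean_scores(scored, track)
    table.to_csv(os.path.join(outdir, "exon_conservation.tsv"), sep="\t",
                 index=False)
    profiles = _cons.class_profiles(table)
    profiles.to_csv(os.path.join(outdir, "conservation_profiles.tsv"),
                    sep="\t", index=False)
    payload = {"exons_scored": int(table["mean_score"].notna().sum())}
    for _, row in profiles.iterrows():
        payload[f"exons_{row['class']}"] = int(row["n_exons"])
        payload[f"median_{row['class']}"] = round(float(row["median"]), 4)
    report.stages["conserve"] = payload


def _de(cfg: RunConfig, outdir: str, report: RunReport) -> pd.DataFrame:
    tpm = pd.read_csv(cfg.inputs["tpm"], sep="\t", index_col=0)
    design = _expr.PairedDesign.from_table(
        pd.read_csv(cfg.inputs["design"], sep="\t")
    )
    biotypes = pd.read_csv(cfg.inputs["biotypes"], sep="\t", index_col=0)
    annotated = list(biotypes.index[biotypes["biotype"] != "novel"])
    result = _expr.paired_de_test(
        tpm, design, min_tpm=float(cfg.de.get("min_tpm", 0.5))
    )
    selected = _expr.de_select(
        result,
        annotated=annotated,
        max_adj_p=float(cfg.de.get("max_adj_p", 0.001)),
        min_abs_fc=float(cfg.de.get("min_abs_fc", 1.2)),
        min_tpm_fraction=float(cfg.de.get("min_tpm_fraction", 0.9)),
    )
    selected.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t",
                    index_label="feature_id")
    high = selected.index[selected["high_confidence"]]
    novel_set = set(biotypes.index[biotypes["biotype"] == "novel"])
    report.stages["de"] = {
        "features_tested": int(len(selected)),
        "high_confidence": int(len(high)),
        "high_confidence_novel": int(sum(f in novel_set for f in high)),
    }
    return selected


def _modules(cfg: RunConfig, outdir: str, report: RunReport,
             de_table: pd.DataFrame) -> pd.Series:
    tpm = pd.read_csv(cfg.inputs["tpm"], sep="\t", index_col=0)
    design = _expr.PairedDesign.from_table(
        pd.read_csv(cfg.inputs["design"], sep="\t")
    )
    biotypes = pd.read_csv(cfg.inputs["biotypes"], sep="\t", index_col=0)
    log_expr = np.log2(tpm + 1.0)

    beta = cfg.network.get("beta", 6)
    if beta == "auto":
        beta, _diag = _coex.pick_soft_threshold(log_expr)
    adj = _coex.adjacency(log_expr, int(beta))
    tom = _coex.topological_overlap(adj)
    assignment = _coex.detect_modules(
        tom, list(log_expr.index),
        min_size=int(cfg.network.get("min_module_size", 30)),
        cut_height=float(cfg.network.get("cut_height", 0.99)),
    )
    assignment.to_frame().to_csv(os.path.join(outdir, "modules.tsv"), sep="\t",
                                 index_label="feature_id")
    eigengenes = _coex.eigengene_matrix(log_expr, assignment)
    eigengenes.to_csv(os.path.join(outdir, "eigengenes.tsv"), sep="\t",
                      index_label="sample")
    trait = np.array(
        [1.0 if design.condition[s] == "post" else 0.0 for s in log_expr.columns]
    )
    trait_cor = _coex.module_trait_correlation(eigengenes, trait)
    trait_cor.to_csv(os.path.join(outdir, "module_trait.tsv"), sep="\t",
                     index=False)
    kme = _coex.module_membership(log_expr, eigengenes)
    kme.to_csv(os.path.join(outdir, "kme.tsv"), sep="\t",
               index_label="feature_id")

    de_set = set(de_table.index[de_table["high_confidence"]])
    lnc_set = set(biotypes.index[biotypes["biotype"] == "lncRNA"])
    hubs = _coex.hub_genes(
        kme, assignment,
        threshold=float(cfg.network.get("kme_threshold", 0.7)),
        restrict_to=de_set & lnc_set,
    )
    hubs.to_csv(os.path.join(outdir, "hub_lncrnas.tsv"), sep="\t", index=False)

    payload = {
        "n_modules": int(assignment.max()),
        "n_assigned": int((assignment > 0).sum()),
        "n_hub_lncrnas": int(len(hubs)),
    }
    for _, row in trait_cor.iterrows():
        payload[f"module{int(row['module'])}_trait_pcc"] = round(
            float(row["pcc"]), 3
        )
    report.stages["modules"] = payload
    return assignment


def _eqtl_stage(cfg: RunConfig, outdir: str, report: RunReport,
                novel: AnnotationCatalog, assignment: pd.Series) -> None:
    snps = _eqtl.read_snp_table(
        cfg.inputs["snps"], p_threshold=float(cfg.eqtl.get("p_threshold", 1e-8))
    )
    overlaps = _eqtl.overlap_exons_with_snps(novel, snps)
    overlaps.to_csv(os.path.join(outdir, "eqtl_overlaps.tsv"), sep="\t",
                    index=False)
    tpm = pd.read_csv(cfg.inputs["tpm"], sep="\t", index_col=0)
    log_expr = np.log2(tpm + 1.0)
    pairs = sorted(
        {(r.transcript_id, r.egene_id) for r in overlaps.itertuples(index=False)}
    )
    cor = _eqtl.lncrna_egene_correlation(log_expr, pairs, modules=assignment)
    cor.to_csv(os.path.join(outdir, "eqtl_correlations.tsv"), sep="\t",
               index=False)
    payload = {
        "snps_kept": len(snps),
        "overlaps": int(len(overlaps)),
        "pairs": int(len(pairs)),
    }
    for _, row in cor.iterrows():
        if not row["error"]:
            payload[f"pcc_{row['lncrna_id']}_{row['egene_id']}"] = round(
                float(row["pcc"]), 3
            )
    report.stages["eqtl"] = payload


STAGE_ORDER = ("discover", "conserve", "de", "modules", "eqtl")


def run_stages(cfg: RunConfig, outdir: str, stages) -> RunReport:
    """Run the named stages plus whatever upstream stages they depend on.

    conserve and eqtl need the novel set from discover; modules needs the
    DE table; eqtl also needs the module assignment.  The report covers
    every stage actually executed.
    """
    wanted = set(stages)
    unknown = wanted - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if wanted & {"conserve", "eqtl"}:
        wanted.add("discover")
    if wanted & {"modules", "eqtl"}:
        wanted.add("de")
    if "eqtl" in wanted:
        wanted.add("modules")
    return run_pipeline(cfg, outdir, only=wanted)


def run_pipeline(cfg: RunConfig, outdir: str, only=None) -> RunReport:
    """Run every stage; writes stage tables, report.json and report.txt.

    Raises :class:`StageError` naming the failing stage; outputs written
    before the failure are kept with a ``.partial`` marker file beside
    them.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(outdir, exist_ok=True)
    report = RunReport(config={
        "seed": cfg.seed,
        "discovery": cfg.discovery, "de": cfg.de,
        "network": cfg.network, "eqtl": cfg.eqtl,
    })
    active = set(STAGE_ORDER) if only is None else set(only)
    novel = de_table = assignment = None
    stage = "discover"
    try:
        if "discover" in active:
            novel = _discover(cfg, outdir, report)
        stage = "conserve"
        if "conserve" in active:
            _conserve(cfg, outdir, report, novel)
        stage = "de"
        if "de" in active:
            de_table = _de(cfg, outdir, report)
        stage = "modules"
        if "modules" in active:
            assignment = _modules(cfg, outdir, report, de_table)
        stage = "eqtl"
        if "eqtl" in active:
            _eqtl_stage(cfg, outdir, report, novel, assignment)
    except Exception as exc:
        with open(os.path.join(outdir, ".partial"), "w") as fh:
            fh.write(f"failed at stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc
    marker = os.path.join(outdir, ".partial")
    if os.path.exists(marker):
        os.remove(marker)
    report.to_json(os.path.join(outdir, "report.json"))
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write(report.to_text())
    return report
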