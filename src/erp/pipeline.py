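"""End-to-end orchestration: expression -> programs -> set statistics ->
regulatory modes -> target partition -> enrichment, with optional
footprint-pausing and polysome stages, driven by one config.

The run report is a single machine-readable JSON object; TSV outputs per
stage are derived artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    enrichment,
    expression,
    footprints,
    polysome,
    programs,
    regmode,
    setstats,
    synthetic,
    targetsets,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the analysis plus input paths (or synthetic mode)."""

    tpm_path: str | None = None
    meta_path: str | None = None
    sets_path: str | None = None       # GMT with annotation categories / target lists
    reads_path: str | None = None
    cds_path: str | None = None
    trace_path: str | None = None
    synthetic_seed: int | None = 42    # used when tpm_path is None
    min_avg_tpm: float = 2.0
    floor_tpm: float = 4.0
    fold_cutoff: float = 2.0
    mode_cutoff: float = 1.5
    scan_cutoffs: tuple = (1.3, 1.5, 1.7, 1.9, 2.1)
    pausing_window: int = 140
    target_timepoint: float = 8.0
    k_clusters: int = 3

    def __post_init__(self) -> None:
        for name in ("min_avg_tpm", "floor_tpm", "fold_cutoff", "mode_cutoff", "pausing_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scan_cutoffs" in raw:
            raw["scan_cutoffs"] = tuple(raw["scan_cutoffs"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_or_generate(cfg: RunConfig):
    if cfg.tpm_path:
        matrix = expression.load_expression(cfg.tpm_path, cfg.meta_path)
        truth = None
    else:
        matrix, truth = synthetic.generate_expression(
            synthetic.ExpressionConfig(seed=cfg.synthetic_seed or 0)
        )
    return matrix, truth


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Execute every stage; returns (and writes) the run report.

    Any stage failure raises StageError naming the stage; artifacts of
    completed stages are left in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()}}
    report["config"]["scan_cutoffs"] = list(cfg.scan_cutoffs)

    stage = "expression"
    try:
        raw, truth = _load_or_generate(cfg)
        floored = expression.filter_and_floor(raw, cfg.min_avg_tpm, cfg.floor_tpm)
        lfc_ribo = expression.compute_lfc(floored, "ribo")
        has_rna = any(s.assay == "rna" for s in floored.samples)
        lfc_rna = expression.compute_lfc(floored, "rna") if has_rna else None
        regulated = expression.select_regulated(lfc_ribo, "WT", cfg.fold_cutoff)
        lfc_ribo.to_tsv(out / "lfc_ribo.tsv")
        report["expression"] = {
            "n_genes_input": int(raw.values.shape[0]),
            "n_expressed": int(floored.values.shape[0]),
            "n_regulated_wt": len(regulated),
        }

        stage = "programs"
        wt_ribo_tpm = floored.subset(assay="ribo", genotype="WT").values.loc[sorted(regulated)]
        dist = programs.spearman_distance(wt_ribo_tpm)
        clusters = programs.hierarchical_cluster(dist, k=cfg.k_clusters)
        wt_lfc_frame = lfc_ribo.genotype_frame("WT")
        assignment = programs.assign_program_labels(clusters, wt_lfc_frame)
        assignment.table.to_csv(out / "program_assignments.tsv", sep="\t")
        medians = {}
        for prog in programs.PROGRAMS:
            direction = "repression" if prog == "repression" else "induction"
            genes = assignment.genes(prog)
            medians[prog] = {
                "WT": {
                    f"{t:g}h": programs.program_medians(wt_lfc_frame, genes, t, direction)
                    for t in lfc_ribo.timepoints("WT")
                }
            }
            if "KO" in {s.genotype for s in floored.samples}:
                ko_frame = lfc_ribo.genotype_frame("KO")
                medians[prog]["KO"] = {
                    f"{t:g}h": programs.program_medians(ko_frame, genes, t, direction)
                    for t in lfc_ribo.timepoints("KO")
                }
        report["programs"] = {"sizes": assignment.sizes, "median_percent": medians}
        if truth is not None:
            planted = truth.loc[truth["program"] != "background", "program"]
            common = planted.index.intersection(assignment.table.index)
            acc = float((assignment.table.loc[common, "program"] == planted[common]).mean())
            report["programs"]["recovery_accuracy"] = acc

        stage = "setstats"
        comparisons = []
        background = wt_lfc_frame
        for prog in programs.PROGRAMS:
            genes = sorted(assignment.genes(prog) & set(background.index))
            for t in lfc_ribo.timepoints("WT"):
                comp = setstats.group_vs_background(
                    background.loc[genes, t], background[t], set_name=prog, condition=f"WT_{t:g}h"
                )
                comparisons.append(vars(comp))
        pd.DataFrame(comparisons).to_csv(out / "set_comparisons.tsv", sep="\t", index=False)
        report["setstats"] = {"n_comparisons": len(comparisons)}

        stage = "regmode"
        if lfc_rna is not None:
            paired = pd.DataFrame(
                {
                    "lfc_rna": lfc_rna.genotype_frame("WT")[cfg.target_timepoint],
                    "lfc_ribo": wt_lfc_frame[cfg.target_timepoint],
                }
            ).dropna()
            calls = regmode.classify_table(paired, cfg.mode_cutoff)
            calls.to_csv(out / "regmode_calls.tsv", sep="\t")
            scan = regmode.scan_cutoffs(paired, cfg.scan_cutoffs)
            report["regmode"] = {
                "counts": {m: int((calls["mode"] == m).sum()) for m in regmode.MODES},
                "mrna_fraction_by_cutoff": {
                    f"{c:g}": (None if np.isnan(f) else float(f))
                    for c, f in scan.mrna_fraction.items()
                },
            }

        stage = "targetsets"
        if truth is not None:
            target_ids = frozenset(truth.index[truth["xbp1_atf6_class"] != "none"])
            target_set = setstats.GeneSet("xbp1_atf6_targets", target_ids) if target_ids else None
        elif cfg.sets_path:
            sets = targetsets.read_gmt(cfg.sets_path)
            target_set = sets.get("xbp1_atf6_targets")
        else:
            target_set = None
        if target_set is not None and lfc_rna is not None:
            expressed_targets = targetsets.filter_expressed_targets(
                target_set, raw, cfg.min_avg_tpm
            )
            wt8 = wt_lfc_frame[cfg.target_timepoint]
            ko8 = lfc_ribo.genotype_frame("KO")[cfg.target_timepoint]
            part = targetsets.partition_targets(
                expressed_targets, wt8, ko8, cfg.target_timepoint
            )
            tgt_in_lfc = [g for g in expressed_targets.gene_ids if g in wt8.index]
            report["targetsets"] = {
                "n_expressed_targets": len(expressed_targets),
                "counts": part.counts,
                "fraction_induced_wt": setstats.fraction_induced(wt8[tgt_in_lfc]),
                "fraction_induced_ko": setstats.fraction_induced(ko8[tgt_in_lfc]),
            }

        stage = "enrichment"
        background_set = setstats.GeneSet("expressed", frozenset(floored.gene_ids))
        if truth is not None:
            categories = {
                "er_targets": setstats.GeneSet(
                    "er_targets", frozenset(truth.index[truth["er_target"]])
                )
            }
        elif cfg.sets_path:
            categories = targetsets.read_gmt(cfg.sets_path)
        else:
            categories = None
        if categories:
            rep_genes = assignment.genes("repression")
            rep_set = setstats.GeneSet("repression_program", frozenset(rep_genes))
            enr = enrichment.fisher_enrichment(rep_set, categories, background_set)
            enr.to_csv(out / "enrichment.tsv", sep="\t")
            report["enrichment"] = {
                "n_categories": int(enr.shape[0]),
                "n_enriched": int(enr["enriched"].sum()),
                "top": enr.index[0],
            }

        stage = "footprints"
        if cfg.reads_path and cfg.cds_path:
            reads = footprints.read_records_tsv(cfg.reads_path)
            cds = pd.read_csv(cfg.cds_path, sep="\t", index_col=0)["cds_length"].to_dict()
            kept, _ = footprints.preprocess_reads(reads)
            profiles = footprints.clip_and_profile(kept, cds)
            scores = footprints.pausing_score(profiles, cfg.pausing_window)
            report["footprints"] = {
                "n_profiled": len(profiles),
                "median_pausing_ratio": float(scores.median()),
            }

        stage = "polysome"
        if cfg.trace_path:
            trace = polysome.PolysomeTrace.from_csv(cfg.trace_path)
            seg = polysome.segment_trace(trace)
            report["polysome"] = {"pm_ratio": polysome.pm_ratio(trace, seg)}
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        raise StageError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
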