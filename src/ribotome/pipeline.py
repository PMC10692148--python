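"""End-to-end orchestration: simulate/load -> normalize -> fit -> profile ->
filter -> gene-set statistics -> report.

Every artifact is a plain-text table under the run's output directory and
every number in the report is re-derivable from those tables.  A manifest
records the seed, thresholds, package/library versions and a sha256 per
emitted file; identical config and seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, io as rio
from .counts import (CountMatrix, build_design, estimate_dispersions,
                     estimate_size_factors, filter_low_counts, fit_nb_glm,
                     lrt_interaction, pca_variance)
from .enrichment import (EnrichmentProfile, Thresholds, acute_candidates,
                         call_sci_degs, compute_profile, summarize_geneset,
                         two_arm_filter, verdicts_with_screen)
from .genesets import marker_contamination_panel, operon_panel
from .qpcr import fold_change_table
from .simulate import SimConfig, SynthTruth, generate_experiment, \
    generate_qpcr, write_simulation

log = logging.getLogger("ribotome")


class ValidationError(ValueError):
    """Configuration problems detected before any stage runs."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class InputPaths:
    counts: str
    samples: str
    markers_gmt: Optional[str] = None
    operons_gmt: Optional[str] = None
    qpcr: Optional[str] = None


@dataclass
class RunConfig:
    """Exactly one of ``simulation`` / ``inputs`` must be set."""

    outdir: str
    simulation: Optional[SimConfig] = None
    inputs: Optional[InputPaths] = None
    conditions: List[str] = field(
        default_factory=lambda: ["naive", "dpi2", "dpi10", "dpi42"])
    thresholds: Thresholds = field(default_factory=Thresholds)
    pair_term: bool = True
    lrt_screen: bool = False
    min_count: int = 10
    pca_components: int = 3
    resample_R: int = 10
    seed: int = 0
    qpcr_refs: Optional[List[str]] = None

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError(
                "exactly one of simulation config and input paths must be set")
        if self.simulation is not None:
            self.simulation.validate()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    """In-memory handles plus the emitted manifest."""

    manifest: dict
    profile: EnrichmentProfile
    verdicts: pd.DataFrame
    counts: CountMatrix
    truth: Optional[SynthTruth] = None


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    created: List[str] = []
    artifacts: Dict[str, str] = {}

    def emit(name: str, writer) -> str:
        path = os.path.join(config.outdir, name)
        writer(path)
        created.append(path)
        artifacts[name] = path
        return path

    stage = "setup"
    t0 = time.time()
    try:
        # -- inputs -------------------------------------------------------
        stage = "inputs"
        log.info("[%s] t=%.1fs seed=%d", stage, time.time() - t0, config.seed)
        truth: Optional[SynthTruth] = None
        qpcr_plate = None
        marker_sets = operon_sets = None
        if config.simulation is not None:
            cm, truth = generate_experiment(config.simulation)
            conditions = list(config.simulation.conditions)
            paths = write_simulation(cm, truth, config.simulation,
                                     config.outdir)
            created.extend(paths.values())
            artifacts.update({os.path.basename(p): p for p in paths.values()})
            marker_sets = truth.marker_sets
            operon_sets = truth.operon_sets
            qpcr_plate = generate_qpcr(truth, config.simulation)
            qpcr_refs = truth.reference_genes
        else:
            inp = config.inputs
            counts_df = rio.read_counts_tsv(inp.counts)
            samples = rio.read_sample_sheet(inp.samples)
            conditions = list(config.conditions)
            cm = CountMatrix(counts_df, samples, conditions)
            if inp.markers_gmt:
                marker_sets = rio.read_gmt(inp.markers_gmt)
            if inp.operons_gmt:
                operon_sets = rio.read_gmt(inp.operons_gmt)
            if inp.qpcr:
                qpcr_plate = rio.read_qpcr_tsv(inp.qpcr)
            qpcr_refs = config.qpcr_refs

        # -- normalize / PCA ---------------------------------------------
        stage = "normalize"
        log.info("[%s] t=%.1fs seed=%d", stage, time.time() - t0, config.seed)
        cm_f = filter_low_counts(cm, config.min_count)
        sf = estimate_size_factors(cm_f)
        emit("size_factors.tsv", lambda p: rio.write_table(
            sf.factors.rename_axis("sample_id").reset_index(), p))
        pca = pca_variance(cm_f, sf, k=min(config.pca_components,
                                           cm_f.samples.shape[0]))
        emit("pca_variance.tsv", lambda p: rio.write_table(
            pca.variance_fraction.rename("variance_fraction")
            .rename_axis("component").reset_index(), p))
        emit("pca_scores.tsv", lambda p: rio.write_table(
            pca.scores.rename_axis("sample_id").reset_index(), p))

        # -- model fits ---------------------------------------------------
        stage = "fit"
        log.info("[%s] t=%.1fs genes=%d", stage, time.time() - t0,
                 len(cm_f.gene_ids))
        alpha = estimate_dispersions(cm_f, sf)
        full = build_design(cm_f.samples, conditions, interaction=True,
                            pair_term=config.pair_term)
        reduced = build_design(cm_f.samples, conditions, interaction=False,
                               pair_term=config.pair_term)
        fit_full = fit_nb_glm(cm_f, sf, alpha, full)
        fit_red = fit_nb_glm(cm_f, sf, alpha, reduced)
        fit_unp = None
        if config.pair_term:
            unpaired = build_design(cm_f.samples, conditions,
                                    interaction=True, pair_term=False)
            fit_unp = fit_nb_glm(cm_f, sf, alpha, unpaired)
        lrt = lrt_interaction(fit_full, fit_red)
        emit("lrt.tsv", lambda p: rio.write_table(
            lrt.rename_axis("gene_id").reset_index(), p))

        stage = "profile"
        profile = compute_profile(fit_full, conditions, lrt=lrt,
                                  fit_unpaired=fit_unp)
        for c in conditions:
            emit(f"enrichment_total_{c}.tsv", lambda p, c=c: rio.write_table(
                profile.total_enrichment[c].rename_axis("gene_id")
                .reset_index(), p))
            if c == conditions[0]:
                continue
            for label, store in (("delta", profile.delta),
                                 ("ip_vs_baseline", profile.ip_vs_baseline),
                                 ("total_vs_baseline",
                                  profile.total_vs_baseline)):
                emit(f"{label}_{c}.tsv", lambda p, c=c, s=store:
                     rio.write_table(s[c].rename_axis("gene_id")
                                     .reset_index(), p))

        # -- DEG calls and filtration ------------------------------------
        stage = "filter"
        log.info("[%s] t=%.1fs", stage, time.time() - t0)
        th = config.thresholds
        all_verdicts = []
        raw_lists: Dict[str, List[str]] = {}
        hc_lists: Dict[str, List[str]] = {}
        for c in conditions[1:]:
            degs = call_sci_degs(profile, th, c)
            for direction in ("up", "down"):
                name = f"deg_raw_{direction}_{c}.txt"
                emit(name, lambda p, d=degs[direction]:
                     rio.write_gene_list(sorted(d), p))
                raw_lists[f"{direction}_{c}"] = degs[direction]
            verdicts = two_arm_filter(degs, profile, th, c)
            if config.lrt_screen:
                verdicts = verdicts_with_screen(verdicts, profile, th)
            all_verdicts.append(verdicts)
            for direction in ("up", "down"):
                hc = sorted(verdicts.loc[
                    verdicts["high_confidence"]
                    & (verdicts["direction"] == direction), "gene_id"])
                emit(f"deg_highconf_{direction}_{c}.txt",
                     lambda p, d=hc: rio.write_gene_list(d, p))
                hc_lists[f"{direction}_{c}"] = hc
        verdicts = (pd.concat(all_verdicts, ignore_index=True)
                    if all_verdicts else pd.DataFrame())
        emit("verdicts.tsv", lambda p: rio.write_table(verdicts, p))

        if "dpi2" in conditions and "dpi42" in conditions:
            dpi2_v = verdicts[verdicts["timepoint"] == "dpi2"]
            acute = acute_candidates(dpi2_v, profile, th)
            emit("acute_candidates.txt",
                 lambda p: rio.write_gene_list(sorted(acute), p))

        # -- gene-set statistics ------------------------------------------
        stage = "genesets"
        log.info("[%s] t=%.1fs", stage, time.time() - t0)
        universe = list(cm_f.gene_ids)
        emit("universe.txt", lambda p: rio.write_gene_list(universe, p))
        if marker_sets:
            pre = marker_contamination_panel(
                {k: v for k, v in raw_lists.items() if k.startswith("up_")},
                marker_sets, universe, q_cut=th.q_cut)
            post = marker_contamination_panel(
                {k: v for k, v in hc_lists.items() if k.startswith("up_")},
                marker_sets, universe, q_cut=th.q_cut)
            emit("marker_panel_prefilter.tsv",
                 lambda p: rio.write_table(pre, p))
            emit("marker_panel_postfilter.tsv",
                 lambda p: rio.write_table(post, p))
        if operon_sets:
            focal = conditions[1] if len(conditions) > 1 else None
            query = hc_lists.get(f"up_{focal}", [])
            oz = operon_panel(query, operon_sets, universe,
                              R=config.resample_R, seed=config.seed)
            emit("operon_z.tsv", lambda p: rio.write_table(oz, p))
            summaries = []
            for name, members in operon_sets.items():
                for c in conditions[1:]:
                    s = summarize_geneset(members, profile, c,
                                          lfc_cut=th.enrich_lfc,
                                          q_cut=th.q_cut)
                    summaries.append({"geneset": name, "timepoint": c,
                                      **{k: v for k, v in s.items()
                                         if k != "per_gene"}})
            emit("geneset_summaries.tsv", lambda p: rio.write_table(
                pd.DataFrame(summaries), p))

        # -- qPCR ---------------------------------------------------------
        if qpcr_plate is not None and qpcr_refs:
            stage = "qpcr"
            log.info("[%s] t=%.1fs", stage, time.time() - t0)
            targets = sorted(set(qpcr_plate["target"]) - set(qpcr_refs))
            folds = fold_change_table(qpcr_plate, targets, qpcr_refs)
            emit("qpcr_folds.tsv", lambda p: rio.write_table(folds, p))

        # -- report and manifest -----------------------------------------
        stage = "report"
        manifest = {
            "ribotome_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "thresholds": dataclasses.asdict(config.thresholds),
            "conditions": conditions,
            "pair_term": config.pair_term,
            "lrt_screen": config.lrt_screen,
            "mode": "simulation" if config.simulation else "inputs",
            "n_genes_filtered": int(len(cm_f.gene_ids)),
            "files": {},
        }
        result = RunResult(manifest=manifest, profile=profile,
                           verdicts=verdicts, counts=cm_f, truth=truth)
        report = write_report(result, raw_lists, hc_lists, pca)
        emit("report.md", lambda p: open(p, "w").write(report))
        manifest["files"] = {name: _sha256(path)
                             for name, path in sorted(artifacts.items())}
        path = os.path.join(config.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        created.append(path)
        log.info("[done] t=%.1fs artifacts=%d", time.time() - t0, len(created))
        return result
    except Exception as exc:   # noqa: BLE001 - abort cleanly, remove partials
        for path in created:
            if os.path.exists(path):
                os.remove(path)
        if isinstance(exc, (ValidationError, StageError)):
            raise
        raise StageError(stage, exc) from exc


def filtration_metrics(verdicts: pd.DataFrame, truth: SynthTruth,
                       timepoint: str, min_true_lfc: float = 1.5) -> dict:
    """Planted-truth evaluation of the two-arm filter at one timepoint.

    ``contaminant_removal`` is the fraction of raw up-calls on planted
    inflammatory (non-OL) genes that the filter rejects;
    ``true_retention`` is the fraction of raw up-calls on genes with a
    planted OL effect >= ``min_true_lfc`` that survive it.
    """
    v = verdicts[(verdicts["timepoint"] == timepoint)
                 & (verdicts["direction"] == "up")]
    raw = set(v["gene_id"])
    hc = set(v.loc[v["high_confidence"], "gene_id"])
    contaminants = raw & set(truth.inflammatory_genes)
    true_up = raw & set(
        truth.true_lfc_ol.index[truth.true_lfc_ol[timepoint] >= min_true_lfc])
    removal = (len(contaminants - hc) / len(contaminants)
               if contaminants else float("nan"))
    retention = len(true_up & hc) / len(true_up) if true_up else float("nan")
    return {"timepoint": timepoint,
            "n_raw_up": len(raw),
            "n_contaminant_raw": len(contaminants),
            "n_true_raw": len(true_up),
            "contaminant_removal": removal,
            "true_retention": retention}


def write_report(result: RunResult, raw_lists: Dict[str, List[str]],
                 hc_lists: Dict[str, List[str]], pca) -> str:
    """Human-readable run summary; every number also lives in a TSV."""
    lines = ["# ribotome run report", ""]
    lines.append("## PCA variance fractions")
    for comp, frac in pca.variance_fraction.items():
        lines.append(f"- {comp}: {frac:.1%}")
    lines.append("")
    lines.append("## Injury DEGs before and after two-arm filtration")
    lines.append("| list | raw | high-confidence |")
    lines.append("|---|---|---|")
    for key in sorted(raw_lists):
        lines.append(f"| {key} | {len(raw_lists[key])} | "
                     f"{len(hc_lists.get(key, []))} |")
    lines.append("")
    if result.truth is not None and not result.verdicts.empty:
        lines.append("## Filtration versus planted truth")
        lines.append("| timepoint | raw up | contaminant removal | "
                     "true retention |")
        lines.append("|---|---|---|---|")
        for tp in sorted(result.verdicts["timepoint"].unique()):
            m = filtration_metrics(result.verdicts, result.truth, tp)
            lines.append(
                f"| {tp} | {m['n_raw_up']} | {m['contaminant_removal']:.1%} "
                f"| {m['true_retention']:.1%} |")
        lines.append("")
    return "\n".join(lines) + "\n"
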