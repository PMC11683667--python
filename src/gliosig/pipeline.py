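"""File-coupled pipeline: simulate → qc → annotate → signature → score →
refine → correlate → survive.

Stages exchange only files (the formats in :mod:`gliosig.io`), so any stage
can be replaced by an external tool's output — e.g. per-cell CNV flags from a
dedicated caller.  One global seed in the config derives a deterministic
per-stage stream; re-running a config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_mouse_tumor
from .errors import DependencyError
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RunConfig,
    read_counts,
    read_gmt,
    write_counts,
    write_gmt,
    write_variant_table,
)
from .qc import QCThresholds, apply_qc, lognormalize, normalize_bulk
from .scoring import iterative_ssgsea, pseudobulk, score_panel, ssgsea_scores
from .signature import (
    derive_signature,
    differential_expression,
    map_mouse_to_human,
    select_signature_populations,
)
from .simulate import (
    SimCohortSpec,
    SurvivalParams,
    simulate_bulk_cohort,
    simulate_gene_sets,
    simulate_sc_cohort,
    simulate_survival,
)
from .survival import correlation_panel, survival_comparison

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "annotate", "signature", "score", "refine", "correlate", "survive"]


@dataclass
class PipelineManifest:
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str], counts: dict[str, int], elapsed: float) -> None:
        self.stages.append(
            {"stage": stage, "outputs": outputs, "record_counts": counts, "elapsed_s": round(elapsed, 3)}
        )

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _outdir(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} requires missing upstream output {path}")
    return path


def stage_simulate(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    params = config.params
    spec = SimCohortSpec(seed=config.stage_seed("simulate"), species=config.species)
    for key in ("n_samples", "cells_per_sample", "n_genes"):
        if key in params:
            setattr(spec, key, int(params[key]))
    counts, truth, variants, arms = simulate_sc_cohort(spec)
    sets = simulate_gene_sets(spec)
    write_counts(counts, out / "counts.mtx", out / "genes.tsv", out / "barcodes.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    write_variant_table(variants, out / "variants.tsv")
    arms.to_csv(out / "gene_arms.tsv", sep="\t", index=False)
    write_gmt(sets, out / "gene_sets.gmt")

    # the bulk cohort's coherent genes are the human-mapped program genes;
    # the last quarter of the program is planted as non-transferring decoys
    mapped_program = [g.upper() for g in spec.program_genes]
    n_dec = max(1, len(mapped_program) // 4)
    bulk, candidate, latent = simulate_bulk_cohort(
        n_samples=int(params.get("bulk_samples", 60)),
        coherent_genes=mapped_program[:-n_dec],
        decoy_genes=mapped_program[-n_dec:],
        seed=config.stage_seed("simulate_bulk"),
    )
    write_counts(bulk, out / "bulk_counts.mtx", out / "bulk_genes.tsv", out / "bulk_samples.tsv")
    surv = simulate_survival(latent, SurvivalParams(), seed=config.stage_seed("simulate_survival"))
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    return {
        "counts": "counts.mtx",
        "truth": "truth.tsv",
        "variants": "variants.tsv",
        "gene_arms": "gene_arms.tsv",
        "gene_sets": "gene_sets.gmt",
        "bulk_counts": "bulk_counts.mtx",
        "survival": "survival.tsv",
    }


def stage_qc(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    counts = read_counts(
        _require(out / "counts.mtx", "qc"), out / "genes.tsv", out / "barcodes.tsv"
    )
    thresholds = QCThresholds.for_species(config.species)
    mito_prefix = "mt-" if config.species == "mouse" else "MT-"
    mito = [g.startswith(mito_prefix) for g in counts.gene_ids]
    filtered, report = apply_qc(counts, thresholds, mito)
    write_counts(filtered, out / "counts_qc.mtx", out / "genes_qc.tsv", out / "barcodes_qc.tsv")
    lognorm = lognormalize(filtered)
    write_counts(
        ExpressionMatrix(lognorm.values, lognorm.gene_ids, lognorm.obs_ids, mode="log_normalized"),
        out / "lognorm.mtx",
        out / "genes_qc.tsv",
        out / "barcodes_qc.tsv",
    )
    pd.DataFrame([report.removed_by | {
        "n_genes_in": report.n_genes_in,
        "n_genes_out": report.n_genes_out,
        "n_cells_in": report.n_cells_in,
        "n_cells_out": report.n_cells_out,
    }]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    return {"counts_qc": "counts_qc.mtx", "lognorm": "lognorm.mtx", "qc_report": "qc_report.tsv"}


def _read_lognorm(out: Path, stage: str) -> ExpressionMatrix:
    expr = read_counts(
        _require(out / "lognorm.mtx", stage), out / "genes_qc.tsv", out / "barcodes_qc.tsv"
    )
    return ExpressionMatrix(expr.values, expr.gene_ids, expr.obs_ids, mode="log_normalized")


def stage_annotate(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    lognorm = _read_lognorm(out, "annotate")
    counts = read_counts(out / "counts_qc.mtx", out / "genes_qc.tsv", out / "barcodes_qc.tsv")
    if config.species != "mouse":
        raise DependencyError("run-all demo annotates mouse-style cohorts; use the library API for human data")
    gfp = counts.gene_values("GFP") if "GFP" in counts.gene_ids else None
    calls = annotate_mouse_tumor(lognorm, gfp_counts=gfp)
    ann = pd.DataFrame({"cell_id": calls.index, "tumor_call": calls.to_numpy().astype(int)})
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    return {"annotation": "annotation.tsv"}


def stage_signature(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    counts = read_counts(_require(out / "counts_qc.mtx", "signature"), out / "genes_qc.tsv", out / "barcodes_qc.tsv")
    lognorm = _read_lognorm(out, "signature")
    truth = pd.read_csv(_require(out / "truth.tsv", "signature"), sep="\t")
    ann = pd.read_csv(_require(out / "annotation.tsv", "signature"), sep="\t")
    calls = pd.Series(ann["tumor_call"].astype(bool).to_numpy(), index=ann["cell_id"])
    cond = pd.Series(truth["condition"].to_numpy(), index=truth["cell_id"])
    group_a, group_b = select_signature_populations(counts, calls, cond)
    de = differential_expression(lognorm, group_a, group_b)
    de.table.to_csv(out / "de_table.tsv", sep="\t")
    sig = derive_signature(de)
    mapped, report = map_mouse_to_human(sig.genes)
    coll = GeneSetCollection([GeneSet("cd83_signature_human", mapped, "mapped signature")])
    write_gmt(coll, out / "cd83_signature.gmt")
    (out / "ortholog_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return {"de_table": "de_table.tsv", "signature": "cd83_signature.gmt"}


def stage_score(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    lognorm = _read_lognorm(out, "score")
    counts = read_counts(out / "counts_qc.mtx", out / "genes_qc.tsv", out / "barcodes_qc.tsv")
    sets = read_gmt(_require(out / "gene_sets.gmt", "score"))
    table = score_panel(lognorm, sets, method="module_score", seed=config.stage_seed("score"))
    table.scores.to_csv(out / "cell_scores.tsv", sep="\t")

    ann = pd.read_csv(_require(out / "annotation.tsv", "score"), sep="\t")
    truth = pd.read_csv(out / "truth.tsv", sep="\t")
    sample_of_cell = pd.Series(truth["sample_id"].to_numpy(), index=truth["cell_id"]).reindex(counts.obs_ids)
    mask = (
        pd.Series(ann["tumor_call"].astype(bool).to_numpy(), index=ann["cell_id"])
        .reindex(counts.obs_ids)
        .fillna(False)
        .to_numpy()
    )
    pb = pseudobulk(counts, sample_of_cell, mask)
    pb_norm = lognormalize(pb, target_sum=1e6)
    pb_scores = {s.name: ssgsea_scores(pb_norm, s) for s in sets}
    pd.DataFrame(pb_scores).to_csv(out / "pseudobulk_scores.tsv", sep="\t")
    return {"cell_scores": "cell_scores.tsv", "pseudobulk_scores": "pseudobulk_scores.tsv"}


def stage_correlate(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    pb = pd.read_csv(_require(out / "pseudobulk_scores.tsv", "correlate"), sep="\t", index_col=0)
    from .scoring import ScoreTable

    prog = pb["cd83_program"]
    panel = ScoreTable(pb.drop(columns=["cd83_program"]), method="ssgsea")
    res = correlation_panel(prog, panel)
    res.to_csv(out / "correlations.tsv", sep="\t", index=False)
    return {"correlations": "correlations.tsv"}


def stage_refine(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    bulk = read_counts(
        _require(out / "bulk_counts.mtx", "refine"), out / "bulk_genes.tsv", out / "bulk_samples.tsv"
    )
    norm = normalize_bulk(bulk)
    sig = read_gmt(_require(out / "cd83_signature.gmt", "refine"))["cd83_signature_human"]
    present = [g for g in sig.genes if g in set(norm.gene_ids)]
    # genes the mouse signature maps onto plus the cohort's candidate decoys
    candidate = GeneSet(sig.name, present or sig.genes, sig.description)
    refined, scores, trace = iterative_ssgsea(norm, candidate)
    write_gmt(GeneSetCollection([refined]), out / "cd83_signature_refined.gmt")
    scores.scores.to_csv(out / "bulk_scores.tsv", sep="\t")
    trace.rows.to_csv(out / "refinement_trace.tsv", sep="\t", index=False)
    return {
        "refined_signature": "cd83_signature_refined.gmt",
        "bulk_scores": "bulk_scores.tsv",
        "refinement_trace": "refinement_trace.tsv",
    }


def stage_survive(config: RunConfig) -> dict[str, str]:
    out = _outdir(config)
    scores = pd.read_csv(_require(out / "bulk_scores.tsv", "survive"), sep="\t", index_col=0).iloc[:, 0]
    surv = pd.read_csv(_require(out / "survival.tsv", "survive"), sep="\t")
    result = survival_comparison(scores, surv)
    result["strata"].rename("stratum").to_frame().to_csv(out / "strata.tsv", sep="\t")
    for lab, curve in result["curves"].items():
        pd.DataFrame(
            {
                "time": curve.times,
                "at_risk": curve.at_risk,
                "events": curve.events,
                "survival": curve.survival,
            }
        ).to_csv(out / f"km_{lab}.tsv", sep="\t", index=False)
    summary = {
        "chi_square": result["chi_square"],
        "p": result["p"],
        "medians": {k: (None if np.isnan(v) else v) for k, v in result["medians"].items()},
    }
    (out / "survival_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"strata": "strata.tsv", "survival_summary": "survival_summary.json"}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "annotate": stage_annotate,
    "signature": stage_signature,
    "score": stage_score,
    "refine": stage_refine,
    "correlate": stage_correlate,
    "survive": stage_survive,
}

# correlate depends on score outputs; refine on signature; survive on refine
STAGE_ORDER = ["simulate", "qc", "annotate", "signature", "score", "correlate", "refine", "survive"]


def run_pipeline(config: RunConfig) -> PipelineManifest:
    """Run every stage in dependency order and write the manifest last."""
    manifest = PipelineManifest(seed=config.seed)
    out = _outdir(config)
    config.to_json(out / "run_config.json")
    for stage in STAGE_ORDER:
        t0 = time.perf_counter()
        outputs = STAGE_FUNCS[stage](config)
        counts = {}
        for key, rel in outputs.items():
            path = out / rel
            if path.suffix == ".tsv":
                with open(path) as fh:
                    counts[key] = max(0, sum(1 for _ in fh) - 1)
        manifest.record(stage, outputs, counts, time.perf_counter() - t0)
        log.info("stage %s done in %.2fs", stage, manifest.stages[-1]["elapsed_s"])
    manifest.to_json(out / "manifest.json")
    return manifest
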