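"""End-to-end orchestration: synthetic cohort -> insertion calling ->
transduction attribution -> annotation -> cohort statistics -> clinical
models, with a run manifest recording config, content hashes and timing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import synthetic
from .annotation import annotate_insertions, derive_open_chromatin
from .calling import CallerParams, call_insertions
from .clinical import (fit_disease_specific_cox, fit_log_count_regression,
                       score_cimp)
from .stats import (colocalize_with_ai_breakpoints, fragile_site_fractions,
                    rank_uniformity_expression_test, tally_recurrent_genes)
from .transduction import (merge_dedupe_calls, summarize_source_activity,
                           transduction_pipeline)

log = logging.getLogger(__name__)

STAGES = ("simulate", "call", "transduce", "annotate", "stats", "clinical")


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the shipped profile."""

    outdir: str = "retrocall_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synthetic: synthetic.SyntheticConfig | None = None
    caller: CallerParams = field(default_factory=CallerParams)
    n_perm: int = 10_000
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and self.synthetic is None:
            first = next(s for s in STAGES if s in self.stages)
            raise ValueError(
                f"stage '{first}' enabled without its input: provide a "
                "synthetic config or enable the simulate stage")


@dataclass
class RunManifest:
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute the enabled stages in order and write all artifacts.

    Returns the manifest and a dict of in-memory results keyed by stage.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = config.synthetic or synthetic.SyntheticConfig(seed=config.seed)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["synthetic"] = dataclasses.asdict(scfg)
    manifest = RunManifest(config=cfg_dict)
    results: dict = {}

    def timed(stage):
        t0 = time.perf_counter()
        def done():
            manifest.stage_seconds[stage] = round(
                time.perf_counter() - t0, 3)
        return done

    done = timed("simulate")
    cohort = synthetic.simulate_cohort(scfg)
    if "simulate" in config.stages:
        synthetic.write_cohort(cohort, out / "cohort")
    manifest.hashes["cohort"] = cohort.content_hash()
    results["cohort"] = cohort
    done()

    calls = None
    if "call" in config.stages:
        done = timed("call")
        calls = call_insertions(
            cohort.tumor_pairs, cohort.normal_pairs, cohort.panel_calls,
            cohort.annotation.decoy_contigs, config.caller)
        rio.write_table(calls, out / "candidates.tsv", "candidates")
        rio.write_bed(calls, out / "candidates.bed", start="window_start",
                      end="window_end", name="family", score="pos_support")
        manifest.hashes["candidates"] = _hash_df(calls)
        results["calls"] = calls
        log.info("called %d somatic insertions", len(calls))
        done()

    tcalls = None
    if "transduce" in config.stages:
        done = timed("transduce")
        sex = cohort.clinical.set_index("sample")["sex"].to_dict()
        from .calling import select_anchor_reads
        site_ev = select_anchor_reads(cohort.tumor_pairs)
        tcalls = transduction_pipeline(
            cohort.tumor_svs, cohort.normal_svs, cohort.annotation.l1hs,
            cohort.panel_calls, sex, site_ev)
        rio.write_table(tcalls.assign(
            ambiguous_source=tcalls["ambiguous_source"]),
            out / "transductions.tsv", "transductions")
        summary = summarize_source_activity(tcalls)
        summary.to_csv(out / "source_activity.tsv", sep="\t", index=False)
        manifest.hashes["transductions"] = _hash_df(tcalls)
        results["transductions"] = tcalls
        results["source_activity"] = summary
        done()

    unified = annotated = None
    if "annotate" in config.stages:
        done = timed("annotate")
        if calls is None or tcalls is None:
            raise ValueError("annotate requires call + transduce stages")
        unified = merge_dedupe_calls(tcalls, calls)
        chromatin = derive_open_chromatin(
            cohort.annotation.dnase, cohort.annotation.callable_regions)
        annotated = annotate_insertions(
            unified, cohort.split_reads, cohort.annotation.genes,
            cohort.annotation.exons, cohort.annotation.replication,
            chromatin)
        rio.write_table(annotated, out / "insertions.tsv", "insertions")
        manifest.hashes["insertions"] = _hash_df(annotated)
        results["insertions"] = annotated
        done()

    if "stats" in config.stages:
        done = timed("stats")
        if annotated is None:
            raise ValueError("stats requires the annotate stage")
        gene_tally = tally_recurrent_genes(
            annotated, cohort.annotation.genes, tpm=cohort.tpm)
        gene_tally.to_csv(out / "gene_tally.tsv", sep="\t", index=False)
        frag = cohort.annotation.genes[cohort.annotation.genes["fragile"]]
        frag_summary = fragile_site_fractions(
            annotated, cohort.ai_events, frag)
        frag_summary.to_csv(out / "fragile_sites.tsv", sep="\t",
                            index=False)
        coloc = colocalize_with_ai_breakpoints(annotated, cohort.ai_events)
        carriers = annotated[annotated["nearest_gene"] != ""][
            ["sample", "nearest_gene"]].rename(
                columns={"nearest_gene": "gene_id"})
        stat = p = None
        try:
            stat, p, _ = rank_uniformity_expression_test(
                cohort.tpm, carriers, n_perm=config.n_perm,
                seed=config.seed + 1)
        except ValueError:
            log.warning("expression rank test skipped (no usable data)")
        (out / "expression_test.json").write_text(json.dumps({
            "statistic": stat, "p": p, "n_perm": config.n_perm,
            "seed": config.seed + 1}, indent=2))
        results["gene_tally"] = gene_tally
        results["fragile_sites"] = frag_summary
        results["ai_colocalization"] = coloc
        results["expression_test"] = {"statistic": stat, "p": p}
        done()

    if "clinical" in config.stages:
        done = timed("clinical")
        cimp_classes, _ = score_cimp(cohort.methylation)
        clin = cohort.clinical.copy()
        clin["cimp_scored"] = clin["sample"].map(cimp_classes)
        reg = fit_log_count_regression(clin)
        cox = fit_disease_specific_cox(clin)
        report = {
            "cimp_agreement": float(
                (clin["cimp_scored"] == clin["cimp"]).mean()),
            "regression": reg.summary().to_dict(orient="records"),
            "regression_gof_p": reg.gof_p,
            "cox": cox.summary().to_dict(orient="records"),
        }
        (out / "clinical_models.json").write_text(
            json.dumps(report, indent=2))
        results["regression"] = reg
        results["cox"] = cox
        results["cimp_scored"] = cimp_classes
        done()

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest, results
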