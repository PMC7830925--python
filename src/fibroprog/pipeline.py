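"""Stage orchestration: simulate → de → enrich → compare → gem, with a
machine-readable run manifest and cross-model summary tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

import fibroprog
from fibroprog import compare as cmp
from fibroprog import gem as gemmod
from fibroprog.config import PipelineConfig
from fibroprog.diffexpr import (
    ExpressionStudy,
    run_differential_expression,
    write_deg_table,
)
from fibroprog.enrichment import (
    read_gmt,
    run_set_enrichment,
    write_enrichment_table,
)
from fibroprog.simulate import (
    SimulationConfig,
    simulate_gene_sets,
    simulate_studies,
    toy_metabolic_model,
    write_panel,
)

log = logging.getLogger("fibroprog")


def _load_studies(config: PipelineConfig, outdir: Path) -> list[ExpressionStudy]:
    if config.expression:
        sheets = config.sample_sheets or []
        if len(sheets) != len(config.expression):
            raise ValueError("need one sample sheet per expression matrix")
        return [
            ExpressionStudy.from_tsv(e, s)
            for e, s in zip(config.expression, sheets)
        ]
    expr_files = sorted(outdir.glob("expression_*.tsv"))
    if not expr_files:
        raise FileNotFoundError(
            f"no expression matrices configured and none found under {outdir}"
        )
    studies = []
    for expr in expr_files:
        label = expr.stem.removeprefix("expression_")
        studies.append(
            ExpressionStudy.from_tsv(expr, outdir / f"samples_{label}.tsv", label)
        )
    return studies


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns a manifest dict (also written to ``outdir/manifest.json``);
    outputs are deterministic for a fixed seed.
    """
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "fibroprog",
        "version": fibroprog.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages_run": [],
        "outputs": [],
    }

    def record(*paths: Path) -> None:
        manifest["outputs"] += [str(p) for p in paths]

    studies: list[ExpressionStudy] | None = None
    de_tables: dict[str, pd.DataFrame] = {}
    set_tables: dict[str, pd.DataFrame] = {}

    if "simulate" in config.stages:
        log.info("stage simulate: generating synthetic panel")
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        studies, truth = simulate_studies(sim)
        raw_sets = simulate_gene_sets(sim, truth)
        model = toy_metabolic_model(truth)
        write_panel(studies, truth, raw_sets, model, outdir)
        record(*sorted(outdir.glob("expression_*.tsv")),
               *sorted(outdir.glob("samples_*.tsv")),
               outdir / "gene_sets.gmt", outdir / "toy_gem.json",
               outdir / "ground_truth.json")
        manifest["stages_run"].append("simulate")

    if {"de", "enrich", "compare", "gem"} & set(config.stages):
        if studies is None:
            studies = _load_studies(config, outdir)

    if "de" in config.stages:
        for study in studies:
            log.info("stage de: %s", study.model_label)
            table = run_differential_expression(study, alpha=config.alpha)
            de_tables[study.model_label] = table
            path = outdir / f"degs_{study.model_label}.tsv"
            write_deg_table(table, path, study.model_label)
            record(path)
        manifest["stages_run"].append("de")

    if "enrich" in config.stages:
        gmt_path = config.gene_sets or outdir / "gene_sets.gmt"
        raw_sets = read_gmt(gmt_path)
        provenance = "custom"
        for study in studies:
            log.info("stage enrich: %s", study.model_label)
            table = run_set_enrichment(
                study, raw_sets, min_size=config.min_set_size,
                provenance=provenance, alpha=config.alpha,
            )
            set_tables[study.model_label] = table
            path = outdir / f"enrichment_{study.model_label}_{provenance}.tsv"
            write_enrichment_table(table, path, study.model_label, provenance)
            record(path)
        manifest["stages_run"].append("enrich")

    if "compare" in config.stages:
        log.info("stage compare")
        if not de_tables:
            raise RuntimeError("compare stage requires the de stage")
        gene_part = cmp.partition(de_tables)
        if len(gene_part.models) >= 2:
            for direction, sets in (("up", gene_part.up), ("down", gene_part.down)):
                venn = cmp.venn_counts(sets)
                path = outdir / f"venn_{direction}.tsv"
                cmp.write_venn_table(venn, path, direction)
                record(path)
            pair = cmp.similarity_matrices(gene_part)
            cmp.write_similarity(pair, outdir, prefix="similarity")
            record(outdir / "similarity_pos.tsv", outdir / "similarity_neg.tsv")
        if set_tables:
            set_part = cmp.partition(set_tables)
            if len(set_part.models) >= 2:
                set_pair = cmp.similarity_matrices(set_part)
                cmp.write_similarity(set_pair, outdir, prefix="similarity_sets")
                record(outdir / "similarity_sets_pos.tsv",
                       outdir / "similarity_sets_neg.tsv")
            summary = summarize(set_tables, min_models=config.min_models)
            for name, table in summary.items():
                path = outdir / f"summary_{name}.tsv"
                table.to_csv(path, sep="\t")
                record(path)
            if config.reference_table:
                reference = cmp.read_sign_reference(config.reference_table)
                for label, table in set_tables.items():
                    overlap, counts = cmp.reference_sign_overlap(table, reference)
                    path = outdir / f"reference_overlap_{label}.tsv"
                    with open(path, "w") as fh:
                        fh.write(f"# reference sign concordance, model={label}; "
                                 + ", ".join(f"{k}={v}" for k, v in counts.items())
                                 + "\n")
                        overlap.to_csv(fh, sep="\t", index=False)
                    record(path)
        # common-program gene counts across all models
        common_up = set.intersection(*gene_part.up.values()) if gene_part.up else set()
        common_down = (
            set.intersection(*gene_part.down.values()) if gene_part.down else set()
        )
        path = outdir / "common_genes.tsv"
        with open(path, "w") as fh:
            fh.write("# genes significant in the same direction in all models\n")
            fh.write("direction\tcount\tgenes\n")
            fh.write(f"up\t{len(common_up)}\t{','.join(sorted(common_up))}\n")
            fh.write(f"down\t{len(common_down)}\t{','.join(sorted(common_down))}\n")
        record(path)
        manifest["stages_run"].append("compare")

    if "gem" in config.stages:
        model_path = config.gem_model or outdir / "toy_gem.json"
        model = gemmod.parse_model(model_path)
        if not de_tables:
            raise RuntimeError("gem stage requires the de stage")
        for label, table in de_tables.items():
            log.info("stage gem: %s", label)
            analysis = gemmod.run_gem_integration(
                model, table, alpha=config.alpha, f=config.objective_fraction,
                w_max=config.w_max, eps=config.capacity_eps,
            )
            paths = gemmod.write_gem_tables(analysis, model, outdir, label)
            record(*paths)
        manifest["stages_run"].append("gem")

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def summarize(
    set_tables: dict[str, pd.DataFrame], min_models: int = 3
) -> dict[str, pd.DataFrame]:
    """Wide set × model tables of enrichment estimates.

    ``sets_wide`` masks non-significant entries to NaN; ``sets_common``
    keeps only sets significant (any direction) in at least ``min_models``
    models.
    """
    est = pd.DataFrame({m: t["est"] for m, t in set_tables.items()})
    sig = pd.DataFrame({m: t["direction"] != "ns" for m, t in set_tables.items()})
    sig = sig.fillna(False)
    wide = est.where(sig)
    n_sig = sig.sum(axis=1)
    common = wide.loc[n_sig >= min_models]
    return {"sets_wide": wide, "sets_common": common}
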