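"""Pipeline orchestration: one config in, a directory of stage outputs + manifest out.

Stage order follows the analysis flow: simulate (or load inputs) ->
consensus -> specificity -> biogenesis -> enrich -> associate.  Partial
pipelines are allowed (any prefix-closed subset of stages that satisfies
data dependencies).  Every run writes ``manifest.json`` with the config
hash, seed, stage parameters and SHA-256 checksums of all outputs; two
runs with identical manifests produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import association, biogenesis, consensus, enrichment, simulate, specificity
from .core import CircMatrix, ConfigurationError, PanelMeta, PipelineError, logger
from .reporting import build_manifest, write_manifest
from .simulate import PanelConfig, ToolProfile, read_panel_inputs, simulate_panel

ALL_STAGES = ("simulate", "consensus", "specificity", "biogenesis", "enrich", "associate")

DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "consensus": {"min_tools": 2, "min_reads": 2, "scale": 1e6, "threshold": "per_tool"},
    "specificity": {"cutoff": 0.5, "ubiquity_min": 15},
    "biogenesis": {"rs_min": 0.3, "q_max": 0.05, "min_lines": 10, "n_candidates": 100},
    "enrich": {
        "covariate": "gene_length",
        "n_perm": 1000,
        "statistic": "circ_gene_rate",
        "background": "all",
        "background_min_samples": enrichment.BACKGROUND_MIN_SAMPLES,
    },
    "associate": {
        "grouping": "median",
        "kind": "drug_auc",
        "min_prevalence": 5,
        "min_group": 3,
        "q_max": 0.05,
        "bh_scope": "screen",
    },
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a YAML mapping")
    return cfg


def panel_config_from_dict(d: dict, default_seed: int = 0) -> PanelConfig:
    d = dict(d or {})
    d.setdefault("seed", default_seed)
    if "tools" in d:
        d["tools"] = tuple(
            ToolProfile(**t) if isinstance(t, dict) else t for t in d["tools"]
        )
    valid = {f.name for f in dataclasses.fields(PanelConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulate parameters: {sorted(unknown)}")
    return PanelConfig(**d)


def _stage_params(config: dict, stage: str) -> dict:
    params = dict(DEFAULT_PARAMS.get(stage, {}))
    params.update(config.get(stage) or {})
    return params


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the configured stages; return in-memory results and output paths."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    results: dict[str, Any] = {}
    outputs: dict[str, Path] = {}
    inputs: dict[str, Path] = {}
    stage_params_used: dict[str, dict] = {}

    # --- inputs: simulate or load ------------------------------------------
    data: dict[str, Any] = {}
    if "simulate" in stages:
        try:
            pcfg = panel_config_from_dict(config.get("simulate", {}), default_seed=seed)
            panel = simulate_panel(pcfg)
            paths = panel.write(outdir / "panel")
            outputs.update({f"panel/{k}": p for k, p in paths.items()})
            stage_params_used["simulate"] = dataclasses.asdict(pcfg)
            data = {
                "tool_calls": panel.tool_calls,
                "expression": panel.expression,
                "zscores": panel.zscores,
                "lineage_of": panel.lineage_of,
                "library_size": panel.library_size,
                "annotation": panel.annotation,
                "gene_of_circ": panel.gene_of_circ,
                "drug_auc": panel.drug_auc,
                "mutations": panel.mutations,
                "truth": panel.truth,
            }
            results["panel"] = panel
        except PipelineError as exc:
            raise PipelineError(f"stage simulate: {exc}") from exc
    elif config.get("inputs", {}).get("dir"):
        indir = Path(config["inputs"]["dir"])
        try:
            data = read_panel_inputs(indir)
        except (OSError, KeyError) as exc:
            raise ConfigurationError(f"loading inputs from {indir}: {exc}") from exc
        inputs.update({p.name: p for p in sorted(indir.glob("*.tsv"))})
    elif set(stages) - {"simulate"}:
        raise ConfigurationError("config needs either a 'simulate' stage or inputs.dir")

    meta = PanelMeta(
        lineage_of=dict(data.get("lineage_of", {})),
        library_size=dict(data.get("library_size", {})),
        gene_of_circ=dict(data.get("gene_of_circ", {})),
    )
    results["meta"] = meta

    matrix: CircMatrix | None = None

    def _require(stage: str, condition: bool, what: str) -> None:
        if not condition:
            raise ConfigurationError(f"stage {stage}: missing dependency ({what})")

    for stage in stages:
        if stage == "simulate":
            continue
        params = _stage_params(config, stage)
        stage_params_used[stage] = params
        logger.info("stage %s: %s", stage, params)
        try:
            if stage == "consensus":
                _require(stage, "tool_calls" in data, "tool calls")
                merged = consensus.merge_calls(
                    data["tool_calls"],
                    min_tools=params["min_tools"],
                    min_reads=params["min_reads"],
                    threshold=params["threshold"],
                )
                meta.validate_cell_lines(sorted(set(data["tool_calls"]["cell_line"])))
                matrix = consensus.normalize_reads(
                    merged, meta, scale=params["scale"],
                    cell_lines=sorted(meta.library_size),
                )
                summary = consensus.per_line_summary(matrix, meta)
                matrix.to_tsv(outdir / "circ_matrix.tsv")
                summary.to_csv(outdir / "per_line_summary.tsv", sep="\t")
                outputs["circ_matrix"] = outdir / "circ_matrix.tsv"
                outputs["per_line_summary"] = outdir / "per_line_summary.tsv"
                results["consensus"] = merged
                results["matrix"] = matrix
                results["per_line_summary"] = summary

            elif stage == "specificity":
                _require(stage, matrix is not None, "consensus matrix")
                _require(stage, "expression" in data, "expression matrix")
                spec = specificity.call_specific_genes(
                    data["expression"], meta, cutoff=params["cutoff"]
                )
                breadth = specificity.classify_breadth(
                    matrix, meta, ubiquity_min=params["ubiquity_min"]
                )
                overlap = specificity.specific_overlap_fraction(breadth, spec, meta)
                spec.to_csv(outdir / "specific_genes.tsv", sep="\t", index=False)
                breadth.to_csv(outdir / "breadth.tsv", sep="\t")
                overlap.to_csv(outdir / "overlap_fractions.tsv", sep="\t", index=False)
                outputs["specific_genes"] = outdir / "specific_genes.tsv"
                outputs["breadth"] = outdir / "breadth.tsv"
                outputs["overlap_fractions"] = outdir / "overlap_fractions.tsv"
                results.update(
                    {"specific_genes": spec, "breadth": breadth, "overlap": overlap}
                )

            elif stage == "biogenesis":
                _require(stage, matrix is not None, "consensus matrix")
                _require(stage, "expression" in data, "expression matrix")
                load = consensus.total_backsplice_load(matrix)
                candidates = params.get("candidate_genes")
                if not candidates:
                    candidates = _default_candidates(data, params["n_candidates"])
                corr = biogenesis.correlate_regulators(
                    data["expression"], load, candidates,
                    rs_min=params["rs_min"], q_max=params["q_max"],
                )
                per_lin = biogenesis.per_lineage_correlations(
                    data["expression"], load, meta, candidates,
                    rs_min=params["rs_min"], q_max=params["q_max"],
                    min_lines=params["min_lines"],
                )
                groups = biogenesis.split_high_low(load)
                corr.to_csv(outdir / "regulator_correlations.tsv", sep="\t", index=False)
                per_lin.to_csv(outdir / "regulator_correlations_per_lineage.tsv", sep="\t", index=False)
                groups.rename("group").to_csv(outdir / "load_groups.tsv", sep="\t", index_label="cell_line")
                outputs["regulator_correlations"] = outdir / "regulator_correlations.tsv"
                outputs["regulator_correlations_per_lineage"] = outdir / "regulator_correlations_per_lineage.tsv"
                outputs["load_groups"] = outdir / "load_groups.tsv"
                if "zscores" in data:
                    try:
                        scores = biogenesis.emt_score(data["zscores"])
                        scores.rename("emt_score").to_csv(
                            outdir / "emt_scores.tsv", sep="\t", index_label="cell_line"
                        )
                        outputs["emt_scores"] = outdir / "emt_scores.tsv"
                        results["emt_scores"] = scores
                    except ConfigurationError as exc:
                        logger.warning("EMT scores skipped: %s", exc)
                if "expression" in data:
                    gct, cls = biogenesis.export_gsea_inputs(
                        data["expression"], groups, outdir / "gsea_input"
                    )
                    outputs["gsea_gct"], outputs["gsea_cls"] = gct, cls
                results.update(
                    {"regulator_correlations": corr, "per_lineage_correlations": per_lin,
                     "load": load, "load_groups": groups}
                )

            elif stage == "enrich":
                _require(stage, matrix is not None, "consensus matrix")
                _require(stage, "annotation" in data, "gene annotation")
                ann = data["annotation"]
                focal = sorted(ann.index[ann["actionable"]])
                if params["background"] == "all":
                    background = sorted(set(ann.index) - set(focal))
                elif params["background"] == "circ_min_samples":
                    background = enrichment.rate_background(
                        matrix, meta, list(ann.index), focal,
                        min_samples=params["background_min_samples"],
                    )
                else:
                    raise ConfigurationError(
                        f"unknown background mode {params['background']!r}"
                    )
                if params["statistic"] == "circ_gene_rate":
                    stat = enrichment.make_rate_statistic(matrix, meta)
                elif params["statistic"] == "median_rbp_peaks":
                    stat = enrichment.make_rbp_statistic(ann)
                else:
                    raise ConfigurationError(
                        f"unknown statistic {params['statistic']!r}"
                    )
                res = enrichment.matched_permutation(
                    focal, background, ann, params["covariate"], stat,
                    n_perm=params["n_perm"], seed=seed,
                )
                res.to_frame().to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                pd.Series(res.permuted, name="permuted_statistic").to_csv(
                    outdir / "enrichment_permuted.tsv", sep="\t", index=False
                )
                outputs["enrichment"] = outdir / "enrichment.tsv"
                outputs["enrichment_permuted"] = outdir / "enrichment_permuted.tsv"
                results["enrichment"] = res

            elif stage == "associate":
                _require(stage, matrix is not None, "consensus matrix")
                kind = params["kind"]
                source = {
                    "drug_auc": "drug_auc", "mrna": "expression",
                    "protein": "protein", "mutation": "mutations",
                }.get(kind)
                _require(stage, source in data, f"{kind} feature matrix")
                features = association.FeatureMatrix(kind, data[source])
                records = association.association_screen(
                    matrix, features,
                    grouping=params["grouping"],
                    min_prevalence=params["min_prevalence"],
                    min_group=params["min_group"],
                    q_max=params["q_max"],
                    bh_scope=params["bh_scope"],
                )
                summary = association.summarize_per_feature(records)
                records.to_csv(outdir / "associations.tsv", sep="\t", index=False)
                summary.to_csv(outdir / "association_summary.tsv", sep="\t", index=False)
                outputs["associations"] = outdir / "associations.tsv"
                outputs["association_summary"] = outdir / "association_summary.tsv"
                results["associations"] = records
                results["association_summary"] = summary
        except PipelineError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = build_manifest(
        config=config, seed=seed, stage_params=stage_params_used,
        input_files=inputs, output_files=outputs,
    )
    write_manifest(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    results["outputs"] = outputs
    return results


def _default_candidates(data: dict, n_candidates: int) -> list[str]:
    """Candidate regulator list when none is configured.

    With a truth table available: planted regulators plus the first null
    genes (deterministic); otherwise the first ``n_candidates`` genes of
    the expression matrix.
    """
    genes = list(data["expression"].index)
    truth = data.get("truth")
    if truth is not None:
        reg = list(truth.genes.loc[truth.genes["regulator_effect"] != 0, "gene"])
        nulls = [g for g in genes if g not in set(reg)]
        return reg + nulls[: max(0, n_candidates - len(reg))]
    return genes[:n_candidates]
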