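"""End-to-end orchestration: filter -> log-CPM -> covariate screen ->
surrogate variables -> moderated DE -> covariate-corrected co-expression
network -> modules, eigengenes, robustness -> module/hub/gene-set
enrichments, with per-stage TSV outputs and a deterministic JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, coexpression, diffexpr, enrichment, io, preprocess
from .coexpression import GREY
from .simulate import (
    ConfigurationError,
    CovariateEffect,
    DESpec,
    ModuleSpec,
    SimulationConfig,
    default_paper_like_config,
    simulate_dataset,
    write_truth,
)

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class PipelineConfig:
    """Single configuration object housing every stage's parameters."""

    simulate: SimulationConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    negative_control_set: str | None = "Height"

    cpm_threshold: float = 1.0
    max_low_samples: int = 10
    covariates: list[str] = field(default_factory=lambda: list(preprocess.DEFAULT_COVARIATES))
    screening_alpha: float = 0.01
    voom_span: float = 0.5
    prior_count: float = 0.5
    prior_df: float | str = "auto"
    nominal_alpha: float = 0.05
    use_sva: bool = True
    sva_n_perm: int = 100

    beta: int | str = 9
    min_module_size: int = 30
    cut_height: float | None = None
    hub_fraction: float = 0.10
    robustness_n_splits: int = 20
    robustness_n_perm: int = 100
    edge_connectivity_threshold: float = 3.0

    seed: int = 0
    output_dir: str = "out"


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (crc32 fan-out, kept below 2**31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _config_errors(raw: dict[str, Any]) -> list[str]:
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown configuration keys: {sorted(unknown)}")
    has_paths = any(
        raw.get(k) for k in ("counts_path", "metadata_path", "annotation_path")
    )
    if raw.get("simulate") is not None and has_paths:
        errors.append("configure either simulate or input paths, not both")
    if raw.get("simulate") is None and not has_paths:
        errors.append("one of simulate or input paths is required")
    if has_paths:
        for k in ("counts_path", "metadata_path", "annotation_path"):
            if not raw.get(k):
                errors.append(f"{k} is required when running from files")
    sim = raw.get("simulate")
    if isinstance(sim, dict):
        unknown_sim = set(sim) - _SIM_FIELDS
        if unknown_sim:
            errors.append(f"unknown simulate keys: {sorted(unknown_sim)}")
    hub = raw.get("hub_fraction", 0.10)
    if not (isinstance(hub, (int, float)) and 0 < hub <= 1):
        errors.append("hub_fraction must be in (0, 1]")
    alpha = raw.get("nominal_alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha <= 1):
        errors.append("nominal_alpha must be in (0, 1]")
    beta = raw.get("beta", 9)
    if not (beta == "auto" or (isinstance(beta, int) and beta >= 1)):
        errors.append("beta must be a positive integer or 'auto'")
    mms = raw.get("min_module_size", 30)
    if not (isinstance(mms, int) and mms >= 2):
        errors.append("min_module_size must be an integer >= 2")
    span = raw.get("voom_span", 0.5)
    if not (isinstance(span, (int, float)) and 0 < span <= 1):
        errors.append("voom_span must be in (0, 1]")
    return errors


def _parse_simulate(sim: dict[str, Any] | None) -> SimulationConfig | None:
    if sim is None:
        return None
    if sim == "default" or sim == {}:
        return default_paper_like_config()
    sim = dict(sim)
    if "module_spec" in sim:
        sim["module_spec"] = [ModuleSpec(**m) for m in sim["module_spec"]]
    if "de_spec" in sim:
        sim["de_spec"] = DESpec(**sim["de_spec"])
    if "covariate_effects" in sim:
        sim["covariate_effects"] = {
            k: CovariateEffect(**v) for k, v in sim["covariate_effects"].items()
        }
    if "library_size_range" in sim:
        sim["library_size_range"] = tuple(sim["library_size_range"])
    return SimulationConfig(**sim)


def validate_config(source: str | Path | dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from YAML (path) or a dict, reporting every
    validation problem at once."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if raw.get("simulate") == "default":
        raw["simulate"] = dataclasses.asdict(default_paper_like_config())
    errors = _config_errors(raw)
    if errors:
        raise ConfigurationError("; ".join(errors))
    raw["simulate"] = _parse_simulate(raw.get("simulate"))
    if raw["simulate"] is not None:
        raw["simulate"].validate()
    config = PipelineConfig(**raw)
    return config


@dataclass
class PipelineReport:
    """Paths, summaries and the manifest produced by a run."""

    output_dir: Path
    summary: dict[str, Any]
    manifest: dict[str, Any]

    @property
    def manifest_path(self) -> Path:
        return self.output_dir / "manifest.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage, writing stage TSVs plus ``manifest.json`` and a
    plain-text ``summary.txt``. Re-running with the same config and seed is
    byte-identical."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "neuronet",
        "version": __version__,
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stages": [],
    }
    summary: dict[str, Any] = {}

    def record(stage: str, outputs: dict[str, Path], **info: Any) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
                **info,
            }
        )
        logger.info("stage %-18s %s", stage, {k: str(v) for k, v in info.items()})

    t0 = time.time()

    # ----- inputs -----------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(
            config.simulate, seed=stage_seed(config.seed, "simulate")
        )
        counts, meta, anno, truth = simulate_dataset(sim)
        io.write_counts(counts, out / "counts.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_annotation(anno, out / "annotation.tsv")
        write_truth(truth, out / "truth.tsv")
        record(
            "simulate",
            {
                "counts.tsv": out / "counts.tsv",
                "metadata.tsv": out / "metadata.tsv",
                "annotation.tsv": out / "annotation.tsv",
                "truth.tsv": out / "truth.tsv",
            },
            n_genes=counts.shape[0],
            n_samples=counts.shape[1],
        )
    else:
        counts = io.read_counts(config.counts_path)
        meta = io.read_metadata(config.metadata_path)
        anno = io.read_annotation(config.annotation_path)
    counts, meta, anno = io.align_inputs(counts, meta, anno)

    # ----- filter + transform ----------------------------------------
    filtered = preprocess.filter_low_expression(
        counts, config.cpm_threshold, config.max_low_samples
    )
    io.write_counts(filtered, out / "counts_filtered.tsv")
    expr = preprocess.log_cpm(filtered, prior_count=config.prior_count)
    expr.logcpm.round(6).rename_axis("gene_id").to_csv(out / "logcpm.tsv", sep="\t")
    record(
        "filter",
        {"counts_filtered.tsv": out / "counts_filtered.tsv", "logcpm.tsv": out / "logcpm.tsv"},
        n_genes_in=counts.shape[0],
        n_genes_kept=filtered.shape[0],
    )
    summary["n_genes_input"] = counts.shape[0]
    summary["n_genes_after_filter"] = filtered.shape[0]
    summary["n_samples"] = filtered.shape[1]

    # ----- covariate screen ------------------------------------------
    screen = preprocess.screen_covariates(
        expr, meta, alpha=config.screening_alpha, covariates=config.covariates
    )
    screen = preprocess.variance_fractions(
        expr, meta, covariates=config.covariates, result=screen
    )
    screen.summary().round(6).to_csv(out / "covariate_screen.tsv", sep="\t", index=False)
    record(
        "covariate_screen",
        {"covariate_screen.tsv": out / "covariate_screen.tsv"},
        widespread=sorted(c for c, w in screen.widespread.items() if w),
    )
    summary["widespread_covariates"] = sorted(
        c for c, w in screen.widespread.items() if w
    )

    # ----- surrogate variables + DE ----------------------------------
    design = preprocess.build_design(meta, config.covariates, include_status=True)
    if config.use_sva:
        sva = preprocess.estimate_surrogate_variables(
            expr,
            design,
            n_perm=config.sva_n_perm,
            seed=stage_seed(config.seed, "sva"),
        )
        sva.sv_matrix.round(8).rename_axis("sample_id").to_csv(
            out / "surrogate_variables.tsv", sep="\t"
        )
        record(
            "sva",
            {"surrogate_variables.tsv": out / "surrogate_variables.tsv"},
            n_sv=sva.n_sv,
        )
        summary["n_surrogate_variables"] = sva.n_sv
        if sva.n_sv:
            design = pd.concat(
                [design, sva.sv_matrix.set_axis(design.index, axis=0)], axis=1
            )

    weighted = diffexpr.voom_weights(
        filtered, design, span=config.voom_span, prior_count=config.prior_count
    )
    de = diffexpr.moderated_fit(
        weighted,
        design,
        coef="status",
        prior_df=config.prior_df,
        nominal_alpha=config.nominal_alpha,
    )
    biotype = anno.set_index("gene_id")
    de_table = de.table.copy()
    de_table.insert(0, "symbol", biotype["symbol"].reindex(de_table.index))
    de_table.insert(1, "biotype", biotype["biotype"].reindex(de_table.index))
    de_table.round(6).rename_axis("gene_id").to_csv(out / "de_table.tsv", sep="\t")
    composition = diffexpr.signature_composition(de, anno, alpha=config.nominal_alpha)
    composition.round(6).to_csv(out / "de_composition.tsv", sep="\t", index=False)
    record(
        "diffexpr",
        {"de_table.tsv": out / "de_table.tsv", "de_composition.tsv": out / "de_composition.tsv"},
        n_significant=int(de.table["significant"].sum()),
        prior_df=_fmt_float(de.prior_df),
    )
    summary["n_de_nominal"] = int(de.table["significant"].sum())
    summary["n_de_bh"] = int((de.table["bh_fdr"] < 0.05).sum())

    # ----- co-expression network -------------------------------------
    corrected = preprocess.residualize(expr, meta, covariates=config.covariates)
    if config.beta == "auto":
        sft = coexpression.pick_soft_threshold(corrected)
        beta = sft.chosen_beta
        sft.table.round(6).to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
        record("soft_threshold", {"soft_threshold.tsv": out / "soft_threshold.tsv"}, beta=beta)
    else:
        beta = int(config.beta)
    summary["beta"] = beta
    net = coexpression.adjacency_matrix(corrected, beta=beta)
    net = coexpression.tom_matrix(net)
    assignment = coexpression.cut_modules(
        net,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
        hub_fraction=config.hub_fraction,
    )
    module_table = pd.DataFrame(
        {
            "module": assignment.module_of_gene,
            "kim": assignment.kim.round(6),
            "hub": assignment.hub_flag,
        }
    )
    module_table.rename_axis("gene_id").to_csv(out / "modules.tsv", sep="\t")
    record(
        "modules",
        {"modules.tsv": out / "modules.tsv"},
        n_modules=len(assignment.modules),
        n_grey=assignment.module_sizes.get(GREY, 0),
    )
    summary["n_modules"] = len(assignment.modules)
    summary["module_sizes"] = {
        m: assignment.module_sizes[m] for m in assignment.modules
    }

    # ----- eigengenes, robustness, status association ----------------
    summaries: dict[str, coexpression.ModuleSummary] = {}
    for m in assignment.modules:
        summaries[m] = coexpression.module_eigengene(corrected, assignment, m)
    if summaries:
        eig_df = pd.DataFrame(
            {m: s.eigengene for m, s in summaries.items()}
        )
        eig_df.round(8).rename_axis("sample_id").to_csv(out / "eigengenes.tsv", sep="\t")
    robustness = coexpression.module_robustness(
        corrected,
        assignment,
        beta=beta,
        n_splits=config.robustness_n_splits,
        n_perm=config.robustness_n_perm,
        seed=stage_seed(config.seed, "robustness"),
    )
    de_enrich = enrichment.module_de_enrichment(assignment, de)
    # over-represented only: a module can also pass Bonferroni by depletion,
    # which is not a status-module candidate
    enriched = {
        r.name for r in de_enrich if (r.corrected_p or 1.0) < 0.05 and r.odds_ratio > 1
    }
    status_modules = []
    rows = []
    for m in assignment.modules:
        s = summaries[m]
        s.robustness_z = robustness.get(m)
        if m in enriched:
            coexpression.eigengene_status_association(s, meta)
            if (s.kw_pvalue or 1.0) < 0.05:
                status_modules.append(m)
        res = next(r for r in de_enrich if r.name == m)
        rows.append(
            {
                "module": m,
                "size": assignment.module_sizes[m],
                "variance_explained": round(s.variance_explained, 6),
                "robustness_z": round(s.robustness_z, 4) if s.robustness_z is not None else "",
                "de_enrichment_or": round(res.odds_ratio, 4),
                "de_enrichment_p": res.pvalue,
                "de_enrichment_bonferroni": res.corrected_p,
                "kw_statistic": round(s.kw_statistic, 6) if s.kw_statistic is not None else "",
                "kw_pvalue": s.kw_pvalue if s.kw_pvalue is not None else "",
                "status_associated": m in status_modules,
            }
        )
    module_summary = pd.DataFrame(rows)
    module_summary.to_csv(out / "module_summary.tsv", sep="\t", index=False)
    outputs = {"module_summary.tsv": out / "module_summary.tsv"}
    if summaries:
        outputs["eigengenes.tsv"] = out / "eigengenes.tsv"
    record("module_summary", outputs, status_modules=status_modules)
    summary["status_modules"] = status_modules

    # ----- hub enrichment + edges ------------------------------------
    if status_modules:
        target = status_modules[0]
        hub_res = enrichment.hub_de_enrichment(assignment, de, target)
        enrichment.enrichment_report([hub_res], target=target).to_csv(
            out / "hub_enrichment.tsv", sep="\t", index=False
        )
        record("hub_enrichment", {"hub_enrichment.tsv": out / "hub_enrichment.tsv"})
        edges = _edge_list(net, assignment, target, config.edge_connectivity_threshold)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        record("edges", {"edges.tsv": out / "edges.tsv"}, n_edges=len(edges))

    # ----- user gene-set enrichments ---------------------------------
    if config.gene_sets and status_modules:
        target = status_modules[0]
        symbols = io.symbols_for(assignment.members(target), anno)
        background = io.symbols_for(assignment.module_of_gene.index, anno)
        reports = []
        for coll_name, gmt_path in sorted(config.gene_sets.items()):
            coll = io.read_gmt(gmt_path)
            res = enrichment.geneset_enrichment(
                symbols, coll, background, negative_control=config.negative_control_set
            )
            rep = enrichment.enrichment_report(res, target=target)
            rep.insert(0, "collection", coll_name)
            reports.append(rep)
        pd.concat(reports).to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
        record(
            "geneset_enrichment",
            {"geneset_enrichment.tsv": out / "geneset_enrichment.tsv"},
        )

    # ----- manifest + summary ----------------------------------------
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    lines = ["neuronet pipeline summary", "=" * 25]
    for k, v in summary.items():
        lines.append(f"{k}: {v}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return PipelineReport(output_dir=out, summary=summary, manifest=manifest)


def _edge_list(
    net: coexpression.NetworkModel,
    assignment: coexpression.ModuleAssignment,
    module: str,
    k_threshold: float,
) -> pd.DataFrame:
    """TOM edge list among members of a module whose whole-network
    connectivity exceeds ``k_threshold`` (for visualization)."""
    genes = np.asarray(net.gene_ids)
    pos = {g: i for i, g in enumerate(genes)}
    members = [g for g in assignment.members(module) if net.connectivity[pos[g]] > k_threshold]
    rows = []
    tom = net.tom
    for i, ga in enumerate(members):
        for gb in members[i + 1 :]:
            rows.append(
                {"gene_a": ga, "gene_b": gb, "tom": round(float(tom[pos[ga], pos[gb]]), 8)}
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom"])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
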