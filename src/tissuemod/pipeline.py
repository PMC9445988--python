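"""End-to-end pipeline runner on a simulated two-disease study.

Stage order: simulate (two cohorts, A and B) -> per-dataset DEG +
confounder screen -> per-tissue merge + empirical-Bayes batch adjustment
-> cross-tissue matrix -> per-disease network, modules and hub-gene screen
-> cross-disease consensus -> RRA per tissue -> GWAS window mapping ->
tissue-specific gene calls and shared genes -> ORA against the planted-
module GMT.  Every output is a text table under the run directory, and a
provenance JSON records the config, seed and per-file checksums.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import batch, consensus, deg, gwas, io, network, rra, simulate, specificity
from .config import PipelineConfig
from .dataset import MergedTissueMatrix

log = logging.getLogger("tissuemod")

__version__ = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def deg_stage(datasets, config: PipelineConfig):
    """Normalise, test, screen: returns (deg tables, DEG sets, excluded genes)."""
    tables, sets, excluded = {}, {}, set()
    for ds in datasets:
        normalised = deg.log2_normalise(ds)
        table = deg.differential_expression(normalised, covariates=config.covariates)
        report = deg.confounder_screen(normalised, config.confounders,
                                       alpha=config.confounder_alpha)
        tables[ds.name] = table
        sets[ds.name] = deg.select_degs(table, alpha=config.deg_alpha)
        excluded |= report.excluded_genes
    return tables, sets, excluded


def integration_stage(datasets, deg_sets: dict, config: PipelineConfig) -> MergedTissueMatrix:
    """Merge per tissue over the global DEG union, adjust batches, combine."""
    global_degs: set = set()
    for s in deg_sets.values():
        global_degs |= s
    by_tissue: dict = {}
    for ds in datasets:
        by_tissue.setdefault(ds.tissue, []).append(deg.log2_normalise(ds))
    adjusted = []
    for tissue in sorted(by_tissue):
        merged = batch.merge_tissue(by_tissue[tissue], [global_degs],
                                    case_only=config.case_only)
        model = batch.fit_empirical_bayes_batch(merged)
        adjusted.append(batch.apply_batch_adjustment(merged, model))
    return batch.combine_tissues(adjusted, mode=config.combine_mode)


def network_stage(matrix: MergedTissueMatrix, config: PipelineConfig):
    """Soft power, TOM, modules, eigengenes, module-tissue correlation."""
    X = matrix.expr
    if config.power_override is not None:
        beta, scan = config.power_override, None
    else:
        scan = network.scan_soft_thresholds(X, powers=config.powers,
                                            fit_target=config.fit_target,
                                            signed=config.signed_network)
        beta = network.recommended_power(scan)
    net = network.build_network(X, beta, signed=config.signed_network)
    modules = network.detect_modules(net, cut_height=config.cut_height,
                                     min_module_size=config.min_module_size)
    modules = network.merge_similar_modules(X, modules, merge_cut=config.merge_cut)
    modules = network.module_tissue_correlation(
        X, modules, matrix.tissue_labels, r_min=config.module_r,
        alpha=config.module_alpha)
    screened = network.screen_module_genes(modules, gs_min=config.gs_min,
                                           kme_min=config.kme_min)
    return net, modules, screened, scan


def rra_stage(deg_tables: dict, datasets, config: PipelineConfig) -> set:
    """Robust DEGs: RRA per tissue over that tissue's per-dataset DEG
    lists (each list holds only the dataset's p < deg_alpha genes, so a
    gene missing from a list simply was not a DEG there), both directions;
    the robust set is the union of significant genes."""
    tissue_of = {ds.name: ds.tissue for ds in datasets}
    by_tissue: dict = {}
    for name, table in deg_tables.items():
        degs = table[table["p"] < config.deg_alpha]
        if len(degs):
            by_tissue.setdefault(tissue_of[name], {})[name] = degs
    robust: set = set()
    for tissue in sorted(by_tissue):
        result = rra.aggregate_directions(by_tissue[tissue], alpha=config.rra_alpha)
        robust |= rra.significant_genes(result)
    return robust


def network_matrix_from_bundle(datasets, case_only: bool = True) -> MergedTissueMatrix:
    """Merge and batch-adjust each tissue over the full gene panel, then
    combine into the cross-tissue matrix (no DEG filter).

    This is the standard desk-scale path for studying module recovery on a
    synthetic bundle, where every planted gene should be allowed into the
    network.
    """
    by_tissue: dict = {}
    for ds in datasets:
        by_tissue.setdefault(ds.tissue, []).append(deg.log2_normalise(ds))
    all_genes = set(datasets[0].expr.index)
    adjusted = []
    for tissue in sorted(by_tissue):
        merged = batch.merge_tissue(by_tissue[tissue], [all_genes],
                                    case_only=case_only)
        model = batch.fit_empirical_bayes_batch(merged)
        adjusted.append(batch.apply_batch_adjustment(merged, model))
    return batch.combine_tissues(adjusted, mode="union")


def _disease_run(datasets, truth, config: PipelineConfig):
    deg_tables, deg_sets, excluded = deg_stage(datasets, config)
    matrix = integration_stage(datasets, deg_sets, config)
    net, modules, screened, scan = network_stage(matrix, config)
    robust = rra_stage(deg_tables, datasets, config)
    return {
        "deg_tables": deg_tables, "deg_sets": deg_sets, "excluded": excluded,
        "matrix": matrix, "network": net, "modules": modules,
        "screened": screened, "scan": scan, "robust": robust, "truth": truth,
    }


def run_pipeline(config: PipelineConfig, out_dir,
                 sim_config: simulate.SimulationConfig | None = None) -> Path:
    """Execute every stage on a simulated two-disease study; returns the run
    directory.  On failure, partial outputs are moved under ``failed/`` and
    a StageError naming the stage is raised."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        base = sim_config or simulate.SimulationConfig()
        runs = {}
        for disease, tag in (("A", "disease_a"), ("B", "disease_b")):
            sim_cfg = simulate.config_with(base, seed=config.stage_seed(tag))
            datasets, truth = simulate.simulate_study(sim_cfg)
            variants, bed = simulate.simulate_gwas_fixture(
                truth, window_hits=10, decoys=5,
                seed=config.stage_seed(tag + "_gwas"))
            simulate.write_fixture_bundle(datasets, truth, out / f"bundle_{disease}",
                                          variants=variants, bed=bed,
                                          seed=sim_cfg.seed)
            runs[disease] = {"datasets": datasets, "truth": truth,
                             "variants": variants, "bed": bed}

        for disease in ("A", "B"):
            stage = f"analysis_{disease}"
            r = runs[disease]
            r.update(_disease_run(r["datasets"], r["truth"], config))
            stage = f"gwas_{disease}"
            variants = gwas.dedupe_variants(r["variants"])
            gwas_genes, hits = gwas.map_variants_to_genes(
                variants, r["bed"], window=config.gwas_window)
            r["gwas_genes"], r["gwas_hits"] = gwas_genes, hits
            stage = f"calls_{disease}"
            r["calls"] = specificity.call_tissue_specific_genes(
                r["screened"], r["robust"], gwas_genes, r["excluded"],
                require_both=config.evidence_require_both)

        stage = "consensus"
        a, b = runs["A"], runs["B"]
        shared = sorted(set(a["matrix"].expr.index) & set(b["matrix"].expr.index))
        cons_out = {}
        if len(shared) >= config.min_module_size:
            beta = config.power_override or 6
            net_a = network.build_network(a["matrix"].expr.loc[shared], beta,
                                          signed=config.signed_network)
            net_b = network.build_network(b["matrix"].expr.loc[shared], beta,
                                          signed=config.signed_network)
            # reference = input with the larger q-quantile
            qa = consensus._offdiag_quantile(net_a.tom, config.quantile)
            qb = consensus._offdiag_quantile(net_b.tom, config.quantile)
            ref, tgt = (net_a.tom, net_b.tom) if qa >= qb else (net_b.tom, net_a.tom)
            pair = consensus.scale_tom(ref, tgt, q=config.quantile)
            ctom = consensus.consensus_tom(pair)
            cnet = network.CoexpressionNetwork(
                genes=pd.Index(shared, name="gene"), beta=beta,
                adjacency=np.minimum(net_a.adjacency, net_b.adjacency), tom=ctom)
            cmods = network.detect_modules(cnet, cut_height=config.cut_height,
                                           min_module_size=config.min_module_size)
            tables = {}
            for disease, r in runs.items():
                ms = network.module_tissue_correlation(
                    r["matrix"].expr.loc[shared],
                    network.ModuleSet(labels=cmods.labels),
                    r["matrix"].tissue_labels,
                    r_min=config.module_r, alpha=config.module_alpha)
                tables[disease] = consensus.correlation_long_table(ms)
            merged_table = consensus.merge_correlation_tables(
                tables["A"], tables["B"], r_min=config.module_r,
                alpha=config.module_alpha)
            cons_out = {"labels": cmods.labels, "table": merged_table,
                        "exponent": pair.exponent,
                        "quantiles": {"reference": pair.quantile_reference,
                                      "target_before": pair.quantile_target_before}}

        stage = "report"
        shared_calls = specificity.shared_genes(a["calls"], b["calls"])
        for disease, r in runs.items():
            prefix = out / f"disease_{disease}"
            prefix.mkdir(exist_ok=True)
            for name, table in r["deg_tables"].items():
                io.write_table(table, prefix / f"deg_{name}.tsv")
            io.write_table(r["matrix"].expr, prefix / "matrix.tsv")
            io.write_table(r["modules"].labels.to_frame(), prefix / "modules.tsv")
            io.write_table(r["modules"].me, prefix / "ME.tsv")
            long = consensus.correlation_long_table(r["modules"])
            io.write_table(long, prefix / "module_tissue_cor.tsv", index=False)
            if r["scan"] is not None:
                io.write_table(r["scan"], prefix / "soft_threshold_scan.tsv", index=False)
            io.write_table(r["screened"], prefix / "screened_genes.tsv", index=False)
            io.write_table(r["gwas_hits"], prefix / "gwas_hits.tsv", index=False)
            io.write_table(r["calls"], prefix / "tissue_specific_genes.tsv", index=False)
            io.write_table(specificity.summarise_calls(r["calls"]),
                           prefix / "call_summary.tsv", index=False)
            gmt = io.read_gmt(out / f"bundle_{disease}" / "planted_modules.gmt")
            universe = set(r["matrix"].expr.index)
            called = set(r["calls"]["gene"]) & universe
            if called:
                io.write_table(specificity.over_representation(called, gmt, universe),
                               prefix / "ora.tsv", index=False)
        io.write_table(shared_calls, out / "shared_tissue_specific_genes.tsv",
                       index=False)
        if cons_out:
            io.write_table(cons_out["labels"].to_frame(), out / "consensus_modules.tsv")
            io.write_table(cons_out["table"], out / "consensus_cor.tsv", index=False)
            io.write_json({"exponent": cons_out["exponent"],
                           "quantile": config.quantile,
                           "quantiles": cons_out["quantiles"]},
                          out / "scaling_report.json")

        stage = "provenance"
        files = sorted(p for p in out.rglob("*") if p.is_file()
                       and p.name != "provenance.json")
        io.write_json(
            {
                "config": config.to_dict(),
                "seed": config.seed,
                "version": __version__,
                "checksums": {str(p.relative_to(out)): _checksum(p) for p in files},
            },
            out / "provenance.json",
        )
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for child in list(out.iterdir()):
            if child.name != "failed":
                shutil.move(str(child), failed / child.name)
        raise StageError(stage, exc) from exc
    return out
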