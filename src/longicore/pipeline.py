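"""End-to-end discovery pipeline: filter -> network -> modules -> trait
selection -> hubs -> random forest -> core-genus intersection.

`run_discovery` wires the stage functions together under one seed and one
config, returns an in-memory report, and optionally writes every stage table
as a self-describing TSV (header comments carry the seed and config) plus a
machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from longicore.abundance_io import AbundanceTable, aggregate_rank, relative_abundance
from longicore.coexpression_network import (
    GREY,
    ModulePartition,
    ModuleTraitResult,
    NetworkConfig,
    SoftThresholdReport,
    adjacency,
    detect_modules,
    mad_filter,
    merge_modules,
    module_trait,
    pick_soft_threshold,
    tom_similarity,
    transform_counts,
)
from longicore.hub_mining import export_module_network, hub_genera, top_hubs, write_network
from longicore.rf_screen import core_intersection, rf_importances, top_k
from longicore.strain_scoring import score_strains

logger = logging.getLogger("longicore")


@dataclass
class PipelineConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    trait: str = "longevity"
    alpha: float = 0.05
    hub_k: int = 10
    rf_top_k: int = 10
    rf_trees: int = 500
    rf_max_depth: int = 7
    weight_threshold: float | None = None   # None = density-controlled export
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.network.validate()


@dataclass
class ModuleFinding:
    """Everything the pipeline learned about one significant module."""

    module: str
    r: float
    p: float
    n_nodes: int
    n_edges: int
    network: object          # hub_mining.WeightedNetwork
    hub_table: pd.DataFrame
    hub_genus_list: list[str]
    rf_table: pd.DataFrame
    top_perm: list[str]
    top_imp: list[str]
    core_genera: list[str]


@dataclass
class RunReport:
    chosen_power: float
    soft_threshold: pd.DataFrame
    partition: ModulePartition
    module_sizes: pd.Series
    trait_result: ModuleTraitResult
    selected: pd.DataFrame
    findings: list[ModuleFinding]
    seed: int

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "chosen_power": self.chosen_power,
            "n_modules": int((self.module_sizes.index != GREY).sum()),
            "module_sizes": {str(k): int(v) for k, v in self.module_sizes.items()},
            "selected_modules": [
                {"module": row["module"], "r": row["r"], "p": row["p"]}
                for _, row in self.selected.iterrows()
            ],
            "findings": [
                {
                    "module": f.module,
                    "n_nodes": f.n_nodes,
                    "n_edges": f.n_edges,
                    "hub_genera": f.hub_genus_list,
                    "rf_top_perm": f.top_perm,
                    "rf_top_impurity": f.top_imp,
                    "core_genera": f.core_genera,
                }
                for f in self.findings
            ],
        }


def run_discovery(table: AbundanceTable, traits: pd.DataFrame,
                  config: PipelineConfig | None = None,
                  out_dir=None) -> RunReport:
    """Run the whole discovery chain on an abundance + trait table pair."""
    config = config or PipelineConfig()
    config.validate()
    traits = traits.loc[table.counts.index]
    if config.trait not in traits.columns:
        raise ValueError(f"trait {config.trait!r} absent from trait table")

    logger.info("transform + MAD filter (%s OTUs in)", table.n_otus)
    matrix = transform_counts(table.counts, config.network.transform)
    matrix = mad_filter(matrix, config.network.mad_keep_fraction)
    # zero-variance profiles cannot enter a correlation network
    keep = matrix.std(axis=0) > 0
    matrix = matrix.loc[:, keep]
    logger.info("%d OTUs retained", matrix.shape[1])

    st = pick_soft_threshold(matrix, config.network)
    logger.info("soft threshold beta = %s", st.chosen_power)
    adj = adjacency(matrix, st.chosen_power, config.network.network_type,
                    config.network.correlation)
    tom = tom_similarity(adj)
    diss = 1.0 - tom

    partition = detect_modules(matrix, diss, config.network)
    partition = merge_modules(partition, matrix, config.network.merge_cut)
    sizes = partition.sizes()
    logger.info("modules: %s", dict(sizes))

    trait_df = traits[[config.trait]].astype(float)
    result = module_trait(matrix, partition, trait_df)
    selected = result.significant_modules(config.trait, config.alpha)
    if selected.empty:
        logger.warning("no module passed alpha = %s", config.alpha)

    genus_annotation = table.rank_labels("genus")
    genus_table = aggregate_rank(table, "genus")
    genus_rel = relative_abundance(genus_table)
    labels = traits[config.trait].astype(int).to_numpy()

    findings = []
    for _, row in selected.iterrows():
        module = row["module"]
        net = export_module_network(
            tom, partition, module,
            weight_threshold=config.weight_threshold,
            genus_annotation=genus_annotation,
        )
        hubs = top_hubs(net, k=config.hub_k)
        hub_gen = hub_genera(hubs)

        module_genera = sorted(
            {g for g in genus_annotation.loc[partition.members(module)] if g}
        )
        feat_cols = [g for g in genus_rel.columns if g in module_genera]
        if len(feat_cols) < 2:
            logger.warning("module %s: too few annotated genera for RF", module)
            continue
        report = rf_importances(
            genus_rel[feat_cols], labels,
            n_trees=config.rf_trees, max_depth=config.rf_max_depth,
            seed=config.seed,
        )
        tp = top_k(report, config.rf_top_k, "perm")
        ti = top_k(report, config.rf_top_k, "impurity")
        core = core_intersection(hub_gen, tp, ti)
        logger.info("module %s: core genera %s", module, core)
        findings.append(
            ModuleFinding(
                module=module, r=float(row["r"]), p=float(row["p"]),
                n_nodes=len(net.nodes), n_edges=net.n_edges,
                network=net,
                hub_table=hubs, hub_genus_list=hub_gen,
                rf_table=report.table, top_perm=tp, top_imp=ti,
                core_genera=core,
            )
        )

    run = RunReport(
        chosen_power=st.chosen_power,
        soft_threshold=st.table,
        partition=partition,
        module_sizes=sizes,
        trait_result=result,
        selected=selected.reset_index(drop=True),
        findings=findings,
        seed=config.seed,
    )
    if out_dir is not None:
        _write_outputs(run, config, Path(out_dir))
    return run


def _header(config: PipelineConfig) -> list[str]:
    return [f"seed = {config.seed}", f"config = {asdict(config)}"]


def _write_tsv(df: pd.DataFrame, path: Path, comments, index=False) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_outputs(run: RunReport, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    comments = _header(config)
    _write_tsv(run.soft_threshold, out / "soft_threshold.tsv", comments)
    assign = pd.DataFrame(
        {"otu": run.partition.labels.index,
         "module": run.partition.labels.values,
         "mm": run.trait_result.mm.reindex(run.partition.labels.index).values,
         "gs": run.trait_result.gs.iloc[:, 0]
              .reindex(run.partition.labels.index).values}
    )
    _write_tsv(assign, out / "module_assignment.tsv", comments)
    eig = run.partition.eigengenes.copy()
    eig.index.name = "sample_id"
    _write_tsv(eig, out / "eigengenes.tsv", comments, index=True)
    _write_tsv(run.trait_result.module_trait, out / "module_trait.tsv", comments)
    _write_tsv(run.trait_result.mm_gs, out / "mm_gs.tsv", comments)
    for f in run.findings:
        prefix = out / f"module_{f.module}"
        _write_tsv(f.hub_table, Path(f"{prefix}_hubs.tsv"), comments)
        _write_tsv(f.rf_table, Path(f"{prefix}_rf_importance.tsv"), comments)
        write_network(f.network, Path(f"{prefix}_edges.tsv"),
                      Path(f"{prefix}_nodes.tsv"), Path(f"{prefix}.sif"))
    with open(out / "run_summary.json", "w") as fh:
        json.dump(run.summary(), fh, indent=2)


def run_strain_scoring(table: pd.DataFrame, out_dir=None,
                       cum_threshold: float = 0.90):
    """KMO gate, PCA and composite ranking; optionally write the two report
    tables (loading matrix / composite scores)."""
    pca, kmo_value = score_strains(table, cum_threshold=cum_threshold)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        load = pca.loadings.copy()
        head = pd.DataFrame(
            [pca.characteristic_roots[: pca.n_components],
             pca.explained_variance * 100.0],
            index=["characteristic_root", "explained_variance_pct"],
            columns=load.columns,
        )
        report = pd.concat([head, load])
        report.index.name = "name"
        report.to_csv(out / "pca_loadings.tsv", sep="\t")
        scores = pca.scores.copy()
        scores.index.name = "strain"
        scores.to_csv(out / "composite_scores.tsv", sep="\t")
        with open(out / "kmo.txt", "w") as fh:
            fh.write(f"kmo = {kmo_value:.6f}\n"
                     f"cumulative_variance_pct = {pca.cumulative * 100:.3f}\n")
    return pca, kmo_value
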