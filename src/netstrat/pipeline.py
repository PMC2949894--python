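"""End-to-end comparative analysis of a conglomerate network and its strata.

Runs the full pipeline — stratification, topology and status change,
network compatibility with randomized nulls, module extraction with the Cp
protocol, functional enrichment, and the randomization/robustness stage —
and writes per-stage TSVs plus a validity summary with one row per analysis
family, stating whether the conglomerate-level result transfers to the
context-dependent subnetworks under the run's own measurements.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from netstrat.enrichment import (
    AnnotationMap,
    distribution_chi2,
    module_enrichment_summary,
    protein_enrichment,
)
from netstrat.graph_core import log, node_stats, read_network
from netstrat.modules import DEFAULT_GRIDS, clique_percolation, cp_comparison_protocol
from netstrat.netcompat import compatibility_null, network_compatibility
from netstrat.randomize import robustness_protocol, status_change_randomization
from netstrat.stratify import ContextHierarchy, stratify_all, write_family
from netstrat.synthdata import SynthConfig, generate
from netstrat.topology import (
    assign_classes,
    class_changes,
    compare_stat_distributions,
    identify_roles,
    powerlaw_slope,
    status_change,
    status_change_table,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``synth`` is set (a synthetic family is generated) or the three
    input paths are.  Defaults follow the analysis conventions: top-20% role
    cutoff, 5/10/20/50 class cutoffs, enrichment alpha 5e-4, 500 replicates
    for compatibility nulls and 20 for status-change nulls.
    """

    outdir: str = "netstrat_run"
    synth: SynthConfig | None = None
    network_path: str | None = None
    hierarchy_path: str | None = None
    annotation_path: str | None = None
    role_pct: float = 20.0
    role_kinds: tuple[str, ...] = ("degree", "betweenness")
    class_cutoffs: tuple[float, ...] = (5, 10, 20, 50)
    cluster_algorithm: str = "cpm"
    cluster_grid: list[dict] | None = None
    min_module_size: int = 3
    alpha: float = 5e-4
    compat_replicates: int = 500
    status_null_replicates: int = 20
    degree_tolerance: float = 0.10
    robustness_fractions: tuple[float, ...] = (0.1, 0.2)
    compare_level: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.synth is None and not (self.network_path and self.hierarchy_path):
            raise ValueError("either synth config or network+hierarchy paths are required")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _inputs(config: RunConfig):
    if config.synth is not None:
        return generate(config.synth)
    conglomerate = read_network(config.network_path, name="conglomerate")
    hierarchy = ContextHierarchy.from_config(config.hierarchy_path)
    annot = AnnotationMap.from_tsv(config.annotation_path) if config.annotation_path else None
    return conglomerate, hierarchy, annot, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report bundle and writes the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [],
        "stages": [],
    }
    bundle: dict = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        manifest["outputs"].append(path.name)

    def stage(name: str):
        manifest["stages"].append(name)
        log(f"[netstrat] stage: {name}")

    try:
        stage("inputs")
        conglomerate, hierarchy, annot, truth = _inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", str(exc)) from exc

    try:
        stage("stratify")
        family = stratify_all(conglomerate, hierarchy)
        write_family(family, outdir / "networks")
        manifest["outputs"].append("networks/")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("stratify", str(exc)) from exc

    compare_nets = [n for n in family.at_level(config.compare_level) if n.n_nodes > 0]
    total = family.total

    try:
        stage("topology")
        needed = tuple({"degree", "clustering", "eccentricity"} | set(config.role_kinds))
        stats_tables = {net.name: node_stats(net, sorted(needed)) for net in [total] + compare_nets}
        summary_rows = []
        for name, tbl in stats_tables.items():
            row = {"network": name, **tbl.summary}
            slope = powerlaw_slope(tbl)
            row["powerlaw_slope"] = slope[0] if slope else float("nan")
            row["powerlaw_r2"] = slope[1] if slope else float("nan")
            summary_rows.append(row)
        emit("network_statistics", pd.DataFrame(summary_rows).set_index("network"))

        status_reports = {}
        for kind in config.role_kinds:
            ref = identify_roles(stats_tables[total.name], kind, config.role_pct)
            reports = [
                status_change(ref, identify_roles(stats_tables[net.name], kind, config.role_pct))
                for net in compare_nets
            ]
            table = status_change_table(reports)
            status_reports[kind] = table
            emit(f"status_change_{kind}", table.set_index("comparison"))

        leap_rows = []
        for kind in config.role_kinds:
            ref_cls = assign_classes(stats_tables[total.name], kind, config.class_cutoffs)
            for net in compare_nets:
                ch = class_changes(
                    ref_cls, assign_classes(stats_tables[net.name], kind, config.class_cutoffs)
                )
                leap_rows.append(
                    {
                        "kind": kind,
                        "subnetwork": net.name,
                        "n_shared": len(ch),
                        "pct_changed": 100.0 * float((ch.delta != 0).mean()) if len(ch) else 0.0,
                        "pct_leap": 100.0 * float(ch.leap.mean()) if len(ch) else 0.0,
                    }
                )
        emit("class_changes", pd.DataFrame(leap_rows))

        welch_rows = []
        for net in compare_nets:
            t, p = compare_stat_distributions(
                stats_tables[total.name], stats_tables[net.name], "degree", "welch"
            )
            welch_rows.append({"pair": f"{total.name}:{net.name}", "t": t, "p": p})
        welch = pd.DataFrame(welch_rows)
        emit("degree_welch_tests", welch.set_index("pair"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("topology", str(exc)) from exc

    try:
        stage("netcompat")
        rng = np.random.default_rng(config.seed)
        compat_rows = []
        nets = compare_nets
        for i in range(len(nets)):
            for j in range(i + 1, len(nets)):
                obs = network_compatibility(nets[i], nets[j])
                res = compatibility_null(
                    total,
                    nets[i].n_nodes,
                    nets[j].n_nodes,
                    n_rep=config.compat_replicates,
                    seed=rng,
                    observed=obs,
                )
                compat_rows.append(
                    {
                        "pair": f"{nets[i].name}:{nets[j].name}",
                        "j_nodes": res.j_nodes,
                        "j_edges": res.j_edges,
                        "null_mean_nodes": res.null_mean_nodes,
                        "null_sd_nodes": res.null_sd_nodes,
                        "p_nodes": res.p_nodes,
                        "null_mean_edges": res.null_mean_edges,
                        "null_sd_edges": res.null_sd_edges,
                        "p_edges": res.p_edges,
                    }
                )
        compat = pd.DataFrame(compat_rows)
        emit("compatibility", compat.set_index("pair"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("netcompat", str(exc)) from exc

    try:
        stage("modules")
        cp_report = cp_comparison_protocol(
            family,
            algorithm=config.cluster_algorithm,
            param_grid=config.cluster_grid,
            min_module_size=config.min_module_size,
            levels=(config.compare_level,),
        )
        emit("cp_scores", cp_report["table"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("modules", str(exc)) from exc

    enrich_summary = None
    chi2_df = pd.DataFrame()
    try:
        if annot is not None:
            stage("enrichment")
            rows = []
            for net in compare_nets:
                table = protein_enrichment(
                    net.nodes, total.nodes, annot, "biological_process", config.alpha
                )
                for term in table.index[table.enriched]:
                    rows.append(
                        {"network": net.name, "term": term, "p": table.loc[term, "p"]}
                    )
            emit("protein_enrichment", pd.DataFrame(rows))
            chi2_rows = []
            total_counts = annot.term_counts(total.nodes, "biological_process")
            for net in compare_nets:
                chi2, df_, p = distribution_chi2(
                    annot.term_counts(net.nodes, "biological_process"), total_counts
                )
                chi2_rows.append({"network": net.name, "chi2": chi2, "df": df_, "p": p})
            chi2_df = pd.DataFrame(chi2_rows)
            emit("annotation_chi2", chi2_df.set_index("network"))

            grid = config.cluster_grid or DEFAULT_GRIDS[config.cluster_algorithm]
            k_mod = grid[0].get("k", 4) if config.cluster_algorithm == "cpm" else 4
            modsets = {
                net.name: clique_percolation(net, k=k_mod)
                for net in [total] + compare_nets
            }
            enrich_summary = module_enrichment_summary(
                modsets,
                annot,
                {net.name: net.nodes for net in [total] + compare_nets},
                "biological_process",
                config.alpha,
                total_name=total.name,
                min_module_size=config.min_module_size,
            )
            emit("module_enrichment", enrich_summary.per_module)
            with (outdir / "module_enrichment_terms.json").open("w") as fh:
                json.dump(
                    {
                        "universal": sorted(enrich_summary.universal_terms),
                        "exclusive": {
                            k: sorted(v) for k, v in enrich_summary.exclusive_terms.items()
                        },
                        "conglomerate_only": sorted(enrich_summary.conglomerate_only_terms),
                        "enriched_fraction": enrich_summary.enriched_fraction,
                    },
                    fh,
                    indent=1,
                )
            manifest["outputs"].append("module_enrichment_terms.json")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", str(exc)) from exc

    try:
        stage("randomize")
        null_rows = []
        root_list = hierarchy.root.proteins
        rng = np.random.default_rng(config.seed + 1)
        for net in compare_nets:
            res = status_change_randomization(
                total,
                stats_tables[total.name],
                net,
                list_size=min(len(hierarchy.contexts[net.name].proteins), len(root_list)),
                universe=root_list,
                kind="degree",
                pct=config.role_pct,
                n_rep=config.status_null_replicates,
                tolerance=config.degree_tolerance,
                seed=rng,
            )
            null_rows.append(
                {
                    "subnetwork": net.name,
                    "observed_pct_hub_to_nonhub": res.observed_pct,
                    "null_mean_pct": res.null_mean,
                    "t": res.t_statistic,
                    "p": res.p_value,
                }
            )
        null_df = pd.DataFrame(null_rows)
        emit("status_change_null", null_df.set_index("subnetwork"))

        robustness = robustness_protocol(
            conglomerate,
            hierarchy,
            fractions=config.robustness_fractions,
            seeds=(config.seed,),
            kind="degree",
            pct=config.role_pct,
            compare_level=config.compare_level,
        )
        emit("robustness", robustness.table)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("randomize", str(exc)) from exc

    # ---- validity summary ------------------------------------------------
    verdicts = []
    welch_sig = float((welch.p < 0.01).mean()) if len(welch) else float("nan")
    verdicts.append(
        {
            "analysis": "network statistics",
            "transferable": "no" if welch_sig > 0.5 else "yes",
            "evidence": f"{welch_sig:.0%} of degree Welch tests vs total have p<0.01",
        }
    )
    for kind, label in (("degree", "hubs"), ("betweenness", "bottlenecks")):
        if kind not in status_reports:
            continue
        tbl = status_reports[kind]
        mean_keep = 100.0 - tbl.attrs["mean_pct_role_to_nonrole"]
        verdicts.append(
            {
                "analysis": label,
                "transferable": "yes (majority)" if mean_keep >= 50 else "no",
                "evidence": f"on average {mean_keep:.1f}% of total-network roles keep their "
                "status in subnetworks (shared nodes)",
            }
        )
    if len(compat):
        above = float((compat.j_nodes > compat.null_mean_nodes).mean())
        verdicts.append(
            {
                "analysis": "network compatibility",
                "transferable": "partial",
                "evidence": f"node agreement exceeds the randomized null in {above:.0%} of pairs",
            }
        )
    if "mannwhitney_p" in cp_report:
        distinct = (
            cp_report["mean_cp_between"] < cp_report["mean_cp_within"]
            and cp_report["mannwhitney_p"] < 0.05
        )
        verdicts.append(
            {
                "analysis": "modules",
                "transferable": "no" if distinct else "yes",
                "evidence": f"Cp total-vs-subnetwork {cp_report['mean_cp_between']:.2f} vs "
                f"within-network {cp_report['mean_cp_within']:.2f} "
                f"(Mann-Whitney p={cp_report['mannwhitney_p']:.2g})",
            }
        )
    if annot is not None and len(chi2_df):
        chi_sig = float((chi2_df.p < 0.01).mean())
        verdicts.append(
            {
                "analysis": "functional enrichment",
                "transferable": "no" if chi_sig > 0.5 else "yes",
                "evidence": f"{chi_sig:.0%} of annotation-count chi-square tests vs total "
                "have p<0.01",
            }
        )
    validity = pd.DataFrame(verdicts).set_index("analysis")
    emit("validity_summary", validity)

    manifest["config"] = asdict(config)
    manifest["decisions"] = [f"D{i}" for i in range(1, 24)]
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, default=str)

    bundle.update(
        family=family,
        stats_tables=stats_tables,
        status_reports=status_reports,
        compatibility=compat,
        cp_report=cp_report,
        enrichment_summary=enrich_summary,
        status_change_null=null_df,
        robustness=robustness,
        validity=validity,
        truth=truth,
        manifest=manifest,
    )
    return bundle
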