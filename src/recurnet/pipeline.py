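"""End-to-end orchestration: differential expression -> enrichment ->
differential co-expression networks -> marker survival validation.

A single :class:`PipelineConfig` either points at input files (expression TSV,
group TSV, clinical CSV, GMT) or embeds a :class:`SimulationConfig`; the run
writes every intermediate table, a checksum manifest, and a JSON report whose
payload is byte-reproducible under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexnet, diffexpr, enrichment, io, survstats
from .synthetic import (
    NON_RECURRENCE,
    RECURRENCE,
    AnnotationCollection,
    ClinicalTable,
    LabeledExpressionMatrix,
    SimulationConfig,
    generate_annotations,
    generate_clinical,
    generate_expression,
)

log = logging.getLogger("recurnet")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one analysis run.

    Exactly one of (``expression_path`` + ``groups_path`` + ``clinical_path``
    + ``gmt_path``) or ``simulation`` must be supplied.  Every threshold the
    analysis applies is surfaced here and logged at run time.
    """

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    p_max: float = 0.05
    q_max: float = 0.10
    min_abs_log_ratio: float = 0.0
    corr_p_max: float = coexnet.DEFAULT_P_MAX
    corr_min_abs_r: float = coexnet.DEFAULT_MIN_ABS_R
    n_perm: int = 0
    cutoff_rule: str = "youden"
    cox_covariates: tuple[str, ...] = ("afp_high",)
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.expression_path, self.groups_path, self.clinical_path, self.gmt_path]
        has_paths = any(p is not None for p in paths)
        if has_paths and self.simulation is not None:
            raise ValueError("config must set input paths OR a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise ValueError("config must set input paths or a simulation block")
        if has_paths and not all(p is not None for p in paths):
            raise ValueError("file mode needs expression, groups, clinical, and GMT paths")
        for name in ("p_max", "q_max", "corr_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.corr_min_abs_r <= 1:
            raise ValueError("corr_min_abs_r must be in [0, 1]")
        if self.cutoff_rule not in ("youden", "median"):
            raise ValueError("cutoff_rule must be 'youden' or 'median'")
        object.__setattr__(self, "cox_covariates", tuple(self.cox_covariates))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_inputs(
    config: PipelineConfig,
) -> tuple[LabeledExpressionMatrix, pd.DataFrame, AnnotationCollection]:
    """Load and cross-validate the three inputs (file mode)."""
    expr = io.read_expression(config.expression_path, config.groups_path)
    clinical = io.read_clinical(config.clinical_path)
    stray = set(clinical.index) - set(expr.sample_ids)
    if stray:
        raise io.InputFormatError(
            "clinical rows with sample IDs absent from the expression matrix: "
            f"{sorted(stray)[:10]}"
        )
    annotations = io.read_gmt(config.gmt_path, universe=expr.gene_ids)
    return expr, clinical, annotations


def _simulate_inputs(
    config: PipelineConfig,
) -> tuple[LabeledExpressionMatrix, pd.DataFrame, AnnotationCollection, ClinicalTable]:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    expr = generate_expression(sim)
    clinical_obj = generate_clinical(expr, sim)
    annotations = generate_annotations(sim, expr)
    return expr, clinical_obj.data, annotations, clinical_obj


def _marker_columns(clinical: pd.DataFrame) -> list[str]:
    return [c for c in clinical.columns if c.startswith("marker_")]


def _validate_markers(
    clinical: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, dict]:
    """Per-marker: ROC cutoff, dichotomization vs recurrence, contingency,
    KM/log-rank, and a Cox model (marker class + configured covariates)."""
    two_group = clinical[clinical["group"].isin([RECURRENCE, NON_RECURRENCE])].copy()
    outcome = (two_group["group"] == RECURRENCE).astype(int).to_numpy()
    results: dict[str, dict] = {}
    for col in _marker_columns(clinical):
        gene = col.removeprefix("marker_")
        values = two_group[col].to_numpy(float)
        if config.cutoff_rule == "youden":
            cut = survstats.roc_cutoff(values, outcome, marker_id=gene)
            cutoff, auc = cut.cutoff, cut.auc
        else:
            cutoff, auc = float(np.median(values)), float("nan")
        dich = survstats.dichotomize(values, cutoff, outcome)
        entry: dict = {
            "cutoff": cutoff,
            "auc": auc,
            "table": dich.table.to_numpy().tolist(),
            "pct_high_recurrence": dich.pct_high.get(1),
            "pct_high_nonrecurrence": dich.pct_high.get(0),
            "degenerate_split": dich.degenerate,
        }
        if not dich.degenerate:
            entry["contingency"] = survstats.contingency_test(dich.table.to_numpy())
            t = two_group["time_months"].to_numpy(float)
            e = two_group["event"].to_numpy(int)
            cls = np.where(dich.high, "high", "low")
            stat, p = survstats.logrank_test(t, e, cls)
            entry["logrank"] = {"stat": stat, "p": p}
            km = survstats.km_estimate(t, e, cls)
            entry["km"] = {
                g: c.to_dict(orient="list") for g, c in km.curves.items()
            }
            cox_df = two_group[["time_months", "event"]].copy()
            cox_df[f"{gene}_high"] = dich.high.astype(int)
            covs = [f"{gene}_high"]
            for c in config.cox_covariates:
                if c in two_group.columns and two_group[c].nunique() > 1:
                    cox_df[c] = two_group[c]
                    covs.append(c)
            try:
                cox = survstats.cox_fit(cox_df, covs)
                entry["cox"] = {
                    idx: {
                        "HR": float(row["HR"]),
                        "ci_low": float(row["ci_low"]),
                        "ci_high": float(row["ci_high"]),
                        "p": float(row["p"]),
                    }
                    for idx, row in cox.iterrows()
                }
            except (survstats.CoxSeparationError, ValueError) as err:
                entry["cox_diagnostic"] = str(err)
        results[gene] = entry
    return results


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order and return the JSON-serializable report.

    Stage order: RVM differential expression -> DEG selection + hierarchical
    clustering -> GO/pathway-style enrichment of the up and down sets ->
    per-group co-expression networks on the DEG panel with k-core and DiffK
    (optional permutation null) -> marker dichotomization and survival
    validation.  All intermediate tables, a manifest, and report.json are
    written to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise RuntimeError(f"output directory {out} is not writable: {err}") from err

    log.info("thresholds: p<%g, q<%g, corr p<%g, |r|>=%g, n_perm=%d, cutoff=%s",
             config.p_max, config.q_max, config.corr_p_max, config.corr_min_abs_r,
             config.n_perm, config.cutoff_rule)

    stage = "inputs"
    written: list[Path] = []
    report: dict = {"stages": {}, "flags": []}
    try:
        if config.simulation is not None:
            expr, clinical, annotations, clinical_obj = _simulate_inputs(config)
            io.write_expression(expr, out / "expression.tsv")
            io.write_groups(expr, out / "groups.tsv")
            io.write_clinical(clinical_obj, out / "clinical.csv")
            io.write_gmt(annotations, out / "genesets.gmt")
            written += [out / "expression.tsv", out / "groups.tsv",
                        out / "clinical.csv", out / "genesets.gmt"]
            report["stages"]["inputs"] = {
                "mode": "simulation",
                "n_genes": len(expr.gene_ids),
                "n_samples": len(expr.sample_ids),
                "n_clinical": int(len(clinical)),
                "n_discarded": clinical_obj.n_discarded,
            }
        else:
            expr, clinical, annotations = read_inputs(config)
            report["stages"]["inputs"] = {
                "mode": "files",
                "n_genes": len(expr.gene_ids),
                "n_samples": len(expr.sample_ids),
                "n_clinical": int(len(clinical)),
            }

        stage = "diffexpr"
        prior = diffexpr.fit_rvm_prior(expr, (RECURRENCE, NON_RECURRENCE))
        de = diffexpr.rvm_t_test(expr, (RECURRENCE, NON_RECURRENCE), prior)
        de.to_csv(out / "de_table.tsv", sep="\t", float_format="%.10g")
        written.append(out / "de_table.tsv")
        sel = diffexpr.select_degs(
            de, p_max=config.p_max, q_max=config.q_max,
            min_abs_log_ratio=config.min_abs_log_ratio,
        )
        report["stages"]["diffexpr"] = {
            "prior_a": prior.a,
            "prior_b": prior.b,
            "prior_at_boundary": prior.at_boundary,
            "moderated_df": float(de["df"].iloc[0]),
            "n_up": sel.n_up,
            "n_down": sel.n_down,
        }
        if len(sel.genes) >= 2 and len(expr.sample_ids) >= 2:
            clust = diffexpr.hierarchical_cluster(expr, genes=sel.genes)
            pd.Series(clust.gene_order, name="gene_id").to_csv(
                out / "cluster_gene_order.tsv", sep="\t", index=False)
            pd.Series(clust.sample_order, name="sample_id").to_csv(
                out / "cluster_sample_order.tsv", sep="\t", index=False)
            written += [out / "cluster_gene_order.tsv", out / "cluster_sample_order.tsv"]

        stage = "enrichment"
        enr_tables = []
        for direction, genes in (("up", sel.up), ("down", sel.down)):
            if not genes:
                report["flags"].append(f"empty {direction} DEG set; enrichment skipped")
                continue
            res = enrichment.enrich(genes, direction, annotations)
            tab = res.table.copy()
            tab.insert(0, "direction", direction)
            tab["n"] = res.n
            tab["N"] = res.N
            enr_tables.append(tab)
        enr_all = (
            pd.concat(enr_tables)
            if enr_tables
            else pd.DataFrame(columns=["direction", "term_name", "nf", "Nf",
                                       "Re", "p_fisher", "p_chi2", "q", "LgP", "n", "N"])
        )
        enr_all.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.10g")
        written.append(out / "enrichment.tsv")
        top_terms = [
            {"term_id": str(t), "direction": row["direction"],
             "Re": float(row["Re"]), "p_fisher": float(row["p_fisher"]),
             "LgP": float(row["LgP"])}
            for t, row in enr_all.sort_values("p_fisher").head(5).iterrows()
        ]
        report["stages"]["enrichment"] = {"n_terms": int(len(enr_all)),
                                          "top_terms": top_terms}

        stage = "coexnet"
        deg_genes = list(sel.genes)
        if len(deg_genes) >= 2:
            sub = expr.subset_genes(deg_genes)
            net1, net2 = coexnet.build_group_networks(
                sub, RECURRENCE, NON_RECURRENCE,
                p_max=config.corr_p_max, min_abs_r=config.corr_min_abs_r,
            )
            for net, name in ((net1, "recurrence"), (net2, "nonrecurrence")):
                edges = pd.DataFrame(
                    [(a, b, d["r"], d["p"]) for a, b, d in net.graph.edges(data=True)],
                    columns=["gene_a", "gene_b", "r", "p"],
                ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
                io.write_edges(edges, name, out / f"edges_{name}.tsv")
                written.append(out / f"edges_{name}.tsv")
            conn = coexnet.diffk(net1, net2)
            conn.table.to_csv(out / "node_metrics.tsv", sep="\t", float_format="%.10g")
            written.append(out / "node_metrics.tsv")
            top = conn.table.head(10)
            report["stages"]["coexnet"] = {
                "n_nodes": int(len(conn.table)),
                "n_edges_recurrence": net1.n_edges,
                "n_edges_nonrecurrence": net2.n_edges,
                "max_core_recurrence": int(conn.table["core1"].max()),
                "max_core_nonrecurrence": int(conn.table["core2"].max()),
                "top_diffk": [
                    {"gene_id": str(g), "k1": int(r["k1"]), "k2": int(r["k2"]),
                     "diffk": float(r["diffk"]), "rank": int(r["rank"])}
                    for g, r in top.iterrows()
                ],
            }
            if config.n_perm > 0:
                perm = coexnet.permutation_significance(
                    sub, RECURRENCE, NON_RECURRENCE, n_perm=config.n_perm,
                    seed=config.seed, p_max=config.corr_p_max,
                    min_abs_r=config.corr_min_abs_r,
                )
                perm.to_csv(out / "diffk_permutation.tsv", sep="\t",
                            float_format="%.10g")
                written.append(out / "diffk_permutation.tsv")
                report["stages"]["coexnet"]["n_perm"] = config.n_perm
        else:
            report["flags"].append("fewer than 2 DEGs; network stage skipped")
            (out / "node_metrics.tsv").write_text(
                "gene_id\tk1\tk2\tK1\tK2\tdiffk\tcore1\tcore2\trank\trank_abs\n")
            written.append(out / "node_metrics.tsv")

        stage = "survival"
        report["stages"]["survival"] = _validate_markers(clinical, config)

        stage = "report"
        manifest = io.write_manifest(written, out / "manifest.json")
        report["provenance"] = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_files": len(manifest),
        }
        payload = json.dumps(report, indent=2, sort_keys=True, default=float)
        (out / "report.json").write_text(payload + "\n")
        return report
    except Exception as err:
        (out / "FAILED_STAGE.txt").write_text(f"{stage}: {err}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
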