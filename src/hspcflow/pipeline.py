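"""End-to-end orchestration: simulate -> qc -> train -> predict ->
composition -> trends -> regulons.

A single JSON-style config with per-stage parameter blocks drives the run;
all randomness flows from one master seed through named substreams.  Each
stage writes plain-text outputs under the run directory and appends a
summary to the run manifest.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, composition, io, qc, regulons, simdata, trends

STAGES = (
    "simulate",
    "qc",
    "train",
    "predict",
    "composition",
    "trends",
    "regulons",
)


class ConfigError(ValueError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Schema and pre-flight path checks; raises before any stage runs."""
    if "outdir" not in config:
        raise ConfigError("config requires an 'outdir'")
    if "seed" not in config or int(config["seed"]) != config["seed"]:
        raise ConfigError("config requires an integer 'seed'")
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}")
    stages = [s for s in STAGES if s in stages]
    cfg = dict(config)
    cfg["stages"] = stages
    if "simulate" not in stages:
        inputs = cfg.get("inputs", {})
        need = {
            "qc": ["reference", "query"],
            "train": ["reference", "query"],
            "predict": ["query"],
            "trends": ["reference_trajectory", "query_trajectory"],
            "regulons": ["auc", "regulon_edges"],
        }
        for stage in stages:
            for key in need.get(stage, []):
                if key not in inputs:
                    raise ConfigError(
                        f"stage {stage!r} needs inputs[{key!r}] when the "
                        "simulate stage is disabled"
                    )
                path = Path(inputs[key])
                if not path.exists():
                    raise ConfigError(
                        f"input path for {key!r} does not exist: {path}"
                    )
    return cfg


def _qc_one(adata, block, label, outdir, manifest_stage):
    prefix = block.get("mito_gene_prefix", "MT-")
    if "max_genes_per_cell" in block:
        ceilings = {
            "max_genes_per_cell": block["max_genes_per_cell"],
            "max_umis_per_cell": block["max_umis_per_cell"],
        }
    else:
        sug = qc.suggest_thresholds(
            adata, quantile=block.get("ceiling_quantile", 0.99)
        )
        ceilings = {
            "max_genes_per_cell": int(sug["max_genes_per_cell"].max()),
            "max_umis_per_cell": int(sug["max_umis_per_cell"].max()),
        }
    thresholds = qc.QCThresholds(
        mito_max_pct=block.get("mito_max_pct", 5.0),
        mito_min_pct=block.get("mito_min_pct"),
        mito_gene_prefix=prefix,
        **ceilings,
    )
    filtered, report = qc.filter_cells(adata, thresholds)
    io.write_tsv(report, outdir / f"qc_report_{label}.tsv")
    norm = qc.log_normalize(filtered, block.get("scale_factor", 1e4))
    hvg, _ = qc.select_hvg(filtered, block.get("n_hvg", 1000))
    manifest_stage[label] = {
        "cells_in": int(adata.n_obs),
        "cells_kept": int(filtered.n_obs),
        "thresholds": {
            **ceilings,
            "mito_max_pct": thresholds.mito_max_pct,
            "mito_min_pct": thresholds.mito_min_pct,
        },
    }
    return filtered, norm, hvg


def run(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir or cfg["outdir"])
    data_dir = outdir / "data"
    res_dir = outdir / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "stages": [],
        "input_hashes": {},
    }
    ctx: dict = {}

    def _record(name, summary):
        manifest["stages"].append({"name": name, "summary": summary})
        io.write_json(manifest, outdir / "manifest.json")

    for stage in cfg["stages"]:
        try:
            if stage == "simulate":
                block = dict(cfg.get("simulate", {}))
                effects_block = block.pop("effects", {}) or {}
                sim_cfg = simdata.SimConfig(seed=seed, **block)
                ref, ref_truth = simdata.generate_reference(sim_cfg)
                effects = simdata.PerturbationEffects(
                    proportion_shift=effects_block.get("proportion_shift", {}),
                    trend_shift={
                        g: dict(v)
                        for g, v in effects_block.get("trend_shift", {}).items()
                    },
                )
                query, query_truth = simdata.generate_query(
                    sim_cfg, ref_truth, effects
                )
                simdata.write_dataset(ref, ref_truth, data_dir / "reference", sim_cfg)
                simdata.write_dataset(query, query_truth, data_dir / "query", sim_cfg)
                auc = simdata.generate_auc_matrix(sim_cfg, ref_truth)
                io.write_tsv(auc, data_dir / "auc.tsv")
                edges = simdata.generate_regulon_edges(sim_cfg)
                io.write_tsv(edges, data_dir / "regulon_edges.tsv", index=False)
                ctx.update(
                    sim_cfg=sim_cfg, reference=ref, reference_truth=ref_truth,
                    query=query, query_truth=query_truth, auc=auc, edges=edges,
                )
                for f in sorted(data_dir.rglob("*.tsv")):
                    manifest["input_hashes"][str(f.relative_to(outdir))] = _sha256(f)
                _record(stage, {
                    "reference_cells": int(ref.n_obs),
                    "query_cells": int(query.n_obs),
                    "genes": int(ref.n_vars),
                })
            elif stage == "qc":
                block = cfg.get("qc", {})
                if "reference" not in ctx:
                    inputs = cfg["inputs"]
                    ctx["reference"] = io.read_mtx_dir(inputs["reference"])
                    ctx["query"] = io.read_mtx_dir(inputs["query"])
                summary: dict = {}
                ref_f, ref_n, ref_hvg = _qc_one(
                    ctx["reference"], block, "reference", res_dir, summary
                )
                qry_f, qry_n, qry_hvg = _qc_one(
                    ctx["query"], block, "query", res_dir, summary
                )
                ctx.update(
                    reference_filtered=ref_f, reference_norm=ref_n,
                    reference_hvg=ref_hvg, query_filtered=qry_f,
                    query_norm=qry_n, query_hvg=qry_hvg,
                )
                pd.Series(ref_hvg, name="gene").to_csv(
                    res_dir / "hvg_reference.tsv", sep="\t", index=False
                )
                pd.Series(qry_hvg, name="gene").to_csv(
                    res_dir / "hvg_query.tsv", sep="\t", index=False
                )
                _record(stage, summary)
            elif stage == "train":
                block = cfg.get("train", {})
                spec = classify.ElasticNetSpec(**{
                    k: (tuple(v) if k == "alpha_grid" else v)
                    for k, v in block.items()
                })
                labels = ctx["reference_filtered"].obs["cell_type"].to_numpy()
                ensemble = classify.train_ensemble(
                    ctx["reference_norm"], labels, ctx["reference_hvg"],
                    ctx["query_hvg"], spec, seed=seed,
                )
                ensemble.to_json(res_dir / "model.json")
                ctx["ensemble"] = ensemble
                _record(stage, {
                    "cell_types": len(ensemble.cell_types),
                    "features": len(ensemble.features),
                    "models": sum(len(v) for v in ensemble.models.values()),
                })
            elif stage == "predict":
                ann = classify.predict(ctx["ensemble"], ctx["query_norm"])
                io.write_tsv(ann.to_frame(), res_dir / "annotations.tsv")
                ctx["annotation"] = ann
                counts = ann.labels.value_counts()
                _record(stage, {
                    "cells": int(len(ann.labels)),
                    "not_assigned": int(counts.get(classify.NOT_ASSIGNED, 0)),
                })
            elif stage == "composition":
                ref_labels = ctx["reference_filtered"].obs["cell_type"]
                ref_meta = ctx["reference_filtered"].obs
                qry_meta = ctx["query_filtered"].obs
                comp_ref = composition.compute_composition(ref_labels, ref_meta)
                comp_qry = composition.compute_composition(
                    ctx["annotation"].labels, qry_meta
                )
                shift = composition.test_composition_shift(comp_ref, comp_qry)
                io.write_tsv(comp_ref, res_dir / "composition_reference.tsv",
                             index=False)
                io.write_tsv(comp_qry, res_dir / "composition_query.tsv",
                             index=False)
                io.write_tsv(shift, res_dir / "composition_shift.tsv")
                ctx["composition_shift"] = shift
                _record(stage, {
                    "significant_types":
                        shift.index[shift["significant"]].tolist(),
                })
            elif stage == "trends":
                block = cfg.get("trends", {})
                branch = block.get("branch", "monocytic")
                grid_size = block.get("grid_size", 500)
                genes = block.get("genes")
                trend_sets = {}
                for label in ("reference", "query"):
                    truth = ctx.get(f"{label}_truth")
                    filtered = ctx[f"{label}_filtered"]
                    norm = ctx[f"{label}_norm"]
                    if truth is not None:
                        traj = pd.concat(
                            [truth.pseudotime,
                             truth.branch_probabilities.add_prefix("bp_")],
                            axis=1,
                        ).loc[filtered.obs_names]
                        if genes is None:
                            genes = sorted(truth.trend_functions)
                    else:
                        traj = io.read_tsv(
                            cfg["inputs"][f"{label}_trajectory"]
                        ).loc[filtered.obs_names]
                    expr = pd.DataFrame(
                        np.asarray(norm[:, genes].X.todense()),
                        index=norm.obs_names, columns=genes,
                    )
                    trend_sets[label] = trends.fit_trends(
                        expr, traj, branch, genes=genes, grid_size=grid_size,
                        condition=label,
                    )
                    io.write_tsv(
                        trends.trend_matrix(trend_sets[label]),
                        res_dir / f"trends_{label}.tsv",
                    )
                clusters = trends.cluster_trends(
                    trend_sets["reference"], block.get("n_clusters", 4)
                )
                io.write_tsv(clusters.to_frame(), res_dir / "trend_clusters.tsv")
                cmp = trends.compare_trends(
                    trend_sets["reference"], trend_sets["query"]
                )
                io.write_tsv(cmp, res_dir / "trend_comparison.tsv")
                ctx["trend_comparison"] = cmp
                _record(stage, {
                    "branch": branch,
                    "genes": len(cmp),
                    "flagged": int((cmp["tier"] != "NS").sum()),
                })
            elif stage == "regulons":
                block = cfg.get("regulons", {})
                if "auc" not in ctx:
                    ctx["auc"] = io.read_tsv(cfg["inputs"]["auc"])
                    ctx["edges"] = pd.read_csv(
                        cfg["inputs"]["regulon_edges"], sep="\t"
                    )
                truth = ctx.get("reference_truth")
                if truth is not None:
                    batches = truth.donors
                    clusters = truth.cell_labels
                else:
                    meta = ctx["reference"].obs
                    batches = meta["donor"]
                    clusters = meta["cell_type"]
                auc = ctx["auc"]
                centered = regulons.batch_center(auc, batches)
                shifted = centered - centered.to_numpy().min()  # RSS needs >= 0
                binary, thresholds = regulons.binarize(centered)
                pct = regulons.percent_active(binary, clusters)
                spec_scores = regulons.rss(shifted, clusters)
                top = regulons.top_regulons(spec_scores, block.get("top_k", 5))
                trimmed, graph = regulons.trim_network(ctx["edges"])
                io.write_tsv(binary, res_dir / "auc_binary.tsv")
                io.write_tsv(pct, res_dir / "regulon_percent_active.tsv")
                io.write_tsv(spec_scores, res_dir / "regulon_rss.tsv")
                io.write_json(top, res_dir / "regulon_top.json")
                io.write_tsv(trimmed, res_dir / "regulon_trimmed_edges.tsv",
                             index=False)
                import networkx as nx

                nx.write_graphml(graph, res_dir / "regulon_network.graphml")
                _record(stage, {
                    "regulons": int(auc.shape[0]),
                    "trimmed_edges": int(len(trimmed)),
                })
        except (ConfigError, KeyError) as err:
            raise ConfigError(f"stage {stage!r} failed: {err}") from err
    return manifest
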