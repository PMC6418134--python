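"""End-to-end orchestration: harmonize -> merge -> networks -> screen -> index.

A single :class:`PipelineConfig` (YAML) drives the whole analysis and every
output is written under one directory with stable ordering and no
timestamps, so identical config + seed produces byte-identical files.  A
JSON manifest records library versions, the RNG seed and per-stage row
counts, including every exclusion (missing clinical values, skipped genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import CohortStudy
from .harmonize import (
    harmonize_to_reference,
    merge_cohorts,
    read_clinical_table,
    read_expression_table,
    write_clinical_table,
    write_expression_table,
)
from .index import compute_immune_index, dichotomize_index, index_cox, predict_survival_curves
from .network import GeneNetwork, build_stratum_networks, compare_networks
from .simulate import SimulationConfig, generate_multi_cohort
from .survival import CoxResult, screen_genes, screen_table


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; exactly one data source."""

    out_dir: str
    simulation: dict | None = None
    inputs: dict | None = None  # {"cohorts": [{"expression":..., "clinical":..., "scale":...}]}
    seed_genes: list[str] | None = None
    reference_cohort: str | None = None
    threshold: float = 0.9
    edge_limit: int = 1
    absolute_corr: bool = False
    cluster_cut: str = "max"
    stratify: list[list[str]] = field(default_factory=lambda: [["recurrence"], ["node", "recurrence"]])
    index_genes: str | list[str] = "discovered"
    percentile: float = 40.0
    min_samples: int = 20
    horizon: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of {simulation, inputs} must be set")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class ReportBundle:
    """Objects and file paths produced by one pipeline run."""

    study: CohortStudy
    networks: dict[str, GeneNetwork]
    comparisons: list
    screen_results: list[CoxResult]
    index: object
    models: dict
    curves: pd.DataFrame
    manifest: dict
    out_dir: Path


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def _canonical_graph(network: GeneNetwork) -> nx.Graph:
    g = nx.Graph()
    for n in sorted(network.graph.nodes):
        g.add_node(n, **{k: network.graph.nodes[n][k] for k in sorted(network.graph.nodes[n])})
    for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
        g.add_edge(a, b, weight=float(network.graph.edges[a, b]["weight"]))
    return g


def export_network(network: GeneNetwork, path: str, fmt: str = "graphml") -> None:
    """Write a network with all node attributes; deterministic ordering.

    ``graphml`` round-trips through :func:`import_network`; ``json`` writes
    a sorted node-link document.
    """
    g = _canonical_graph(network)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "json":
        doc = {
            "stratum": network.stratum,
            "nodes": [{"id": n, **g.nodes[n]} for n in g.nodes],
            "edges": [
                {"source": a, "target": b, "weight": g.edges[a, b]["weight"]}
                for a, b in g.edges
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network(path: str, stratum: str = "", seeds: frozenset[str] = frozenset()) -> GeneNetwork:
    """Read a GraphML network back (nodes/edges re-sorted canonically)."""
    g = nx.read_graphml(path)
    if seeds == frozenset():
        seeds = frozenset(n for n, d in g.nodes(data=True) if d.get("is_seed"))
    net = GeneNetwork(graph=g, stratum=stratum, seeds=seeds)
    net.graph = _canonical_graph(net)
    return net


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_results_tables(results: list[CoxResult], out_dir: str, name: str = "cox_screen",
                         fdr: bool = False) -> Path:
    """Write a Cox screen table (Gene, B, HR, P, CI, stars) as TSV."""
    if not results:
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{name}.tsv"
    screen_table(results, fdr=fdr).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_studies(cfg: PipelineConfig, manifest: dict) -> tuple[list[CohortStudy], list[str], dict]:
    scales: dict[str, str] = {}
    if cfg.simulation is not None:
        sim = SimulationConfig(**{**cfg.simulation, "rng_seed": cfg.simulation.get("rng_seed", cfg.rng_seed)})
        studies = generate_multi_cohort(sim)
        seeds = cfg.seed_genes or list(sim.seed_gene_ids)
        for s in studies:
            scales[s.expression.cohort] = "log2"
    else:
        studies = []
        seeds = list(cfg.seed_genes or [])
        if not seeds:
            raise ValueError("seed_genes must be given for file inputs")
        for spec in cfg.inputs["cohorts"]:
            expr = read_expression_table(spec["expression"], cohort=spec.get("cohort", ""))
            clin = read_clinical_table(spec["clinical"])
            studies.append(CohortStudy(expr, clin, [expr.cohort or "unknown"]))
            scales[expr.cohort] = spec.get("scale", "log2")
    manifest["cohorts"] = {
        s.expression.cohort: {"n_samples": s.n_samples, "n_genes": len(s.genes)} for s in studies
    }
    return studies, seeds, scales


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full analysis; any stage error aborts with the stage name
    after writing a partial manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "rng_seed": cfg.rng_seed,
        "versions": {
            "gcna": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)

    def fail(name: str, err: Exception):
        manifest["failed_stage"] = name
        _write_manifest(manifest, out)
        raise PipelineStageError(name, err) from err

    try:
        stage("load")
        studies, seeds, scales = _load_studies(cfg, manifest)
    except Exception as err:  # noqa: BLE001 - abort with stage name
        fail("load", err)

    try:
        stage("harmonize")
        ref_label = cfg.reference_cohort or studies[-1].expression.cohort
        reference = next(s for s in studies if s.expression.cohort == ref_label)
        harmonized = []
        manifest["harmonization"] = {}
        for s in studies:
            if s.expression.cohort == ref_label:
                harmonized.append(s)
                continue
            aligned, diag = harmonize_to_reference(
                s.expression, reference.expression, target_scale=scales[s.expression.cohort]
            )
            harmonized.append(CohortStudy(aligned, s.clinical.copy(), list(s.provenance)))
            manifest["harmonization"][s.expression.cohort] = diag
        manifest["reference_cohort"] = ref_label
    except Exception as err:
        fail("harmonize", err)

    try:
        stage("merge")
        study = merge_cohorts(harmonized)
        n_missing_event = int(study.clinical["recurrence_event"].isna().sum())
        manifest["merged"] = {
            "n_samples": study.n_samples,
            "n_genes": len(study.genes),
            "n_missing_event": n_missing_event,
            "n_survival_analyzable": study.n_samples - n_missing_event,
        }
        write_expression_table(study.expression, out / "expression_merged.tsv")
        write_clinical_table(study.clinical, out / "clinical_merged.tsv")
    except Exception as err:
        fail("merge", err)

    try:
        stage("networks")
        cox_cache: dict[str, CoxResult] = {}
        networks: dict[str, GeneNetwork] = {}
        for variables in cfg.stratify:
            networks.update(
                build_stratum_networks(
                    study, seeds, list(variables),
                    threshold=cfg.threshold, edge_limit=cfg.edge_limit,
                    absolute=cfg.absolute_corr, cut_mode=cfg.cluster_cut,
                    min_samples=cfg.min_samples, cox_cache=cox_cache,
                )
            )
        manifest["networks"] = {
            label: {"n_nodes": net.graph.number_of_nodes(), "n_edges": net.graph.number_of_edges()}
            for label, net in networks.items()
        }
        for label, net in networks.items():
            safe = label.replace("/", "_").replace("+", "pos").replace("-", "neg")
            export_network(net, out / f"network_{safe}.graphml", "graphml")
            export_network(net, out / f"network_{safe}.json", "json")
    except Exception as err:
        fail("networks", err)

    try:
        stage("compare")
        comparisons = []
        labels = sorted(networks)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                # compare strata that differ only in their recurrence level
                if a.replace("recurrence+", "recurrence-") == b or a.replace("recurrence-", "recurrence+") == b:
                    comparisons.append(compare_networks(networks[a], networks[b]))
        comp_doc = [
            {
                "a": c.label_a,
                "b": c.label_b,
                "common": sorted(c.common_genes),
                "exclusive_to_a": sorted(c.exclusive_to_a),
                "exclusive_to_b": sorted(c.exclusive_to_b),
            }
            for c in comparisons
        ]
        with open(out / "network_comparisons.json", "w") as fh:
            json.dump(comp_doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["comparisons"] = len(comparisons)
    except Exception as err:
        fail("compare", err)

    try:
        stage("screen")
        novel = sorted({g for net in networks.values() for g in net.nonseed_nodes})
        if not novel:
            raise ValueError("no co-expressed genes survived network construction")
        screen_results = []
        for g in novel:
            if g not in cox_cache:
                cox_cache[g] = screen_genes(study, [g])[0]
            screen_results.append(cox_cache[g])
        write_results_tables(screen_results, out, name="cox_screen", fdr=False)
        manifest["screen"] = {
            "n_genes": len(screen_results),
            "n_significant": int(sum(1 for r in screen_results if np.isfinite(r.p) and r.p < 0.05)),
        }
    except Exception as err:
        fail("screen", err)

    try:
        stage("index")
        if cfg.index_genes == "discovered":
            # novel genes of the no-recurrence network(s) with node-adjusted p < 0.05
            gene_set = sorted({
                g
                for label, net in networks.items()
                if label == "recurrence-"
                for g in net.nonseed_nodes
                if np.isfinite(cox_cache[g].p) and cox_cache[g].p < 0.05
            })
        else:
            gene_set = list(cfg.index_genes)
        if len(gene_set) < 2:
            raise ValueError(f"index gene set too small: {gene_set}")
        index = dichotomize_index(compute_immune_index(study, gene_set), cfg.percentile)
        idx_table = pd.DataFrame(
            {"score": index.sample_scores, "group": index.group}
        )
        idx_table.to_csv(out / "immune_index.tsv", sep="\t", index_label="sample_id",
                         float_format="%.6g")
        index.loadings.to_frame().to_csv(out / "index_loadings.tsv", sep="\t",
                                         index_label="gene", float_format="%.6g")
        manifest["index"] = {
            "genes": gene_set,
            "explained_variance_fraction": index.explained_variance_fraction,
            "cutoff_value": index.cutoff_value,
            "n_low": int((index.group == "low").sum()),
            "n_high": int((index.group == "high").sum()),
        }
    except Exception as err:
        fail("index", err)

    try:
        stage("models")
        model1 = index_cox(study, index, mode="continuous")
        model2 = index_cox(study, index, mode="discrete")
        models = {"model1_continuous": model1, "model2_discrete": model2}
        write_results_tables(model1.results + model2.results, out, name="index_models")
        manifest["models"] = {
            name: {r.term: {"B": r.B, "HR": r.HR, "p": r.p} for r in m.results}
            for name, m in models.items()
        }
    except Exception as err:
        fail("models", err)

    try:
        stage("curves")
        curves = predict_survival_curves(model2, horizon=cfg.horizon)
        curves.to_csv(out / "survival_curves.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["curves"] = {"n_rows": len(curves), "horizon": cfg.horizon}
    except Exception as err:
        fail("curves", err)

    _write_manifest(manifest, out)
    return ReportBundle(
        study=study, networks=networks, comparisons=comparisons,
        screen_results=screen_results, index=index, models=models,
        curves=curves, manifest=manifest, out_dir=out,
    )


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
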