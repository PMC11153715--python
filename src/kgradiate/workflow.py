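"""End-to-end workflow: preprocess → radiate → trace → enrich → clouds.

Runs the whole analysis from files on disk and writes a machine-readable
JSON report linking every produced artifact with the parameters that
produced it.  Stage failures abort with the stage name; partial outputs
are retained.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import importlib

from kgradiate import enrichment as enr
from kgradiate import graph as gr
from kgradiate import tracing as tr

# the package namespace rebinds "radiate" to the function of that name
rad = importlib.import_module("kgradiate.radiate")

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The workflow configuration is invalid or references missing files."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class WorkflowConfig:
    node_table: str
    edge_table: str
    sources_file: str
    annotations: str
    dictionary: str
    table: str
    term_names: str | None = None
    preprocess_config: str | None = None
    compartment: str = gr.DEFAULT_COMPARTMENT
    directions: tuple[str, ...] = (rad.FORWARD, rad.REVERSE)
    top_k: int = 10
    trace_modes: tuple[str, ...] = (tr.HOPS, tr.INFLUENCE)
    exclude_currency: bool = True
    alpha: float = 0.05
    semantic_iterations: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**{k: v for k, v in raw.items()})
        # resolve paths relative to the config file
        for attr in (
            "node_table",
            "edge_table",
            "sources_file",
            "annotations",
            "dictionary",
            "table",
            "term_names",
            "preprocess_config",
        ):
            value = getattr(cfg, attr)
            if value is not None:
                setattr(cfg, attr, str((base / value)))
        cfg.directions = tuple(cfg.directions)
        cfg.trace_modes = tuple(cfg.trace_modes)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("node_table", "edge_table", "sources_file", "annotations",
                     "dictionary", "table"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise ConfigError(f"{attr}: file not found: {path}")
        for d in self.directions:
            if d not in (rad.FORWARD, rad.REVERSE):
                raise ConfigError(f"invalid direction {d!r}")
        for m in self.trace_modes:
            if m not in (tr.HOPS, tr.INFLUENCE):
                raise ConfigError(f"invalid trace mode {m!r}")


def _write_radiate_tsv(result: rad.RadiateResult, g: gr.PropertyGraph, path: Path) -> None:
    rows = [
        {
            "node_id": nid,
            "display_name": g.nodes[nid].display_name,
            "labels": ";".join(sorted(g.nodes[nid].labels)),
            "pagerank": f"{score:.12e}",
            "rank": rank,
        }
        for nid, score, rank in rad.rank_nodes(result)
    ]
    pd.DataFrame(rows, columns=["node_id", "display_name", "labels", "pagerank", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def run_workflow(cfg: WorkflowConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns (and writes) the report dict."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "node_table": cfg.node_table,
            "edge_table": cfg.edge_table,
            "sources_file": cfg.sources_file,
            "compartment": cfg.compartment,
            "directions": list(cfg.directions),
            "top_k": cfg.top_k,
            "trace_modes": list(cfg.trace_modes),
            "exclude_currency": cfg.exclude_currency,
            "alpha": cfg.alpha,
            "semantic_iterations": cfg.semantic_iterations,
            "seed": cfg.seed,
        },
        "stages": [],
        "artifacts": {},
        "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }

    def stage(name: str):
        def deco(fn):
            try:
                info = fn() or {}
            except Exception as exc:  # noqa: BLE001 - rethrown with stage context
                _write_report(report, out)
                raise StageError(name, exc) from exc
            report["stages"].append({"name": name, **info})
            return info

        return deco

    state: dict = {}

    @stage("preprocess")
    def _preprocess():
        raw = gr.read_graph(cfg.node_table, cfg.edge_table)
        pcfg = (
            gr.PreprocessConfig.from_yaml(cfg.preprocess_config)
            if cfg.preprocess_config
            else gr.PreprocessConfig()
        )
        g = gr.preprocess_pathway_graph(raw, pcfg)
        view = gr.traversal_view(g, pcfg, exclude_currency=cfg.exclude_currency)
        node_path, edge_path = out / "graph_nodes.tsv", out / "graph_edges.tsv"
        gr.write_graph(g, node_path, edge_path)
        report["artifacts"]["graph"] = [str(node_path), str(edge_path)]
        state.update(graph=g, view=view, pcfg=pcfg)
        return {
            "raw_nodes": raw.n_nodes,
            "raw_edges": raw.n_edges,
            "nodes": g.n_nodes,
            "edges": g.n_edges,
            "view_nodes": view.n_nodes,
            "view_edges": view.n_edges,
        }

    @stage("radiate")
    def _radiate():
        stids = [
            line.strip()
            for line in Path(cfg.sources_file).read_text().splitlines()
            if line.strip()
        ]
        sources = gr.find_nodes(state["view"], stids, compartment=cfg.compartment)
        results = {}
        for direction in cfg.directions:
            result = rad.radiate(state["view"], sources, direction)
            path = out / f"radiate_{direction}.tsv"
            _write_radiate_tsv(result, state["view"], path)
            report["artifacts"][f"radiate_{direction}"] = str(path)
            results[direction] = result
        state.update(sources=sources, radiate=results)
        return {"n_source_ids": len(stids), "n_source_nodes": len(sources)}

    @stage("rank")
    def _rank():
        result = state["radiate"].get(rad.FORWARD) or next(iter(state["radiate"].values()))
        ranked = [
            (nid, score, rank)
            for nid, score, rank in rad.rank_nodes(result, label_filter="Protein")
            if nid not in state["sources"]
        ][: cfg.top_k]
        path = out / "top_proteins.tsv"
        pd.DataFrame(
            [
                {
                    "node_id": nid,
                    "display_name": state["view"].nodes[nid].display_name,
                    "pagerank": f"{score:.12e}",
                    "rank": rank,
                }
                for nid, score, rank in ranked
            ],
            columns=["node_id", "display_name", "pagerank", "rank"],
        ).to_csv(path, sep="\t", index=False)
        report["artifacts"]["top_proteins"] = str(path)
        state["targets"] = [nid for nid, _, _ in ranked]
        state["genes"] = sorted(
            {state["view"].nodes[nid].display_name for nid in state["targets"]}
        )
        return {"top_k": cfg.top_k, "n_targets": len(state["targets"])}

    @stage("trace")
    def _trace():
        view = state["view"]
        info = {}
        state["traces"] = {}
        for mode in cfg.trace_modes:
            if mode == tr.HOPS:
                ps = tr.all_shortest_paths(view, state["sources"], set(state["targets"]))
            else:
                weighting = tr.influence_weights(view, state["radiate"][rad.FORWARD])
                ps = tr.highest_influence_paths(
                    view, weighting, state["sources"], set(state["targets"])
                )
            state["traces"][mode] = ps
            info[f"{mode}_paths"] = len(ps.paths)
            info[f"{mode}_unreachable"] = len(ps.unreachable)
        return info

    @stage("sankey")
    def _sankey():
        view = state["view"]
        edge_types = {(e.source, e.target): e.type for e in view.edges}
        names = {nid: n.display_name for nid, n in view.nodes.items()}
        info = {}
        for mode, ps in state["traces"].items():
            tg = tr.build_trace_graph(ps)
            path = out / f"sankey_{mode}.json"
            tr.export_sankey(tg, path, edge_types=edge_types, names=names)
            report["artifacts"][f"sankey_{mode}"] = str(path)
            info[f"{mode}_nodes"] = tg.n_nodes
            info[f"{mode}_links"] = tg.n_edges
        return info

    @stage("enrichment_table")
    def _table():
        table = enr.EnrichmentTable.from_tsv(cfg.table)
        state["table"] = table
        return {"rows": len(table.rows)}

    @stage("go_enrichment")
    def _enrich():
        ann = enr.AnnotationSet.from_tsv(cfg.annotations, term_names=cfg.term_names)
        rows = enr.go_enrichment(state["genes"], ann, alpha=cfg.alpha)
        path = out / "go_enrichment.tsv"
        enr.enrichment_to_frame(rows).to_csv(path, sep="\t", index=False)
        report["artifacts"]["go_enrichment"] = str(path)
        state["enrichment"] = rows
        return {
            "tested_terms": len(rows),
            "significant": sum(r.significant for r in rows),
        }

    @stage("entity_cloud")
    def _cloud():
        dictionary = enr.Dictionary.from_tsv(cfg.dictionary)
        state["dictionary"] = dictionary
        cloud = enr.entity_cloud(
            state["table"].texts(state["genes"]), dictionary, entity_type="gene"
        )
        path = out / "entity_cloud.json"
        path.write_text(json.dumps(cloud, indent=2) + "\n")
        report["artifacts"]["entity_cloud"] = str(path)
        return {"n_concepts": len(cloud)}

    if cfg.semantic_iterations >= 1:

        @stage("semantic_expansion")
        def _expand():
            expanded = enr.semantic_expand(
                state["genes"],
                state["table"],
                state["dictionary"],
                iterations=cfg.semantic_iterations,
            )
            path = out / "expanded_genes.txt"
            path.write_text("\n".join(sorted(expanded)) + "\n")
            report["artifacts"]["expanded_genes"] = str(path)
            return {"seed_genes": len(state["genes"]), "expanded_genes": len(expanded)}

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
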