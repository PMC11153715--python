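"""Property-graph model, IO and Reactome-style preprocessing.

The graph is a directed multigraph of typed nodes (entities, reactions,
pathways) and typed edges.  Sub-cellular compartments and species are node
properties rather than separate nodes, and ubiquitous "currency" compounds
(ATP, H+, ...) can be flagged so traversal views exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Edge types the graph algorithms are allowed to traverse.  The concrete
#: production list is deployment-specific; this default covers the standard
#: Reactome schema relations and is overridable via PreprocessConfig.
DEFAULT_TRAVERSABLE_EDGE_TYPES = frozenset(
    {
        "input",
        "output",
        "catalyst",
        "activeUnit",
        "regulator",
        "positivelyRegulates",
        "negativelyRegulates",
        "hasComponent",
        "hasMember",
        "hasCandidate",
        "hasEvent",
        "referenceEntity",
    }
)

#: Ubiquitous compounds whose hub connectivity creates spurious shortcuts,
#: plus the regulatory protein ubiquitin.  Matched case-insensitively
#: against display names; overridable via PreprocessConfig.
DEFAULT_CURRENCY_NAMES = frozenset(
    {
        "atp",
        "adp",
        "amp",
        "gtp",
        "gdp",
        "nad+",
        "nadh",
        "nadp+",
        "nadph",
        "fad",
        "fadh2",
        "h+",
        "h2o",
        "o2",
        "co2",
        "phosphate",
        "pyrophosphate",
        "coa",
        "ubiquitin",
    }
)

DEFAULT_DROP_LABELS = frozenset({"Person", "Affiliation", "Taxon", "InstanceEdit"})

DEFAULT_COMPARTMENT = "extracellular region"

NODE_COLUMNS = ("id", "labels", "display_name", "compartments", "species", "is_currency")
EDGE_COLUMNS = ("source", "target", "type")

LIST_SEP = ";"


class GraphFormatError(ValueError):
    """A node/edge table is missing a required column or is malformed."""


class ReferentialError(ValueError):
    """An edge references a node that does not exist."""


class NodeLookupError(KeyError):
    """None of the requested node identifiers resolve in the graph."""


@dataclass
class NodeRecord:
    """A typed graph node.

    ``id`` follows the Reactome stable-identifier convention; compartment
    variants of the same entity use dotted suffixes (``R-ALL-123.cyto``).
    """

    id: str
    labels: frozenset[str]
    display_name: str = ""
    compartments: tuple[str, ...] = ()
    species: str = ""
    is_currency: bool = False

    def __post_init__(self) -> None:
        self.labels = frozenset(self.labels)
        self.compartments = tuple(self.compartments)
        if not self.labels:
            raise ValueError(f"node {self.id!r}: labels must be non-empty")


@dataclass(frozen=True)
class EdgeRecord:
    """A typed directed edge."""

    source: str
    target: str
    type: str

    def __post_init__(self) -> None:
        if not self.type:
            raise ValueError(f"edge {self.source!r}->{self.target!r}: empty type")

    def reversed(self) -> "EdgeRecord":
        return EdgeRecord(self.target, self.source, self.type)


@dataclass
class PropertyGraph:
    """Directed multigraph with typed, attributed nodes and edges.

    Parallel edges between the same ordered node pair are allowed when
    their types differ; ``(source, target, type)`` triples are unique.
    """

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: list[EdgeRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict, compare=False)

    # -- construction -------------------------------------------------

    def add_node(self, node: NodeRecord) -> None:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: EdgeRecord) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise ReferentialError(
                    f"edge {edge.source!r}-[{edge.type}]->{edge.target!r} "
                    f"references unknown node {endpoint!r}"
                )
        key = (edge.source, edge.target, edge.type)
        if key in self._edge_keys():
            raise ValueError(f"duplicate edge {key!r}")
        self.edges.append(edge)

    def _edge_keys(self) -> set[tuple[str, str, str]]:
        return {(e.source, e.target, e.type) for e in self.edges}

    def validate(self) -> None:
        """Raise if the graph violates its invariants."""
        keys = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise ReferentialError(
                        f"edge {e.source!r}-[{e.type}]->{e.target!r} "
                        f"references unknown node {endpoint!r}"
                    )
            key = (e.source, e.target, e.type)
            if key in keys:
                raise ValueError(f"duplicate edge {key!r}")
            keys.add(key)

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_edges(self, node_id: str) -> list[EdgeRecord]:
        return [e for e in self.edges if e.source == node_id]

    def copy(self) -> "PropertyGraph":
        g = PropertyGraph(
            nodes={nid: replace(n) for nid, n in self.nodes.items()},
            edges=list(self.edges),
            meta=dict(self.meta),
        )
        return g

    def reverse(self) -> "PropertyGraph":
        """Return a copy with every edge direction flipped."""
        g = self.copy()
        g.edges = [e.reversed() for e in self.edges]
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PropertyGraph):
            return NotImplemented
        return self.nodes == other.nodes and sorted(
            self.edges, key=lambda e: (e.source, e.target, e.type)
        ) == sorted(other.edges, key=lambda e: (e.source, e.target, e.type))

    # -- conversion ---------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid, node in self.nodes.items():
            g.add_node(
                nid,
                labels=sorted(node.labels),
                display_name=node.display_name,
                compartments=list(node.compartments),
                species=node.species,
                is_currency=node.is_currency,
            )
        for e in self.edges:
            g.add_edge(e.source, e.target, key=e.type, type=e.type)
        return g

    def to_digraph(self) -> nx.DiGraph:
        """Collapse parallel edges; ``multiplicity`` counts collapsed edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if g.has_edge(e.source, e.target):
                g[e.source][e.target]["multiplicity"] += 1
            else:
                g.add_edge(e.source, e.target, multiplicity=1)
        return g


@dataclass
class PreprocessConfig:
    """Rules applied by :func:`preprocess_pathway_graph`."""

    drop_labels: frozenset[str] = DEFAULT_DROP_LABELS
    keep_species: str = "Homo sapiens"
    reverse_edge_types: frozenset[str] = frozenset()
    #: each rule: {"type": <existing edge type>, "new_type": str, "reverse": bool}
    add_edge_rules: list[dict] = field(default_factory=list)
    currency_names: frozenset[str] = DEFAULT_CURRENCY_NAMES
    traversable_edge_types: frozenset[str] = DEFAULT_TRAVERSABLE_EDGE_TYPES

    def __post_init__(self) -> None:
        self.drop_labels = frozenset(self.drop_labels)
        self.reverse_edge_types = frozenset(self.reverse_edge_types)
        self.currency_names = frozenset(n.lower() for n in self.currency_names)
        self.traversable_edge_types = frozenset(self.traversable_edge_types)
        if not self.traversable_edge_types:
            raise ValueError("traversable_edge_types must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "drop_labels",
            "keep_species",
            "reverse_edge_types",
            "add_edge_rules",
            "currency_names",
            "traversable_edge_types",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# IO


def read_graph(node_table: str | Path, edge_table: str | Path) -> PropertyGraph:
    """Load a property graph from node/edge TSV tables.

    List-valued columns (``labels``, ``compartments``) are ``;``-separated.
    Raises :class:`GraphFormatError` on missing columns and
    :class:`ReferentialError` on dangling edge endpoints.
    """
    nodes_df = pd.read_csv(node_table, sep="\t", dtype=str, keep_default_na=False)
    edges_df = pd.read_csv(edge_table, sep="\t", dtype=str, keep_default_na=False)
    for col in NODE_COLUMNS:
        if col not in nodes_df.columns:
            raise GraphFormatError(f"node table {node_table}: missing column {col!r}")
    for col in EDGE_COLUMNS:
        if col not in edges_df.columns:
            raise GraphFormatError(f"edge table {edge_table}: missing column {col!r}")

    g = PropertyGraph()
    for row in nodes_df.itertuples(index=False):
        g.add_node(
            NodeRecord(
                id=row.id,
                labels=frozenset(x for x in row.labels.split(LIST_SEP) if x),
                display_name=row.display_name,
                compartments=tuple(x for x in row.compartments.split(LIST_SEP) if x),
                species=row.species,
                is_currency=row.is_currency.strip().lower() in {"true", "1", "yes"},
            )
        )
    for row in edges_df.itertuples(index=False):
        g.add_edge(EdgeRecord(source=row.source, target=row.target, type=row.type))
    return g


def write_graph(g: PropertyGraph, node_table: str | Path, edge_table: str | Path) -> None:
    """Write node/edge TSV tables, deterministically ordered by id."""
    node_rows = [
        {
            "id": n.id,
            "labels": LIST_SEP.join(sorted(n.labels)),
            "display_name": n.display_name,
            "compartments": LIST_SEP.join(n.compartments),
            "species": n.species,
            "is_currency": str(n.is_currency).lower(),
        }
        for n in sorted(g.nodes.values(), key=lambda n: n.id)
    ]
    edge_rows = [
        {"source": e.source, "target": e.target, "type": e.type}
        for e in sorted(g.edges, key=lambda e: (e.source, e.target, e.type))
    ]
    pd.DataFrame(node_rows, columns=list(NODE_COLUMNS)).to_csv(
        node_table, sep="\t", index=False
    )
    pd.DataFrame(edge_rows, columns=list(EDGE_COLUMNS)).to_csv(
        edge_table, sep="\t", index=False
    )


def write_graphml(g: PropertyGraph, path: str | Path) -> None:
    mg = nx.MultiDiGraph()
    for nid, node in sorted(g.nodes.items()):
        mg.add_node(
            nid,
            labels=LIST_SEP.join(sorted(node.labels)),
            display_name=node.display_name,
            compartments=LIST_SEP.join(node.compartments),
            species=node.species,
            is_currency=node.is_currency,
        )
    for e in sorted(g.edges, key=lambda e: (e.source, e.target, e.type)):
        mg.add_edge(e.source, e.target, key=e.type, type=e.type)
    nx.write_graphml(mg, str(path))


def read_graphml(path: str | Path) -> PropertyGraph:
    mg = nx.read_graphml(str(path), force_multigraph=True)
    g = PropertyGraph()
    for nid, data in mg.nodes(data=True):
        g.add_node(
            NodeRecord(
                id=str(nid),
                labels=frozenset(x for x in data.get("labels", "").split(LIST_SEP) if x),
                display_name=data.get("display_name", ""),
                compartments=tuple(
                    x for x in data.get("compartments", "").split(LIST_SEP) if x
                ),
                species=data.get("species", ""),
                is_currency=bool(data.get("is_currency", False)),
            )
        )
    for u, v, data in mg.edges(data=True):
        g.add_edge(EdgeRecord(source=str(u), target=str(v), type=data["type"]))
    return g


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_pathway_graph(g: PropertyGraph, cfg: PreprocessConfig) -> PropertyGraph:
    """Apply the pathway-graph cleaning rules and return a new graph.

    Removes nodes carrying any dropped label, removes nodes of foreign
    species (nodes with an empty species string are kept), reverses the
    listed edge types, applies edge-addition rules, and flags currency
    nodes.  The result carries ``meta["preprocessed"] = True`` and a second
    application is a no-op, because edge reversal is an involution.
    """
    if g.meta.get("preprocessed"):
        return g.copy()

    out = PropertyGraph(meta=dict(g.meta))

    dropped_by_label = 0
    dropped_by_species = 0
    for node in g.nodes.values():
        if node.labels & cfg.drop_labels:
            dropped_by_label += 1
            continue
        if node.species and node.species != cfg.keep_species:
            dropped_by_species += 1
            continue
        out.add_node(replace(node))

    reversed_count = 0
    for e in g.edges:
        if e.source not in out.nodes or e.target not in out.nodes:
            continue
        if e.type in cfg.reverse_edge_types:
            out.add_edge(e.reversed())
            reversed_count += 1
        else:
            out.add_edge(e)

    added = 0
    for rule in cfg.add_edge_rules:
        match_type = rule["type"]
        new_type = rule["new_type"]
        flip = bool(rule.get("reverse", False))
        for e in list(out.edges):
            if e.type != match_type:
                continue
            new = EdgeRecord(e.target, e.source, new_type) if flip else EdgeRecord(
                e.source, e.target, new_type
            )
            if (new.source, new.target, new.type) not in out._edge_keys():
                out.add_edge(new)
                added += 1

    out = label_currency_nodes(out, cfg.currency_names)
    out.meta["preprocessed"] = True

    logger.info(
        "preprocess: dropped %d nodes by label, %d by species; reversed %d edges; "
        "added %d edges; kept %d nodes / %d edges",
        dropped_by_label,
        dropped_by_species,
        reversed_count,
        added,
        out.n_nodes,
        out.n_edges,
    )
    if out.n_nodes == 0:
        logger.warning("preprocess: resulting graph is empty")
    return out


def label_currency_nodes(g: PropertyGraph, currency_names: Iterable[str]) -> PropertyGraph:
    """Flag nodes whose display name matches a currency name (case-insensitive)."""
    names = {n.lower() for n in currency_names}
    out = g.copy()
    flagged = 0
    for node in out.nodes.values():
        if node.display_name.lower() in names:
            node.is_currency = True
            flagged += 1
    logger.info("currency labeling: flagged %d nodes", flagged)
    return out


def traversal_view(
    g: PropertyGraph, cfg: PreprocessConfig, exclude_currency: bool = True
) -> PropertyGraph:
    """Subgraph restricted to traversable edge types.

    With ``exclude_currency`` (the default), flagged currency nodes and all
    their incident edges are removed, so no analysis path can run through
    them.  The input graph is left unmodified.
    """
    out = PropertyGraph(meta=dict(g.meta))
    for node in g.nodes.values():
        if exclude_currency and node.is_currency:
            continue
        out.add_node(replace(node))
    for e in g.edges:
        if e.type not in cfg.traversable_edge_types:
            continue
        if e.source in out.nodes and e.target in out.nodes:
            out.add_edge(e)
    return out


# ---------------------------------------------------------------------------
# Node lookup


def _matches(node_id: str, st_id: str) -> bool:
    # compartment variants use dotted suffixes on the base identifier
    return node_id == st_id or node_id.startswith(st_id + ".")


def find_nodes(
    g: PropertyGraph,
    ids: Sequence[str],
    compartment: str = DEFAULT_COMPARTMENT,
) -> set[str]:
    """Resolve stable identifiers to node ids, preferring a compartment.

    When an identifier matches several compartment-specific instances the
    ones located in ``compartment`` (exact lowercase match against any of a
    node's compartments) are preferred; otherwise all instances are
    returned with a compartment-mismatch warning.  Unresolved identifiers
    are logged; if nothing resolves a :class:`NodeLookupError` is raised.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    want = compartment.lower()
    resolved: set[str] = set()
    unresolved: list[str] = []
    for st_id in ids:
        candidates = sorted(nid for nid in g.nodes if _matches(nid, st_id))
        if not candidates:
            unresolved.append(st_id)
            continue
        in_compartment = [
            nid
            for nid in candidates
            if any(c.lower() == want for c in g.nodes[nid].compartments)
        ]
        if in_compartment:
            resolved.update(in_compartment)
        else:
            logger.warning(
                "find_nodes: %r has no instance in compartment %r; "
                "returning %d other instance(s)",
                st_id,
                compartment,
                len(candidates),
            )
            resolved.update(candidates)
    if unresolved:
        logger.warning("find_nodes: unresolved ids: %s", ", ".join(unresolved))
    if not resolved:
        raise NodeLookupError(f"none of the requested ids resolve: {list(ids)}")
    return resolved
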