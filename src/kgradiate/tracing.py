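"""Source→target path tracing, trace graphs, and Sankey export.

Two path criteria are supported: minimum hop count (all shortest paths on
the unweighted traversal view) and highest influence (minimum sum of
inverse-PPR edge weights).  The union of the selected paths forms a trace
graph whose edges count how many paths traverse them; the trace graph
serializes to an index-based nodes/links Sankey JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from kgradiate.graph import PropertyGraph
from kgradiate.radiate import PPRConfig, RadiateResult

logger = logging.getLogger(__name__)

HOPS = "hops"
INFLUENCE = "influence"

DEFAULT_MAX_PATHS = 10_000
DEFAULT_REL_TOL = 1e-9


@dataclass
class InfluenceWeighting:
    """Edge weights ``w(u,v) = 1 / max(π(u), π(v), epsilon_floor)``."""

    weights: dict[tuple[str, str], float]

    def validate(self) -> None:
        for key, w in self.weights.items():
            if not (w > 0 and w < float("inf")):
                raise ValueError(f"weight for {key!r} not finite positive: {w!r}")


@dataclass
class PathSet:
    mode: str  # hops | influence
    paths: list[tuple[str, ...]]
    costs: list[float]
    unreachable: set[tuple[str, str]] = field(default_factory=set)
    truncated: bool = False


@dataclass
class TraceGraph:
    #: node id → role, one of source | target | intermediate
    roles: dict[str, str]
    #: (u, v) → number of paths traversing the edge
    traversal_counts: dict[tuple[str, str], int]

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.traversal_counts)


def _check_endpoints(g: PropertyGraph, sources, targets) -> None:
    if not sources or not targets:
        raise ValueError("sources and targets must be non-empty")
    missing = (set(sources) | set(targets)) - g.nodes.keys()
    if missing:
        raise KeyError(f"nodes not in traversal view: {sorted(missing)}")


def all_shortest_paths(
    g: PropertyGraph,
    sources: set[str],
    targets: set[str],
    max_paths: int = DEFAULT_MAX_PATHS,
) -> PathSet:
    """All minimum-hop directed paths for every (source, target) pair.

    Unreachable pairs are recorded in ``unreachable`` rather than raised.
    Per-pair enumeration stops at ``max_paths`` with the truncation flag
    set; truncation is never silent.
    """
    _check_endpoints(g, sources, targets)
    dg = g.to_digraph()
    ps = PathSet(mode=HOPS, paths=[], costs=[])
    for s in sorted(sources):
        for t in sorted(targets):
            try:
                gen = nx.all_shortest_paths(dg, s, t)
                count = 0
                for path in gen:
                    if count >= max_paths:
                        ps.truncated = True
                        logger.warning(
                            "all_shortest_paths: truncated at %d paths for (%s, %s)",
                            max_paths, s, t,
                        )
                        break
                    ps.paths.append(tuple(path))
                    ps.costs.append(float(len(path) - 1))
                    count += 1
            except nx.NetworkXNoPath:
                ps.unreachable.add((s, t))
    return ps


def influence_weights(
    g: PropertyGraph, r: RadiateResult, cfg: PPRConfig | None = None
) -> InfluenceWeighting:
    """Inverse-max-PPR weighting of every edge of the traversal view."""
    if cfg is None:
        cfg = PPRConfig()
    missing = g.nodes.keys() - r.scores.keys()
    if missing:
        raise ValueError(f"radiate result lacks scores for: {sorted(missing)[:5]}")
    weights: dict[tuple[str, str], float] = {}
    for e in g.edges:
        pi = max(r.scores[e.source], r.scores[e.target], cfg.epsilon_floor)
        weights[(e.source, e.target)] = 1.0 / pi
    return InfluenceWeighting(weights=weights)


def _near_minimal_paths(
    dg: nx.DiGraph,
    s: str,
    t: str,
    rel_tol: float,
    max_paths: int,
) -> tuple[list[tuple[str, ...]], list[float], bool, bool]:
    """All simple s→t paths with weight within rel_tol of the minimum.

    Depth-first search pruned by exact shortest-distance-to-target
    (Dijkstra on the reversed graph), so only near-optimal prefixes are
    expanded.
    """
    try:
        dist_to_t = nx.single_source_dijkstra_path_length(
            dg.reverse(copy=False), t, weight="weight"
        )
    except nx.NodeNotFound:
        return [], [], True, False
    if s not in dist_to_t:
        return [], [], True, False
    best = dist_to_t[s]
    bound = best * (1.0 + rel_tol) + 1e-300

    paths: list[tuple[str, ...]] = []
    costs: list[float] = []
    truncated = False
    stack: list[tuple[str, tuple[str, ...], float]] = [(s, (s,), 0.0)]
    while stack:
        node, prefix, cost = stack.pop()
        if node == t:
            if len(paths) >= max_paths:
                truncated = True
                break
            paths.append(prefix)
            costs.append(cost)
            continue
        for _, v, w in dg.out_edges(node, data="weight"):
            if v in prefix:
                continue
            new_cost = cost + w
            if v in dist_to_t and new_cost + dist_to_t[v] <= bound:
                stack.append((v, prefix + (v,), new_cost))
    order = sorted(range(len(paths)), key=lambda i: (costs[i], paths[i]))
    return [paths[i] for i in order], [costs[i] for i in order], False, truncated


def highest_influence_paths(
    g: PropertyGraph,
    weighting: InfluenceWeighting,
    sources: set[str],
    targets: set[str],
    rel_tol: float = DEFAULT_REL_TOL,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> PathSet:
    """All paths whose weight sum is within ``rel_tol`` of the per-pair minimum.

    Weighted shortest paths need a tie tolerance because edge weights are
    floating point; the tolerance is relative to the minimum weight sum.
    """
    _check_endpoints(g, sources, targets)
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    for (u, v), w in weighting.weights.items():
        dg.add_edge(u, v, weight=w)
    ps = PathSet(mode=INFLUENCE, paths=[], costs=[])
    for s in sorted(sources):
        for t in sorted(targets):
            paths, costs, unreachable, truncated = _near_minimal_paths(
                dg, s, t, rel_tol, max_paths
            )
            if unreachable:
                ps.unreachable.add((s, t))
                continue
            ps.paths.extend(paths)
            ps.costs.extend(costs)
            if truncated:
                ps.truncated = True
                logger.warning(
                    "highest_influence_paths: truncated at %d paths for (%s, %s)",
                    max_paths, s, t,
                )
    return ps


def build_trace_graph(p: PathSet) -> TraceGraph:
    """Union of all paths with node roles and per-edge traversal counts."""
    if not p.paths:
        logger.warning("build_trace_graph: empty path set")
        return TraceGraph(roles={}, traversal_counts={})
    sources = {path[0] for path in p.paths}
    targets = {path[-1] for path in p.paths}
    roles: dict[str, str] = {}
    counts: dict[tuple[str, str], int] = {}
    for path in p.paths:
        for node in path:
            if node in sources:
                roles[node] = "source"
            elif node in targets:
                roles[node] = "target"
            else:
                roles[node] = "intermediate"
        for u, v in zip(path, path[1:]):
            counts[(u, v)] = counts.get((u, v), 0) + 1
    roles = dict(sorted(roles.items()))
    counts = dict(sorted(counts.items()))
    return TraceGraph(roles=roles, traversal_counts=counts)


def export_sankey(
    tg: TraceGraph,
    out: str | Path,
    edge_types: dict[tuple[str, str], str] | None = None,
    names: dict[str, str] | None = None,
) -> dict:
    """Write the trace graph as index-based Sankey JSON.

    ``nodes`` is a sorted list of ``{id, name, role}``; ``links`` reference
    node indices and carry the traversal count as ``value``.  Output is
    byte-stable for a given trace.
    """
    node_ids = sorted(tg.roles)
    index = {nid: i for i, nid in enumerate(node_ids)}
    doc = {
        "nodes": [
            {
                "id": nid,
                "name": (names or {}).get(nid, nid),
                "role": tg.roles[nid],
            }
            for nid in node_ids
        ],
        "links": [
            {
                "source_index": index[u],
                "target_index": index[v],
                "value": count,
                "edge_type": (edge_types or {}).get((u, v), ""),
            }
            for (u, v), count in sorted(tg.traversal_counts.items())
        ],
    }
    Path(out).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc
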