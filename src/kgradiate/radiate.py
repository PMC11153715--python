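"""Forward and reverse radiate analysis (personalized PageRank).

Ranks every node of a traversal view by its personalized PageRank with
the teleport vector uniform over a source set.  Forward analysis follows
edge directions as-is ("which nodes are influenced by the sources?");
reverse analysis flips every edge before the computation ("which nodes
influence the sources?").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from kgradiate.graph import PropertyGraph

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


class UnknownSourceError(KeyError):
    """A requested source node is not present in the graph."""


@dataclass
class PPRConfig:
    damping: float = 0.85
    tol: float = 1e-10  # L1 change between iterations
    max_iter: int = 1000
    epsilon_floor: float = 1e-12  # smallest usable score for weighting

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class RadiateResult:
    direction: str
    sources: frozenset[str]
    scores: dict[str, float]
    converged: bool
    iterations: int
    node_labels: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scores sum to {total!r}, expected 1")
        if any(v < 0 for v in self.scores.values()):
            raise ValueError("negative score")
        if not self.sources <= self.scores.keys():
            raise ValueError("sources must be score keys")


def _transition_matrix(g: PropertyGraph, order: list[str]) -> sparse.csr_matrix:
    """Row-stochastic transition matrix; dangling rows are left all-zero.

    Parallel edges between the same ordered pair collapse to a single
    transition with weight proportional to their multiplicity.
    """
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    dg = g.to_digraph()
    rows, cols, vals = [], [], []
    for u in order:
        out = list(dg.out_edges(u, data="multiplicity"))
        if not out:
            continue
        total = float(sum(m for _, _, m in out))
        for _, v, m in out:
            rows.append(index[u])
            cols.append(index[v])
            vals.append(m / total)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def radiate(
    g: PropertyGraph,
    sources: set[str] | frozenset[str],
    direction: str = FORWARD,
    cfg: PPRConfig | None = None,
) -> RadiateResult:
    """Personalized PageRank of every node with respect to ``sources``.

    The teleport vector is uniform over the sources, dangling-node mass is
    redistributed according to the teleport vector, and the converged
    scores are renormalized to sum exactly to 1.  ``direction="reverse"``
    runs the identical computation on the edge-reversed graph.
    """
    if cfg is None:
        cfg = PPRConfig()
    if direction not in (FORWARD, REVERSE):
        raise ValueError(f"direction must be {FORWARD!r} or {REVERSE!r}")
    if not sources:
        raise ValueError("sources must be non-empty")
    missing = set(sources) - g.nodes.keys()
    if missing:
        raise UnknownSourceError(f"sources not in graph: {sorted(missing)}")

    if direction == REVERSE:
        result = radiate(g.reverse(), sources, FORWARD, cfg)
        result.direction = REVERSE
        return result

    order = sorted(g.nodes)
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)

    p = np.zeros(n)
    p[[index[s] for s in sources]] = 1.0 / len(sources)

    P = _transition_matrix(g, order)
    dangling = np.asarray(P.sum(axis=1)).ravel() == 0.0
    d = cfg.damping

    x = p.copy()
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        dangling_mass = x[dangling].sum()
        x_new = d * (x @ P + dangling_mass * p) + (1.0 - d) * p
        if np.abs(x_new - x).sum() < cfg.tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        logger.warning("radiate: no convergence after %d iterations", cfg.max_iter)

    x = np.maximum(x, 0.0)
    x /= x.sum()  # absorb floating-point drift; PPR is stochastic already

    result = RadiateResult(
        direction=FORWARD,
        sources=frozenset(sources),
        scores={nid: float(x[index[nid]]) for nid in order},
        converged=converged,
        iterations=iterations,
        node_labels={nid: g.nodes[nid].labels for nid in order},
    )
    return result


def rank_nodes(
    r: RadiateResult,
    label_filter: str | None = None,
    top_k: int | None = None,
) -> list[tuple[str, float, int]]:
    """Ranked ``(node_id, score, rank)`` list, descending by score.

    Ties break by ascending node id.  ``label_filter`` restricts the list
    to nodes carrying that label (ranks are re-assigned after filtering);
    ``top_k`` truncates.
    """
    items = sorted(r.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if label_filter is not None:
        items = [
            (nid, s) for nid, s in items if label_filter in r.node_labels.get(nid, ())
        ]
    ranked = [(nid, score, i + 1) for i, (nid, score) in enumerate(items)]
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked
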