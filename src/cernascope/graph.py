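"""PPI graph handling: score filtering, degree hubs, k-cores and MCODE.

The dense-module detector follows the molecular-complex-detection (MCODE)
scheme: every node is weighted by the density of the highest k-core of its
closed neighborhood times that core's k; complexes are grown greedily from
the highest-weight unseen seed, admitting neighbors whose weight is at least
``seed_weight * (1 - node_score_cutoff)``; modules lacking a k-core of the
configured k are discarded and a haircut removes singly-connected members.
Module score is density x size. All tie-breaks are lexicographic on node id
so module membership is reproducible regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from ._util import read_tsv
from .cerna import HubSet, rank_by_degree


def load_ppi(edges, min_score: float = 0.7) -> nx.Graph:
    """Build the scored PPI graph, keeping edges with score >= ``min_score``.

    ``edges`` is a path to a TSV (gene_a, gene_b, combined_score) or an
    iterable of such rows. Self-loops are dropped; duplicate edges are merged
    keeping the maximum score; a score outside [0, 1] raises with its row
    number.
    """
    if isinstance(edges, (str, Path)):
        df = read_tsv(edges)
        rows = list(df[["gene_a", "gene_b", "combined_score"]].itertuples(index=False))
    elif isinstance(edges, pd.DataFrame):
        rows = list(edges[["gene_a", "gene_b", "combined_score"]].itertuples(index=False))
    else:
        rows = list(edges)
    g = nx.Graph()
    for i, (a, b, score) in enumerate(rows, start=1):
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"row {i}: combined score {score} outside [0, 1]")
        if a == b:
            continue
        if score < min_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    return g


def degree_hubs(graph: nx.Graph, threshold: float = 20, comparator: str = ">",
                top_n: int | None = None) -> HubSet:
    """Degree-ranked hub genes; supports strict '>' and inclusive '>='.

    ``top_n`` optionally truncates the ranked list after thresholding.
    """
    degrees = dict(graph.degree())
    hubs = rank_by_degree(degrees, sorted(graph.nodes), threshold, comparator)
    if top_n is not None:
        hubs.members = hubs.members[:top_n]
    return hubs


def k_core(graph: nx.Graph) -> dict:
    """Core number of every node (standard iterative-pruning decomposition)."""
    return dict(nx.core_number(graph))


def _max_core_subgraph(graph: nx.Graph) -> tuple[nx.Graph, int]:
    """The highest k-core of ``graph`` and its k (k=0 for edgeless graphs)."""
    if graph.number_of_nodes() == 0:
        return graph.copy(), 0
    cores = nx.core_number(graph)
    k = max(cores.values())
    nodes = [n for n, c in cores.items() if c == k]
    return graph.subgraph(nodes).copy(), k


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def mcode_weights(graph: nx.Graph) -> pd.DataFrame:
    """Per-node MCODE vertex weighting.

    For each node the closed neighborhood graph is built, its highest k-core
    found, and the weight is that core's density times k. Isolated nodes get
    weight 0. Returns a DataFrame indexed by node with columns
    ``k`` (core number of the neighborhood core), ``core_density``, ``weight``.
    """
    rows = []
    for node in sorted(graph.nodes):
        closed = list(graph.neighbors(node)) + [node]
        sub = graph.subgraph(closed)
        core, k = _max_core_subgraph(sub)
        density = _density(core)
        rows.append((node, k, density, k * density))
    return pd.DataFrame(rows, columns=["node", "k", "core_density", "weight"]
                        ).set_index("node")


@dataclass(frozen=True)
class MCODEModule:
    """A detected dense module; ``score`` = subgraph density x size."""

    members: tuple  # sorted node ids
    seed_node: str
    score: float
    density: float

    @property
    def size(self) -> int:
        return len(self.members)


def mcode_modules(graph: nx.Graph, degree_cutoff: int = 2,
                  node_score_cutoff: float = 0.2, k_core: int = 2,
                  max_depth: int = 100, haircut: bool = True,
                  fluff: bool = False, fluff_density: float = 0.2
                  ) -> list[MCODEModule]:
    """Seed-and-grow dense-module detection.

    Nodes with degree below ``degree_cutoff`` never seed a module. Each module
    is grown breadth-first from the highest-weight unseen seed up to
    ``max_depth``, admitting unseen neighbors with weight >=
    ``seed_weight * (1 - node_score_cutoff)``. Grown node sets lacking a
    k-core of the configured k are discarded (their nodes stay visited, so
    every node belongs to at most one module). ``haircut`` removes
    singly-connected members in one pass; ``fluff`` optionally adds boundary
    neighbors whose closed-neighborhood density exceeds ``fluff_density``
    (fluffed nodes may be shared between modules). Modules are returned
    sorted by score desc, size desc, seed id asc.
    """
    weights = mcode_weights(graph)["weight"].to_dict()
    seeds = sorted((n for n in graph.nodes if graph.degree(n) >= degree_cutoff),
                   key=lambda n: (-weights[n], n))
    seen: set = set()
    modules: list[MCODEModule] = []
    for seed in seeds:
        if seed in seen:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            node, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for nb in sorted(graph.neighbors(node)):
                if nb in seen or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    frontier.append((nb, depth + 1))
        seen |= members
        sub = graph.subgraph(members)
        cores = nx.core_number(sub)
        if not cores or max(cores.values()) < k_core:
            continue
        if haircut:
            keep = [n for n in members if sub.degree(n) >= 2]
            sub = graph.subgraph(keep)
        if fluff:
            extra = set()
            for node in list(sub.nodes):
                for nb in graph.neighbors(node):
                    if nb in sub or nb in extra:
                        continue
                    closed = list(graph.neighbors(nb)) + [nb]
                    if _density(graph.subgraph(closed)) > fluff_density:
                        extra.add(nb)
            sub = graph.subgraph(set(sub.nodes) | extra)
        if sub.number_of_nodes() < 2:
            continue
        density = _density(sub)
        modules.append(MCODEModule(members=tuple(sorted(sub.nodes)),
                                   seed_node=seed,
                                   score=density * sub.number_of_nodes(),
                                   density=density))
    modules.sort(key=lambda m: (-m.score, -m.size, m.seed_node))
    return modules


def modules_frame(modules: list[MCODEModule]) -> pd.DataFrame:
    """Tabular module export: module_id, score, size, seed, members."""
    return pd.DataFrame({
        "module_id": [i + 1 for i in range(len(modules))],
        "score": [m.score for m in modules],
        "size": [m.size for m in modules],
        "seed": [m.seed_node for m in modules],
        "members": [",".join(m.members) for m in modules],
    })
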