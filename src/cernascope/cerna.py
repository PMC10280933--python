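"""Assembly and interrogation of the lncRNA-miRNA-mRNA (ceRNA) network.

A ceRNA triple (l, m, g) asserts that lncRNA l and mRNA g are co-expressed
and share miRNA m as a predicted binding partner: (l, g) must be a retained
co-expression pair, (l, m) a lncRNA->miRNA interaction, and (m, g) a
miRNA->mRNA interaction. The network is the union of all triples' nodes and
edges; it is tripartite with only lncRNA-miRNA and miRNA-mRNA edges (the
co-expression relation is a selection criterion, not an edge). Degree counts
incident edges, so a lncRNA's degree equals its number of distinct mediating
miRNAs — the quantity the hub gate (degree > 20) is applied to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from ._util import read_tsv, write_tsv

log = logging.getLogger(__name__)

_VALID_KINDS = {("lncRNA", "miRNA"), ("miRNA", "mRNA")}


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a (source_id, target_id, source_type, target_type) table.

    Duplicate rows are silently de-duplicated with a logged count; type pairs
    other than lncRNA->miRNA / miRNA->mRNA are rejected.
    """
    df = read_tsv(path, dtype=str)
    required = ["source_id", "target_id", "source_type", "target_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    kinds = set(zip(df["source_type"], df["target_type"]))
    bad = kinds - _VALID_KINDS
    if bad:
        raise ValueError(f"{path}: unsupported interaction types {sorted(bad)}")
    n0 = len(df)
    df = df.drop_duplicates(required).reset_index(drop=True)
    if len(df) < n0:
        log.info("%s: dropped %d duplicate interaction rows", path, n0 - len(df))
    return df


@dataclass(frozen=True)
class CeRNANetwork:
    """Tripartite network defined entirely by its supporting triples."""

    triples: frozenset  # of (lncrna_id, mirna_id, mrna_id)
    node_attrs: dict = field(default_factory=dict, compare=False)

    @property
    def lncrna_nodes(self) -> frozenset:
        return frozenset(t[0] for t in self.triples)

    @property
    def mirna_nodes(self) -> frozenset:
        return frozenset(t[1] for t in self.triples)

    @property
    def mrna_nodes(self) -> frozenset:
        return frozenset(t[2] for t in self.triples)

    @property
    def lnc_mir_edges(self) -> frozenset:
        return frozenset((l, m) for l, m, _ in self.triples)

    @property
    def mir_mrna_edges(self) -> frozenset:
        return frozenset((m, g) for _, m, g in self.triples)

    @property
    def edges(self) -> frozenset:
        return self.lnc_mir_edges | self.mir_mrna_edges

    @property
    def n_edges(self) -> int:
        return len(self.lnc_mir_edges) + len(self.mir_mrna_edges)

    def node_type(self, node: str) -> str:
        if node in self.lncrna_nodes:
            return "lncRNA"
        if node in self.mirna_nodes:
            return "miRNA"
        return "mRNA"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in sorted(self.lncrna_nodes | self.mirna_nodes | self.mrna_nodes):
            g.add_node(node, node_type=self.node_type(node),
                       direction=self.node_attrs.get(node, ""))
        for u, v in sorted(self.edges):
            g.add_edge(u, v)
        return g


@dataclass
class HubSet:
    """Degree-ranked nodes passing a threshold; ordering is deterministic."""

    members: list  # of (node_id, degree), degree desc then id asc
    threshold: float
    comparator: str  # ">" or ">="

    @property
    def ids(self) -> list:
        return [node for node, _ in self.members]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.members, columns=["node_id", "degree"])


def _compare(degree: int, threshold: float, comparator: str) -> bool:
    if comparator == ">":
        return degree > threshold
    if comparator == ">=":
        return degree >= threshold
    raise ValueError(f"comparator must be '>' or '>=' (got {comparator!r})")


def rank_by_degree(degrees: dict, candidates, threshold: float,
                   comparator: str) -> HubSet:
    members = [(node, degrees[node]) for node in candidates
               if _compare(degrees[node], threshold, comparator)]
    members.sort(key=lambda kv: (-kv[1], kv[0]))
    return HubSet(members, threshold, comparator)


def assemble_cerna(pairs: pd.DataFrame, lnc_mir: pd.DataFrame,
                   mir_mrna: pd.DataFrame,
                   de_records: pd.DataFrame | None = None) -> CeRNANetwork:
    """Merge co-expression pairs with the two interaction tables into triples.

    A triple (l, m, g) is included iff (l, g) is a retained co-expression pair
    and both interactions (l, m) and (m, g) are present. The result is
    order-independent in all three inputs. An empty pair table yields an empty
    network with a warning.
    """
    if len(pairs) == 0:
        log.warning("no co-expression pairs; ceRNA network is empty")
        return CeRNANetwork(frozenset())
    mirs_of_lnc: dict[str, set] = {}
    for l, m in zip(lnc_mir["source_id"], lnc_mir["target_id"]):
        mirs_of_lnc.setdefault(l, set()).add(m)
    mirs_of_mrna: dict[str, set] = {}
    for m, g in zip(mir_mrna["source_id"], mir_mrna["target_id"]):
        mirs_of_mrna.setdefault(g, set()).add(m)

    triples = set()
    for l, g in zip(pairs["lncrna_id"], pairs["mrna_id"]):
        shared = mirs_of_lnc.get(l, set()) & mirs_of_mrna.get(g, set())
        triples.update((l, m, g) for m in shared)

    attrs: dict[str, str] = {}
    if de_records is not None:
        lookup = dict(zip(de_records["gene_id"], de_records["direction"]))
        for l, m, g in triples:
            attrs[l] = lookup.get(l, "")
            attrs[g] = lookup.get(g, "")
    return CeRNANetwork(frozenset(triples), attrs)


def node_degrees(network: CeRNANetwork) -> dict:
    """Incident-edge degree per node in the tripartite graph."""
    degrees: dict[str, int] = {}
    for u, v in network.edges:
        degrees[u] = degrees.get(u, 0) + 1
        degrees[v] = degrees.get(v, 0) + 1
    return degrees


def hub_lncrnas(network: CeRNANetwork, min_degree: float = 20,
                comparator: str = ">") -> HubSet:
    """LncRNA nodes whose degree clears the hub gate (default strict > 20)."""
    degrees = node_degrees(network)
    return rank_by_degree(degrees, sorted(network.lncrna_nodes),
                          min_degree, comparator)


def extract_subnetwork(network: CeRNANetwork, lncrna_ids) -> CeRNANetwork:
    """Restrict the network to triples whose lncRNA is in ``lncrna_ids``."""
    wanted = set(lncrna_ids)
    unknown = wanted - set(network.lncrna_nodes)
    if unknown:
        raise ValueError(f"unknown lncRNA ids: {sorted(unknown)}")
    triples = frozenset(t for t in network.triples if t[0] in wanted)
    attrs = {n: d for n, d in network.node_attrs.items()
             if any(n in (t[0], t[2]) for t in triples)}
    return CeRNANetwork(triples, attrs)


def core_mrnas(sets: dict) -> tuple[set, pd.DataFrame]:
    """Exact intersection of >= 2 named gene sets, plus a membership table.

    The membership table (one row per gene in the union, one boolean column
    per input set, plus ``in_all``) is the tabular equivalent of the Venn
    diagram used to call core genes.
    """
    if len(sets) < 2:
        raise ValueError("core_mrnas requires at least 2 named sets")
    named = {name: set(s) for name, s in sets.items()}
    if any(len(s) == 0 for s in named.values()):
        empty_names = [n for n, s in named.items() if not s]
        log.warning("empty input set(s) %s; intersection is empty", empty_names)
    core = set.intersection(*named.values())
    union = sorted(set.union(*named.values()))
    table = pd.DataFrame({"gene_id": union})
    for name, s in named.items():
        table[name] = [g in s for g in union]
    table["in_all"] = [g in core for g in union]
    return core, table


# --- import/export ------------------------------------------------------------

def write_triples(network: CeRNANetwork, path: str | Path) -> Path:
    df = pd.DataFrame(sorted(network.triples),
                      columns=["lncrna_id", "mirna_id", "mrna_id"])
    return write_tsv(df, path)


def read_triples(path: str | Path, node_attrs: dict | None = None) -> CeRNANetwork:
    df = read_tsv(path, dtype=str)
    triples = frozenset(zip(df["lncrna_id"], df["mirna_id"], df["mrna_id"]))
    return CeRNANetwork(triples, node_attrs or {})


def write_sif(network: CeRNANetwork, path: str | Path) -> Path:
    """Cytoscape simple-interaction format: source <tab> relation <tab> target."""
    path = Path(path)
    lines = [f"{l}\tlnc-mir\t{m}" for l, m in sorted(network.lnc_mir_edges)]
    lines += [f"{m}\tmir-mrna\t{g}" for m, g in sorted(network.mir_mrna_edges)]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_sif(path: str | Path) -> set:
    """Edges (source, relation, target) from a SIF file."""
    edges = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed SIF line: {line!r}")
        edges.add(tuple(parts))
    return edges


def write_graphml(network: CeRNANetwork, path: str | Path) -> Path:
    g = network.to_networkx()
    degrees = node_degrees(network)
    for node in g.nodes:
        g.nodes[node]["degree"] = degrees.get(node, 0)
    nx.write_graphml(g, str(path))
    return Path(path)
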