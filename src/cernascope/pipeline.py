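"""End-to-end orchestration: DE -> co-expression -> ceRNA -> graphs -> enrichment.

Every stage writes its table(s) under the output directory and records a
checksum of its inputs and parameters; a rerun with unchanged inputs reuses
the cached output byte-for-byte. With a fixed seed the whole bundle is
deterministic. The JSON summary only ever contains counts and lists that can
be re-derived from the stage files it points to.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cerna, coexpression, diffexpr, enrichment, graph
from ._util import sha256_file, sha256_text, write_json, write_tsv
from .matrix import read_expression

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and every stage threshold of the analysis."""

    matrix: str = ""
    samples: str = ""
    lnc_mir: str = ""
    mir_mrna: str = ""
    ppi: str = ""
    gmt: str = ""
    # DE gates
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    # co-expression gates
    r_min: float = 0.97
    p_max: float = 0.01
    use_absolute_r: bool = False
    # PPI / hub gates
    ppi_min_score: float = 0.7
    ppi_hub_degree: float = 20         # whole-PPI hubs, strict >
    ppi_hub_top_n: int | None = None
    cerna_ppi_hub_degree: float = 4    # ceRNA-PPI hubs, inclusive >=
    lnc_hub_degree: float = 20         # hub lncRNAs, strict >
    # MCODE
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    # enrichment
    ora_min_size: int = 5
    ora_max_size: int = 500
    gsea_n_perm: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name in ("matrix", "samples", "lnc_mir", "mir_mrna", "ppi", "gmt"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"{name} input not found: {path}")
        if not (0 <= self.alpha <= 1 and 0 <= self.p_max <= 1):
            raise ValueError("alpha and p_max must lie in [0, 1]")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [-1, 1]")
        if not 0 <= self.ppi_min_score <= 1:
            raise ValueError("ppi_min_score must lie in [0, 1]")


@dataclass
class ResultBundle:
    out_dir: Path
    summary: dict
    cache_hits: list = field(default_factory=list)

    def path(self, name: str) -> Path:
        return self.out_dir / name


class _StageCache:
    """Checksum-keyed reuse of stage outputs."""

    def __init__(self, out_dir: Path):
        self.path = out_dir / "cache.json"
        self.state = (json.loads(self.path.read_text())
                      if self.path.exists() else {})

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return (self.state.get(stage) == key
                and all(p.exists() for p in outputs))

    def record(self, stage: str, key: str) -> None:
        self.state[stage] = key
        write_json(self.state, self.path)


def _stage_key(config: PipelineConfig, files: list[str], params: list) -> str:
    parts = [sha256_file(f) for f in files if f] + [repr(params)]
    return sha256_text("|".join(parts))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ResultBundle:
    """Run every stage in dependency order and write the result bundle."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out)
    hits: list[str] = []

    def run_stage(stage, files, params, outputs, compute):
        key = _stage_key(config, files, params)
        paths = [out / o for o in outputs]
        if cache.fresh(stage, key, paths):
            hits.append(stage)
            log.info("stage %s: cache hit", stage)
            return
        log.info("stage %s: computing (params=%s)", stage, params)
        compute()
        cache.record(stage, key)

    # --- differential expression ---------------------------------------------
    matrix = read_expression(config.matrix, config.samples)
    run_stage(
        "de", [config.matrix, config.samples],
        [config.fc_up, config.fc_down, config.alpha], ["de.tsv"],
        lambda: write_tsv(diffexpr.differential_expression(
            matrix, config.fc_up, config.fc_down, config.alpha), out / "de.tsv"))
    de = pd.read_csv(out / "de.tsv", sep="\t")

    # --- co-expression ---------------------------------------------------------
    run_stage(
        "coexpr", [config.matrix, config.samples, str(out / "de.tsv")],
        [config.r_min, config.p_max, config.use_absolute_r],
        ["coexpression.tsv"],
        lambda: write_tsv(coexpression.coexpression_pairs(
            de, matrix, config.r_min, config.p_max, config.use_absolute_r),
            out / "coexpression.tsv"))
    pairs = pd.read_csv(out / "coexpression.tsv", sep="\t")

    # --- ceRNA assembly --------------------------------------------------------
    def _assemble():
        lnc_mir = cerna.read_interactions(config.lnc_mir)
        mir_mrna = cerna.read_interactions(config.mir_mrna)
        net = cerna.assemble_cerna(pairs, lnc_mir, mir_mrna, de_records=de)
        cerna.write_triples(net, out / "triples.tsv")
        cerna.write_sif(net, out / "cerna.sif")
        cerna.write_graphml(net, out / "cerna.graphml")
        hubs = cerna.hub_lncrnas(net, config.lnc_hub_degree, ">")
        write_tsv(hubs.to_frame(), out / "hub_lncrnas.tsv")

    run_stage(
        "cerna", [str(out / "coexpression.tsv"), config.lnc_mir, config.mir_mrna],
        [config.lnc_hub_degree],
        ["triples.tsv", "cerna.sif", "cerna.graphml", "hub_lncrnas.tsv"],
        _assemble)
    net = cerna.read_triples(out / "triples.tsv")
    hub_lnc = pd.read_csv(out / "hub_lncrnas.tsv", sep="\t")

    # --- PPI: whole-network hubs, MCODE modules, ceRNA-PPI hubs ----------------
    def _graphs():
        ppi = graph.load_ppi(config.ppi, config.ppi_min_score)
        hubs = graph.degree_hubs(ppi, config.ppi_hub_degree, ">",
                                 top_n=config.ppi_hub_top_n)
        write_tsv(hubs.to_frame(), out / "ppi_hubs.tsv")
        modules = graph.mcode_modules(
            ppi, degree_cutoff=config.mcode_degree_cutoff,
            node_score_cutoff=config.mcode_node_score_cutoff,
            k_core=config.mcode_k_core, max_depth=config.mcode_max_depth)
        write_tsv(graph.modules_frame(modules), out / "mcode_modules.tsv")
        sub = ppi.subgraph(n for n in ppi.nodes if n in net.mrna_nodes)
        cerna_hubs = graph.degree_hubs(sub, config.cerna_ppi_hub_degree, ">=")
        write_tsv(cerna_hubs.to_frame(), out / "cerna_ppi_hubs.tsv")

    run_stage(
        "graphs", [config.ppi, str(out / "triples.tsv")],
        [config.ppi_min_score, config.ppi_hub_degree, config.ppi_hub_top_n,
         config.cerna_ppi_hub_degree, config.mcode_degree_cutoff,
         config.mcode_node_score_cutoff, config.mcode_k_core,
         config.mcode_max_depth],
        ["ppi_hubs.tsv", "mcode_modules.tsv", "cerna_ppi_hubs.tsv"], _graphs)
    ppi_hubs = pd.read_csv(out / "ppi_hubs.tsv", sep="\t")
    cerna_ppi_hubs = pd.read_csv(out / "cerna_ppi_hubs.tsv", sep="\t")
    modules = pd.read_csv(out / "mcode_modules.tsv", sep="\t")

    # --- enrichment ------------------------------------------------------------
    def _enrich():
        collection = enrichment.read_gmt(config.gmt)
        universe = [g for g, b in zip(matrix.gene_ids, matrix.biotypes)
                    if b == "mRNA"]
        query = de.loc[(de["biotype"] == "mRNA") & (de["direction"] != "ns"),
                       "gene_id"]
        table = enrichment.ora(query, universe, collection,
                               config.ora_min_size, config.ora_max_size)
        write_tsv(table, out / "ora.tsv")
        mr = de[de["biotype"] == "mRNA"].sort_values(
            ["log2fc", "gene_id"], ascending=[False, True])
        ranked = list(mr["gene_id"])
        metric = mr["log2fc"].to_numpy()
        rows = []
        for name in sorted(collection):
            members = set(collection[name]) & set(ranked)
            if not (0 < len(members) < len(ranked)):
                continue
            res = enrichment.gsea_permutation_p(
                ranked, metric, members, n_perm=config.gsea_n_perm,
                seed=config.seed, set_name=name)
            rows.append((name, res.es, res.p, res.n_perm))
        write_tsv(pd.DataFrame(rows, columns=["set_name", "es", "p", "n_perm"]),
                  out / "gsea.tsv")

    run_stage(
        "enrich", [config.gmt, str(out / "de.tsv")],
        [config.ora_min_size, config.ora_max_size, config.gsea_n_perm,
         config.seed], ["ora.tsv", "gsea.tsv"], _enrich)
    ora_table = pd.read_csv(out / "ora.tsv", sep="\t")

    # --- core genes ------------------------------------------------------------
    def _core():
        named = {
            "cerna_mrnas": set(net.mrna_nodes),
            "cerna_ppi_hubs": set(cerna_ppi_hubs["node_id"].astype(str)),
            "ppi_hubs": set(ppi_hubs["node_id"].astype(str)),
        }
        if all(len(s) > 0 for s in named.values()):
            core, membership = cerna.core_mrnas(named)
        else:
            core, membership = set(), pd.DataFrame(
                columns=["gene_id", *named, "in_all"])
        write_tsv(membership, out / "core_membership.tsv")
        write_tsv(pd.DataFrame({"gene_id": sorted(core)}), out / "core_genes.tsv")

    run_stage(
        "core", [str(out / "triples.tsv"), str(out / "cerna_ppi_hubs.tsv"),
                 str(out / "ppi_hubs.tsv")], [],
        ["core_membership.tsv", "core_genes.tsv"], _core)
    core_genes = pd.read_csv(out / "core_genes.tsv", sep="\t")
    core_list = ([] if core_genes.empty
                 else sorted(core_genes["gene_id"].astype(str)))

    summary = {
        "config": dataclasses.asdict(config),
        "de": diffexpr.de_summary(de),
        "n_coexpression_pairs": int(len(pairs)),
        "cerna": {
            "n_lncrna": len(net.lncrna_nodes),
            "n_mirna": len(net.mirna_nodes),
            "n_mrna": len(net.mrna_nodes),
            "n_edges": net.n_edges,
            "n_triples": len(net.triples),
        },
        "hub_lncrnas": list(hub_lnc["node_id"].astype(str)) if len(hub_lnc) else [],
        "n_ppi_hubs": int(len(ppi_hubs)),
        "n_cerna_ppi_hubs": int(len(cerna_ppi_hubs)),
        "mcode_module_sizes": [int(s) for s in modules["size"]] if len(modules) else [],
        "core_genes": core_list,
        "top_ora_set": (str(ora_table.iloc[0]["set_name"])
                        if len(ora_table) else None),
    }
    bundle = ResultBundle(out_dir=out, summary=summary, cache_hits=hits)
    write_report(bundle, out / "summary.json")
    return bundle


def write_report(bundle: ResultBundle, path: str | Path) -> Path:
    """Machine-readable JSON summary plus a short human-readable text report."""
    path = Path(path)
    write_json(bundle.summary, path)
    s = bundle.summary
    lines = ["ceRNA pipeline summary", "======================"]
    for key, value in sorted(s.get("de", {}).items()):
        lines.append(f"dif genes {key}: {value}")
    lines.append(f"co-expression pairs: {s.get('n_coexpression_pairs', 0)}")
    c = s.get("cerna", {})
    lines.append("ceRNA network: "
                 f"{c.get('n_lncrna', 0)} lncRNAs, {c.get('n_mirna', 0)} miRNAs, "
                 f"{c.get('n_mrna', 0)} mRNAs, {c.get('n_edges', 0)} edges")
    lines.append(f"hub lncRNAs: {', '.join(s.get('hub_lncrnas', [])) or 'none'}")
    lines.append(f"MCODE module sizes: {s.get('mcode_module_sizes', [])}")
    lines.append(f"core genes: {', '.join(s.get('core_genes', [])) or 'none'}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path
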