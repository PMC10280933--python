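"""Enrichment statistics: hypergeometric over-representation and GSEA.

Over-representation analysis (ORA) tests each gene set for excess overlap
with a query list against a universe using the upper hypergeometric tail

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

with N the universe size, K the set size within the universe, n the query
size, and k the observed overlap. Benjamini-Hochberg adjustment is applied
across the tested sets of a collection.

The GSEA enrichment score is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum over a ranked gene list: hits increment by
|metric|^exponent normalized over the in-set total, misses decrement by
1/(N - N_set). Significance uses a gene-label permutation null (set
membership reshuffled) — with only four arrays per phenotype group the study
design admits too few label splits for phenotype permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# --- GMT ---------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict:
    """Parse a GMT file into an ordered {set_name: [genes]} mapping.

    Each line is ``name <tab> description <tab> gene1 <tab> gene2 ...``.
    Duplicate member genes within a set are collapsed (first occurrence kept);
    a duplicate set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, list] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = list(dict.fromkeys(g for g in fields[2:] if g))
        if not members:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
    return sets


def write_gmt(collection: dict, path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{name}\t{description}\t" + "\t".join(members)
             for name, members in collection.items()]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# --- ORA ---------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) for a draw of n from a universe of N with K marked."""
    if not 0 <= k <= min(K, n):
        raise ValueError("k must lie in [0, min(K, n)]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(query, universe, collection: dict, min_size: int = 5,
        max_size: int = 500) -> pd.DataFrame:
    """Over-representation of ``query`` in each collection set vs ``universe``.

    Query genes outside the universe are dropped with a warning. Sets whose
    intersection with the universe falls outside [min_size, max_size] are
    skipped. Returns records (set_name, N, K, n, k, p, q, fold_enrichment)
    ordered by p then name; q is BH-adjusted across the tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        log.warning("dropping %d query genes outside the universe", len(stray))
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        K = len(members)
        if K < min_size or K > max_size:
            continue
        k = len(members & query)
        p = hypergeom_tail(N, K, n, k)
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append((name, N, K, n, k, p, fold))
    out = pd.DataFrame(rows, columns=["set_name", "N", "K", "n", "k", "p",
                                      "fold_enrichment"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out = out[["set_name", "N", "K", "n", "k", "p", "q", "fold_enrichment"]]
    return out.sort_values(["p", "set_name"]).reset_index(drop=True)


# --- GSEA --------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    p: float
    n_perm: int
    seed: int


def _running_sums(metric_sorted: np.ndarray, hits: np.ndarray,
                  exponent: float) -> np.ndarray:
    """Weighted-KS running sums for one or many membership indicator rows.

    ``hits`` is boolean, shape (..., N); returns cumulative sums of the same
    shape. Misses decrement by 1/(N - N_set); hits increment by the in-set
    normalized |metric|^exponent.
    """
    hits = np.atleast_2d(hits)
    n_total = hits.shape[-1]
    n_hit = hits.sum(axis=-1, keepdims=True)
    if np.any(n_hit == 0) or np.any(n_hit == n_total):
        raise ValueError("gene set must hit a strict, non-empty subset of the "
                         "ranked list")
    w = np.abs(metric_sorted) ** exponent
    hit_w = np.where(hits, w, 0.0)
    totals = hit_w.sum(axis=-1, keepdims=True)
    # all-zero hit weights (e.g. zero metric inside the set): fall back to
    # equal weights so the statistic stays defined
    flat = (totals == 0.0)
    if np.any(flat):
        hit_w = np.where(flat & hits, 1.0, hit_w)
        totals = hit_w.sum(axis=-1, keepdims=True)
    steps = hit_w / totals - (~hits) / (n_total - n_hit)
    return np.cumsum(steps, axis=-1)


def _es_from_runs(runs: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(runs), axis=-1)
    return np.take_along_axis(runs, idx[..., None], axis=-1)[..., 0]


def gsea_es(ranked_genes, rank_metric, gene_set, exponent: float = 1.0) -> float:
    """Enrichment score of ``gene_set`` along a ranked gene list.

    ``ranked_genes`` is an ordered, duplicate-free id sequence (best rank
    first) with ``rank_metric`` aligned per gene. The ES is the running-sum
    value of largest magnitude (signed). An empty intersection with the
    ranked list raises rather than silently returning 0.
    """
    ranked = list(ranked_genes)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicates")
    metric = np.asarray(rank_metric, dtype=float)
    if metric.shape != (len(ranked),):
        raise ValueError("rank_metric must align with ranked_genes")
    members = set(gene_set)
    hits = np.array([g in members for g in ranked])
    if not hits.any():
        raise ValueError("gene set does not intersect the ranked list")
    runs = _running_sums(metric, hits, exponent)
    return float(_es_from_runs(runs)[0])


def gsea_permutation_p(ranked_genes, rank_metric, gene_set,
                       n_perm: int = 1000, seed: int = 0,
                       exponent: float = 1.0,
                       set_name: str = "") -> GseaResult:
    """Two-sided gene-permutation p for the enrichment score.

    Set membership is reshuffled over the ranked list ``n_perm`` times
    (seeded); p = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = list(ranked_genes)
    metric = np.asarray(rank_metric, dtype=float)
    es_obs = gsea_es(ranked, metric, gene_set, exponent)
    members = set(gene_set)
    n_hit = sum(1 for g in ranked if g in members)
    n_total = len(ranked)
    rng = np.random.default_rng(seed)
    hits = np.zeros((n_perm, n_total), dtype=bool)
    for i in range(n_perm):
        hits[i, rng.choice(n_total, size=n_hit, replace=False)] = True
    es_null = _es_from_runs(_running_sums(metric, hits, exponent))
    p = (1 + int(np.sum(np.abs(es_null) >= abs(es_obs) - 1e-12))) / (n_perm + 1)
    return GseaResult(set_name=set_name, es=es_obs, p=float(p),
                      n_perm=n_perm, seed=seed)
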