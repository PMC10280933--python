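"""Pearson co-expression between differential lncRNAs and mRNAs.

Every dif-lncRNA x dif-mRNA pair is tested across all samples (case and
control pooled); a pair is retained when r > ``r_min`` (strictly — the signed
threshold is taken literally; pass ``use_absolute=True`` for |r|) and
p < ``p_max``. With eight samples the r > 0.97 gate already implies p << 0.01,
so the p gate is redundant under the default design but is still enforced as
part of the criterion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires equal lengths >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("pearson undefined for zero-variance profiles")
    return float(np.corrcoef(x, y)[0, 1])


def pearson_pvalue(r, n: int):
    """Two-sided p for Pearson r via t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df.

    |r| = 1 maps to p = 0 by convention. Accepts scalars or arrays.
    """
    if n < 3:
        raise ValueError("pearson_pvalue requires n >= 3")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|r| must be <= 1")
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(n - 2) / np.sqrt(1.0 - rr ** 2)
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rr) >= 1.0, 0.0, p)
    return float(p) if p.ndim == 0 else p


def passes_gate(r: float, p: float, r_min: float = 0.97, p_max: float = 0.01,
                use_absolute: bool = False) -> bool:
    """The retention criterion: strict r > r_min (or |r| > r_min) and p < p_max."""
    value = abs(r) if use_absolute else r
    return bool(value > r_min and p < p_max)


def coexpression_pairs(de_records: pd.DataFrame, matrix: ExpressionMatrix,
                       r_min: float = 0.97, p_max: float = 0.01,
                       use_absolute: bool = False) -> pd.DataFrame:
    """Retained lncRNA-mRNA pairs among differential genes.

    Returns a DataFrame with columns (lncrna_id, mrna_id, r, p, n), ordered by
    (lncrna_id, mrna_id). Zero-variance profiles are skipped with a log
    message rather than raising. Empty differential input yields an empty
    table (with a warning) so degenerate thresholds flow through the pipeline.
    """
    dif = de_records[de_records["direction"] != "ns"]
    lnc_ids = sorted(dif.loc[dif["biotype"] == "lncRNA", "gene_id"])
    mrna_ids = sorted(dif.loc[dif["biotype"] == "mRNA", "gene_id"])
    empty = pd.DataFrame(columns=["lncrna_id", "mrna_id", "r", "p", "n"])
    if not lnc_ids or not mrna_ids:
        log.warning("no differential lncRNAs and/or mRNAs; empty co-expression set")
        return empty

    n = len(matrix.sample_ids)
    L = matrix.values.loc[lnc_ids].to_numpy(dtype=float)
    M = matrix.values.loc[mrna_ids].to_numpy(dtype=float)

    def standardize(a: np.ndarray, ids: list[str]):
        sd = a.std(axis=1)
        keep = sd > 0.0
        for gid in np.asarray(ids)[~keep]:
            log.info("skipping zero-variance profile %s", gid)
        z = (a[keep] - a[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        return z, list(np.asarray(ids)[keep])

    Lz, lnc_kept = standardize(L, lnc_ids)
    Mz, mrna_kept = standardize(M, mrna_ids)
    if not lnc_kept or not mrna_kept:
        return empty

    R = np.clip(Lz @ Mz.T / n, -1.0, 1.0)
    P = pearson_pvalue(R, n)
    gate = (np.abs(R) if use_absolute else R) > r_min
    li, mi = np.nonzero(gate & (P < p_max))
    out = pd.DataFrame({
        "lncrna_id": np.asarray(lnc_kept)[li],
        "mrna_id": np.asarray(mrna_kept)[mi],
        "r": R[li, mi],
        "p": P[li, mi],
        "n": n,
    })
    return out.sort_values(["lncrna_id", "mrna_id"]).reset_index(drop=True)
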