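"""Wet-lab validation statistics: 2^-ddCt quantification and Mann-Whitney U.

Relative qPCR quantification normalizes the target gene's Ct to a reference
gene per sample (dCt = Ct_target - Ct_reference), then to the control group
(ddCt = mean dCt_case - mean dCt_control); the group fold change is
2^-ddCt. Per-sample relative quantities 2^-(dCt - mean dCt_control) are also
returned for plotting and group comparison. Group means are used throughout —
the samples are unpaired.

The Mann-Whitney U comparison is exact (full labeling enumeration) for small
tie-free inputs and switches to the tie- and continuity-corrected normal
approximation otherwise; the method used is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_TOTAL_N = 12  # exact branch when n1+n2 <= this and no ties

CT_COLUMNS = ["sample_id", "group", "gene_id", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class DdctResult:
    gene_id: str
    ddct: float
    fold: float                      # 2^-ddCt, case relative to control
    per_sample: pd.DataFrame         # sample_id, group, dct, rel_quantity


def ddct_fold(records: pd.DataFrame, gene_id: str) -> DdctResult:
    """2^-ddCt relative quantification of one gene, case vs control.

    ``records`` has columns (sample_id, group, gene_id, ct_target,
    ct_reference); every sample must carry a reference Ct.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    sub = records[records["gene_id"] == gene_id].copy()
    if sub.empty:
        raise ValueError(f"no Ct records for gene {gene_id!r}")
    bad_ref = sub.loc[~np.isfinite(sub["ct_reference"].astype(float)), "sample_id"]
    if len(bad_ref):
        raise ValueError(f"missing reference Ct for sample(s) {list(bad_ref)}")
    for g in ("case", "control"):
        if not (sub["group"] == g).any():
            raise ValueError(f"no {g} Ct records for gene {gene_id!r}")
    sub["dct"] = sub["ct_target"].astype(float) - sub["ct_reference"].astype(float)
    mean_case = sub.loc[sub["group"] == "case", "dct"].mean()
    mean_control = sub.loc[sub["group"] == "control", "dct"].mean()
    ddct = mean_case - mean_control
    sub["rel_quantity"] = 2.0 ** (-(sub["dct"] - mean_control))
    per_sample = sub[["sample_id", "group", "dct", "rel_quantity"]].reset_index(drop=True)
    return DdctResult(gene_id=gene_id, ddct=float(ddct),
                      fold=float(2.0 ** (-ddct)), per_sample=per_sample)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "normal-approx"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Exact p by full enumeration of labelings when n1+n2 <= 12 with no ties;
    otherwise the normal approximation with tie and continuity corrections.
    All-tied input returns p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=x.size * y.size / 2.0, p=1.0,
                                 method="normal-approx")
    if x.size + y.size <= EXACT_MAX_TOTAL_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                                 method="exact")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic),
                             p=float(min(res.pvalue, 1.0)),
                             method="normal-approx")


def qpcr_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ddCt fold change plus Mann-Whitney comparison of the
    per-sample relative quantities; one row per gene in the Ct table."""
    rows = []
    for gene_id in sorted(records["gene_id"].unique()):
        res = ddct_fold(records, gene_id)
        ps = res.per_sample
        mw = mann_whitney(ps.loc[ps["group"] == "case", "rel_quantity"],
                          ps.loc[ps["group"] == "control", "rel_quantity"])
        rows.append((gene_id, res.ddct, res.fold, mw.u, mw.p, mw.method))
    return pd.DataFrame(rows, columns=["gene_id", "ddct", "fold", "u", "p",
                                       "method"])
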